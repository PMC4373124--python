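"""Readers and writers for the plain-text formats used across the package.

Dialects: UTF-8 throughout, header rows mandatory, "." decimal separator.
FASTA population labels come from a ``|``-separated header token
(``>sample|population``) or a sidecar TSV (columns sample, population).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import FrequencyTable, FstMatrix
from .errors import InputError
from .haplotree import ANCESTRAL, DERIVED, MISSING, HaploTree, Marker, YGenotype
from .mtdna import DEFAULT_HVS1_WINDOW, Hvs1Sequence, MtMotifTable


# ---------------------------------------------------------------- FASTA ---

def write_fasta(sequences, path):
    records = [
        SeqRecord(
            Seq(s.sequence),
            id=f"{s.sample_id}|{s.population}",
            description=f"window={s.declared_window[0]}-{s.declared_window[1]}",
        )
        for s in sequences
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path, population_map=None, default_window=DEFAULT_HVS1_WINDOW):
    """Read HVS-I sequences; population from the header token or a map."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, _, pop = rec.id.partition("|")
        if population_map is not None:
            pop = population_map.get(sample, pop)
        if not pop:
            raise InputError(f"no population for sequence {sample!r}")
        if sample in seen:
            raise InputError(f"duplicate sequence ID {sample!r}")
        seen.add(sample)
        window = default_window
        for token in rec.description.split():
            if token.startswith("window="):
                a, _, b = token[len("window="):].partition("-")
                window = (int(a), int(b))
        out.append(
            Hvs1Sequence(
                sample_id=sample,
                population=pop,
                sequence=str(rec.seq),
                declared_window=window,
            )
        )
    return out


# --------------------------------------------------------- genotype TSV ---

def write_genotypes_tsv(genotypes, markers, path):
    """Rows = samples, columns = markers, cells in {A,C,G,T,0}."""
    marker_by_name = {m.name: m for m in markers}
    rows = {}
    pops = {}
    for g in genotypes:
        cells = {}
        for name, state in g.states.items():
            m = marker_by_name[name]
            if state == MISSING:
                cells[name] = "0"
            elif state == DERIVED:
                cells[name] = m.derived_allele
            else:
                cells[name] = m.ancestral_allele
        rows[g.sample_id] = cells
        pops[g.sample_id] = g.population
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.insert(0, "population", pd.Series(pops))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path, markers):
    marker_by_name = {m.name: m for m in markers}
    df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
    genotypes = []
    for i, (sample, row) in enumerate(df.iterrows(), start=2):
        states = {}
        for name, cell in row.items():
            if name == "population":
                continue
            m = marker_by_name.get(name)
            if m is None:
                raise InputError(f"line {i}: unknown marker column {name!r}")
            if cell == "0":
                states[name] = MISSING
            elif cell == m.derived_allele:
                states[name] = DERIVED
            elif cell == m.ancestral_allele:
                states[name] = ANCESTRAL
            else:
                raise InputError(
                    f"line {i}: allele {cell!r} matches neither state of {name}"
                )
        genotypes.append(
            YGenotype(sample_id=sample, population=row["population"], states=states)
        )
    return genotypes


# ------------------------------------------------------- frequency CSV ---

def write_frequency_csv(table: FrequencyTable, path):
    df = table.counts.copy()
    df.insert(0, "n", table.n)
    df.index.name = "population"
    df.to_csv(path)


def read_frequency_csv(path) -> FrequencyTable:
    df = pd.read_csv(path, index_col="population")
    n = df.pop("n")
    counts = df.astype(int)
    bad = counts.sum(axis=1) != n
    if bad.any():
        raise InputError(
            f"rows not summing to n: {counts.index[bad].tolist()}"
        )
    counts.index.name = None
    return FrequencyTable(counts)


# ------------------------------------------------------------- F_ST CSV ---

def write_fst_csv(matrix: FstMatrix, path, p_path=None):
    matrix.fst.to_csv(path)
    if p_path is not None and matrix.p is not None:
        matrix.p.to_csv(p_path)


def read_fst_csv(path, p_path=None) -> FstMatrix:
    fst = pd.read_csv(path, index_col=0)
    fst.columns.name = None
    p = pd.read_csv(p_path, index_col=0) if p_path else None
    return FstMatrix(list(fst.index), fst, p)


# ---------------------------------------------------------- metadata CSV --

def read_metadata_csv(path) -> pd.DataFrame:
    """population, region (west/east of the Wallace line), lat, lon."""
    df = pd.read_csv(path, index_col="population")
    missing = {"region", "lat", "lon"} - set(df.columns)
    if missing:
        raise InputError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def write_metadata_csv(df: pd.DataFrame, path):
    out = df.copy()
    out.index.name = "population"
    out.to_csv(path)


# --------------------------------------------------- newick + marker TSV --

def write_tree(tree: HaploTree, newick_path, markers_path=None):
    def render(node):
        kids = tree.children[node]
        if not kids:
            return node
        return "(" + ",".join(render(k) for k in sorted(kids)) + ")" + node

    with open(newick_path, "w") as fh:
        fh.write(render(tree.root) + ";\n")
    if markers_path is not None:
        rows = [
            {
                "marker": m.name,
                "node": m.node,
                "ancestral": m.ancestral_allele,
                "derived": m.derived_allele,
            }
            for ms in tree.markers.values()
            for m in ms
        ]
        pd.DataFrame(rows).to_csv(markers_path, sep="\t", index=False)


def read_tree(newick_path, markers_path=None) -> HaploTree:
    from io import StringIO

    from Bio import Phylo

    with open(newick_path) as fh:
        clade_tree = Phylo.read(StringIO(fh.read()), "newick")
    parent = {}

    def walk(clade, par):
        name = clade.name
        if name is None:
            raise InputError("newick tree has an unnamed node")
        parent[name] = par
        for child in clade.clades:
            walk(child, name)

    walk(clade_tree.root, None)
    markers = []
    if markers_path is not None:
        df = pd.read_csv(markers_path, sep="\t")
        markers = [
            Marker(r["marker"], r["node"], r["ancestral"], r["derived"])
            for _, r in df.iterrows()
        ]
    return HaploTree(parent, markers)


# ------------------------------------------------------- motif table TSV --

def write_motif_table(table: MtMotifTable, path):
    rows = [
        {"haplogroup": hg, "position": pos, "derived": alt}
        for hg, vs in table.entries.items()
        for pos, alt in sorted(vs)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_motif_table(path, tree: HaploTree) -> MtMotifTable:
    df = pd.read_csv(path, sep="\t")
    entries = {}
    for _, r in df.iterrows():
        entries.setdefault(r["haplogroup"], set()).add(
            (int(r["position"]), r["derived"])
        )
    return MtMotifTable(entries, tree)


# ------------------------------------------------------ ESRI ASCII grid ---

def write_esri_ascii_grid(surface, path, nodata=-9999.0):
    """Write a GeoSurface as an ESRI ASCII grid (.asc).

    Requires uniform cell size; the grid is written north-up (last row of
    the array is the northernmost)."""
    import numpy as np

    grid = surface.grid
    x, y = surface.x_coords, surface.y_coords
    dx = float(x[1] - x[0])
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {x[0] - dx / 2}\n")
        fh.write(f"yllcorner {y[0] - dx / 2}\n")
        fh.write(f"cellsize {dx}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in grid[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_grid_csv(surface, path):
    import numpy as np

    gx, gy = np.meshgrid(surface.x_coords, surface.y_coords)
    pd.DataFrame(
        {"lon": gx.ravel(), "lat": gy.ravel(), "value": surface.grid.ravel()}
    ).to_csv(path, index=False)
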