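"""Synthetic fixtures: marker panels, haplogroup trees, genotype and
HVS-I sequence generators, admixture scenarios, and reconstructions of the
published Bornean/Sulawesi frequency tables.

The three study populations are reconstructed from their printed haplogroup
frequencies: mtDNA sample sizes are 159 (Ma'anyan), 19 (Lebbo') and 27
(Bajo); Y-chromosome male counts are not printed and are recovered as the
smallest sample size whose rounded counts reproduce every printed 4-decimal
frequency (90, 15 and 27 respectively).

The mtDNA motif table and HVS-I reference window packaged here are
synthetic miniatures: only the Polynesian-motif positions (16217, 16247,
16261 and coding 14022) and the Malagasy-motif positions (1473, 3423) are
real diagnostic sites; every other haplogroup is tagged by invented,
mutually distinct control-region positions so that classification is exact
on fixtures.  The reference window is a deterministic synthetic stand-in
for the true control-region reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diversity import (
    FrequencyTable,
    find_sample_size,
    infer_counts_from_frequencies,
)
from .errors import ConfigurationError, InputError
from .haplotree import DERIVED, ANCESTRAL, MISSING, HaploTree, Marker, YGenotype
from .mtdna import (
    CODING,
    CONTROL,
    DEFAULT_HVS1_WINDOW,
    MotifDef,
    MtMotifTable,
    ReferenceWindow,
    region_of,
)

import pandas as pd

# --------------------------------------------------------------------------
# printed frequency tables (4-decimal, "--" entries omitted)
# --------------------------------------------------------------------------

# Y chromosome: haplogroup node label -> (Lebbo, Maanyan, Bajo) frequency
Y_TABLE = {
    "C":      (0.1333, 0.5222, 0.0370),
    "K":      (0.0667, None,   None),
    "K-M526": (0.1333, 0.0222, 0.2222),
    "O1a":    (None,   0.0222, 0.0370),
    "O1a1":   (None,   0.1000, None),
    "O2a1":   (0.3333, 0.0778, None),
    "O3":     (None,   0.0111, 0.0370),
    "C1c":    (None,   None,   0.2222),
    "O1a2":   (0.2667, 0.0222, None),
    "O2a1a":  (None,   0.0111, None),
    "O3a2":   (0.0667, 0.1778, 0.0741),
    "O3a2b":  (None,   None,   0.0370),
    "M1a":    (None,   None,   0.0741),
    "P":      (None,   0.0222, None),
    "R":      (None,   None,   0.1481),
    "R1a":    (None,   0.0111, None),
    "T1a":    (None,   None,   0.0741),
    "L1a":    (None,   None,   0.0370),
}

# mtDNA: haplogroup -> (Lebbo, Maanyan, Bajo) frequency
MT_TABLE = {
    "B4a":      (0.2105, 0.0943, 0.0741),
    "B4c1b":    (None,   0.0252, 0.0741),
    "B4c2":     (None,   0.1887, None),
    "B5a":      (0.1579, 0.0377, 0.0370),
    "B4a2a":    (None,   0.0440, None),
    "B4a4":     (None,   None,   0.0741),
    "B4b1":     (None,   0.0818, None),
    "F3b1a":    (None,   0.0189, None),
    "M12":      (None,   0.0377, None),
    "M20":      (0.1579, 0.0440, None),
    "M71a2":    (0.1579, None,   None),
    "M73":      (None,   0.0566, 0.0370),
    "M74b1":    (None,   0.1069, None),
    "N22":      (None,   0.0189, None),
    "N9a6a":    (None,   0.0252, None),
    "R22":      (None,   None,   0.0370),
    "R9b1a1a":  (0.1053, None,   None),
    "X":        (None,   None,   0.0370),
    "Q1":       (None,   None,   0.0741),
    "B4a1a1":   (None,   None,   0.0370),
    "D4s":      (None,   0.0629, None),
    "E1a":      (0.2105, None,   0.0741),
    "F1a":      (None,   0.0377, 0.0370),
    "F1a1a":    (None,   0.0377, None),
    "F1a3":     (None,   None,   0.0741),
    "F1a4":     (None,   0.0252, None),
    "M7b1a1i":  (None,   None,   0.1481),
    "M7b1a2":   (None,   0.0126, 0.0741),
    "M7c1a4a":  (None,   0.0126, 0.1111),
    "M2":       (None,   0.0063, None),
    "M35a":     (None,   0.0189, None),
    "M5a4":     (None,   0.0063, None),
}

POPULATIONS = ("Lebbo", "Maanyan", "Bajo")
MT_SAMPLE_SIZES = {"Maanyan": 159, "Lebbo": 19, "Bajo": 27}

# --------------------------------------------------------------------------
# Y tree and marker panel
# --------------------------------------------------------------------------

# (node, parent, marker, ancestral, derived)
_Y_TREE_SPEC = [
    ("Y", None, None, None, None),
    ("C", "Y", "RPS4Y", "C", "T"),
    ("C1c", "C", "M38", "T", "G"),
    ("K", "Y", "M9", "C", "G"),
    ("L1a", "K", "M76", "A", "G"),
    ("T1a", "K", "M70", "A", "C"),
    ("K-M526", "K", "M526", "G", "C"),
    ("O1a", "K-M526", "M119", "A", "C"),
    ("O1a1", "O1a", "P203", "G", "A"),
    ("O1a2", "O1a", "M110", "T", "C"),
    ("O2a1", "K-M526", "M95", "C", "T"),
    ("O2a1a", "O2a1", "M88", "A", "G"),
    ("O3", "K-M526", "M122", "T", "C"),
    ("O3a2", "O3", "P201", "C", "T"),
    ("O3a2b", "O3a2", "M7", "C", "G"),
    ("M1a", "K-M526", "M186", "G", "T"),
    ("P", "K-M526", "M45", "G", "A"),
    ("R", "P", "M207", "A", "G"),
    ("R1a", "R", "M17", "G", "A"),
]

# --------------------------------------------------------------------------
# mtDNA motif table (synthetic miniature; see module docstring)
# --------------------------------------------------------------------------

# haplogroup -> parent, own diagnostic additions (pos, ref, alt, region)
_MT_TREE_SPEC = {
    "rCRS": (None, []),
    "B4a": ("rCRS", [(16189, "T", "C", CONTROL), (16299, "A", "G", CONTROL)]),
    "B4a1a1": ("B4a", [
        (16217, "T", "C", CONTROL),
        (16247, "A", "G", CONTROL),
        (16261, "C", "T", CONTROL),
        (14022, "A", "G", CODING),
    ]),
    "B4a2a": ("B4a", [(16052, "C", "T", CONTROL)]),
    "B4a4": ("B4a", [(16055, "G", "A", CONTROL)]),
    "F1a": ("rCRS", [(16108, "C", "T", CONTROL), (16129, "G", "A", CONTROL)]),
    "F1a1a": ("F1a", [(16162, "A", "G", CONTROL)]),
    "F1a3": ("F1a", [(16172, "T", "C", CONTROL)]),
    "F1a4": ("F1a", [(16304, "T", "C", CONTROL)]),
    "B4c1b": ("rCRS", [(16060, "C", "T", CONTROL), (16063, "T", "C", CONTROL)]),
    "B4c2": ("rCRS", [(16066, "A", "G", CONTROL), (16069, "C", "T", CONTROL)]),
    "B5a": ("rCRS", [(16072, "T", "C", CONTROL), (16075, "A", "G", CONTROL)]),
    "B4b1": ("rCRS", [(16078, "C", "T", CONTROL), (16081, "G", "A", CONTROL)]),
    "F3b1a": ("rCRS", [(16084, "T", "C", CONTROL), (16087, "A", "G", CONTROL)]),
    "M12": ("rCRS", [(16090, "C", "T", CONTROL), (16093, "T", "C", CONTROL)]),
    "M20": ("rCRS", [(16096, "A", "G", CONTROL), (16099, "C", "T", CONTROL)]),
    "M71a2": ("rCRS", [(16102, "T", "C", CONTROL), (16105, "G", "A", CONTROL)]),
    "M73": ("rCRS", [(16111, "A", "G", CONTROL), (16114, "C", "T", CONTROL)]),
    "M74b1": ("rCRS", [(16117, "T", "C", CONTROL), (16120, "A", "G", CONTROL)]),
    "N22": ("rCRS", [(16123, "C", "T", CONTROL), (16126, "T", "C", CONTROL)]),
    "N9a6a": ("rCRS", [(16132, "G", "A", CONTROL), (16135, "A", "G", CONTROL)]),
    "R22": ("rCRS", [(16138, "C", "T", CONTROL), (16141, "T", "C", CONTROL)]),
    "R9b1a1a": ("rCRS", [(16144, "A", "G", CONTROL), (16147, "C", "T", CONTROL)]),
    "X": ("rCRS", [(16150, "T", "C", CONTROL), (16153, "G", "A", CONTROL)]),
    "Q1": ("rCRS", [(16156, "A", "G", CONTROL), (16159, "C", "T", CONTROL)]),
    "D4s": ("rCRS", [(16165, "T", "C", CONTROL), (16168, "A", "G", CONTROL)]),
    "E1a": ("rCRS", [(16174, "C", "T", CONTROL), (16177, "A", "G", CONTROL)]),
    "M7b1a1i": ("rCRS", [(16180, "T", "C", CONTROL), (16183, "A", "G", CONTROL)]),
    "M7b1a2": ("rCRS", [(16186, "C", "T", CONTROL), (16195, "C", "T", CONTROL)]),
    "M7c1a4a": ("rCRS", [(16198, "C", "T", CONTROL), (16201, "A", "G", CONTROL)]),
    "M2": ("rCRS", [(16204, "C", "T", CONTROL), (16207, "A", "G", CONTROL)]),
    "M35a": ("rCRS", [(16210, "T", "C", CONTROL), (16213, "G", "A", CONTROL)]),
    "M5a4": ("rCRS", [(16220, "C", "T", CONTROL), (16224, "T", "C", CONTROL)]),
}

# Malagasy-motif coding positions: the paper names the sites, not the
# alleles; placeholder T>C alleles are used.
MALAGASY_CODING = [(1473, "T", "C"), (3423, "T", "C")]

POLYNESIAN_MOTIF = MotifDef(
    name="Polynesian",
    required_variants=((16217, "C"), (16247, "G"), (16261, "T"), (14022, "G")),
)

MALAGASY_MOTIF = MotifDef(
    name="Malagasy",
    required_variants=(
        (16217, "C"), (16247, "G"), (16261, "T"), (1473, "C"), (3423, "C")
    ),
)

_REFERENCE_SEED = 20150317  # fixed: the reference is a constant of the package
HVS1_REFERENCE_START = 16001
HVS1_REFERENCE_LENGTH = 400


def _cumulative_mt_entries():
    """Haplogroup -> list of (pos, ref, alt, region), parent-inclusive."""
    out = {}

    def build(hg):
        if hg in out:
            return out[hg]
        parent, own = _MT_TREE_SPEC[hg]
        base = list(build(parent)) if parent is not None else []
        out[hg] = base + list(own)
        return out[hg]

    for hg in _MT_TREE_SPEC:
        build(hg)
    return out


def synthetic_hvs1_reference() -> ReferenceWindow:
    """Deterministic synthetic HVS-I reference window (16001..16400).

    A stand-in for the true control-region reference: bases at the packaged
    diagnostic positions are fixed to the table's reference alleles, the
    remainder is seeded-random.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=HVS1_REFERENCE_LENGTH))
    for entries in _cumulative_mt_entries().values():
        for pos, ref, _alt, region in entries:
            if region == CONTROL:
                offset = pos - HVS1_REFERENCE_START
                if 0 <= offset < HVS1_REFERENCE_LENGTH:
                    seq[offset] = ref
    # avoid accidental homopolymers swallowing diagnostic sites is not
    # needed: private mutations avoid diagnostic positions by default.
    return ReferenceWindow(start=HVS1_REFERENCE_START, sequence="".join(seq))


def make_fixture_panel():
    """Miniature Y tree + marker panel and mtDNA motif table.

    Returns ``(y_tree, markers, mt_table)`` where the Y tree carries one
    defining marker per printed haplogroup and the motif table covers every
    printed mtDNA haplogroup, including the four Polynesian-motif variants
    under B4a1a1.
    """
    parent = {node: par for node, par, *_ in _Y_TREE_SPEC}
    markers = [
        Marker(name=m, node=node, ancestral_allele=anc, derived_allele=der)
        for node, _par, m, anc, der in _Y_TREE_SPEC
        if m is not None
    ]
    y_tree = HaploTree(parent, markers)

    mt_parent = {hg: spec[0] for hg, spec in _MT_TREE_SPEC.items()}
    mt_tree = HaploTree(mt_parent)
    entries = {
        hg: {(pos, alt) for pos, _ref, alt, _r in ent}
        for hg, ent in _cumulative_mt_entries().items()
        if hg != "rCRS"
    }
    mt_table = MtMotifTable(entries, mt_tree)
    return y_tree, markers, mt_table


@dataclass
class PopulationSpec:
    """Composition of one synthetic population."""

    name: str
    n: int
    haplogroup_counts: dict
    missing_rate: float = 0.0
    private_mutation_rate: float = 0.0

    def __post_init__(self):
        if sum(self.haplogroup_counts.values()) != self.n:
            raise InputError(f"{self.name}: haplogroup counts do not sum to n")
        if not 0 <= self.missing_rate < 1:
            raise InputError(f"{self.name}: missing_rate out of [0,1)")
        if self.private_mutation_rate < 0:
            raise InputError(f"{self.name}: negative private_mutation_rate")


def simulate_y_genotypes(spec: PopulationSpec, tree: HaploTree, markers, seed=None):
    """Simulate binary-marker genotypes realising the spec's haplogroup
    counts: derived on the root path, ancestral elsewhere, missing with
    ``missing_rate``."""
    for hg in spec.haplogroup_counts:
        if hg not in tree.parent:
            raise InputError(f"unknown haplogroup {hg!r}")
    rng = np.random.default_rng(seed)
    genotypes = []
    i = 0
    for hg in sorted(spec.haplogroup_counts):
        path = set(tree.path(hg))
        for _ in range(spec.haplogroup_counts[hg]):
            i += 1
            states = {}
            for m in markers:
                if spec.missing_rate and rng.random() < spec.missing_rate:
                    states[m.name] = MISSING
                else:
                    states[m.name] = DERIVED if m.node in path else ANCESTRAL
            genotypes.append(
                YGenotype(
                    sample_id=f"{spec.name}_Y{i:03d}",
                    population=spec.name,
                    states=states,
                )
            )
    return genotypes


@dataclass
class CodingSidecar:
    """Targeted coding-region genotypes (sample -> {position: allele}),
    mirroring follow-up typing of motif carriers."""

    calls: dict = field(default_factory=dict)

    def typed_regions(self, sample_id):
        return {CONTROL, CODING} if sample_id in self.calls else {CONTROL}

    def variants_for(self, sample_id):
        from .mtdna import VariantCall

        out = []
        for pos, (ref, alt) in self.calls.get(sample_id, {}).items():
            if alt != ref:
                out.append(VariantCall(pos, ref, alt, "substitution"))
        return out


def simulate_hvs1_sequences(
    spec: PopulationSpec,
    mt_table: MtMotifTable,
    reference: ReferenceWindow | None = None,
    seed=None,
    window=DEFAULT_HVS1_WINDOW,
    coding_sidecar=True,
    allow_private_on_diagnostic=False,
):
    """Simulate HVS-I sequences realising the spec's haplogroup counts.

    Each sequence carries its haplogroup's control-region diagnostic
    variants plus Poisson(``private_mutation_rate``) private substitutions
    at non-diagnostic positions.  Coding-region diagnostic variants go into
    a :class:`CodingSidecar` (B4a-clade individuals get coding typing for
    the Polynesian/Malagasy positions); without the sidecar a coding
    diagnostic raises :class:`ConfigurationError`.

    Returns ``(sequences, sidecar)``.
    """
    reference = reference or synthetic_hvs1_reference()
    entries = _cumulative_mt_entries()
    for hg in spec.haplogroup_counts:
        if hg not in entries:
            raise InputError(f"unknown mtDNA haplogroup {hg!r}")
    rng = np.random.default_rng(seed)

    from .mtdna import Hvs1Sequence, _window_positions

    win_pos = _window_positions(*window)
    diagnostic_positions = {
        pos for ent in entries.values() for pos, *_ in ent
    }
    ref_sub = reference.slice(window)
    sequences = []
    sidecar = CodingSidecar()
    i = 0
    for hg in sorted(spec.haplogroup_counts):
        hap_entries = entries[hg]
        for _ in range(spec.haplogroup_counts[hg]):
            i += 1
            sid = f"{spec.name}_M{i:03d}"
            seq = list(ref_sub.sequence)
            coding_calls = {}
            for pos, ref_b, alt, region in hap_entries:
                if region == CONTROL and pos in win_pos:
                    seq[win_pos.index(pos)] = alt
                elif region == CODING:
                    if not coding_sidecar:
                        raise ConfigurationError(
                            f"{hg}: diagnostic position {pos} lies outside the "
                            "HVS-I window and no coding sidecar was requested"
                        )
                    coding_calls[pos] = (ref_b, alt)
                else:
                    raise ConfigurationError(
                        f"{hg}: diagnostic position {pos} outside window {window}"
                    )
            # B4a-clade carriers get targeted coding typing of the motif sites
            if coding_sidecar and _is_b4a_clade(hg):
                coding_calls.setdefault(14022, ("A", "A"))
                for pos, ref_b, _alt in MALAGASY_CODING:
                    coding_calls.setdefault(pos, (ref_b, ref_b))
            if coding_calls:
                sidecar.calls[sid] = coding_calls

            n_private = rng.poisson(spec.private_mutation_rate)
            candidates = [
                p for p in win_pos
                if allow_private_on_diagnostic or p not in diagnostic_positions
            ]
            for pos in rng.choice(
                candidates, size=min(n_private, len(candidates)), replace=False
            ):
                idx = win_pos.index(int(pos))
                current = seq[idx]
                seq[idx] = rng.choice([b for b in "ACGT" if b != current])
            sequences.append(
                Hvs1Sequence(
                    sample_id=sid,
                    population=spec.name,
                    sequence="".join(seq),
                    declared_window=window,
                )
            )
    return sequences, sidecar


def _is_b4a_clade(hg):
    cur = hg
    while cur is not None:
        if cur == "B4a":
            return True
        cur = _MT_TREE_SPEC[cur][0]
    return False


@dataclass
class AdmixtureScenario:
    """A target population formed as a mixture of source frequency vectors,
    with optional Wright-Fisher drift before the final sampling step."""

    sources: list  # list of pd.Series (frequencies)
    proportions: list
    n: int
    drift: tuple | None = None  # (generations, Ne)
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise InputError("proportions must be a simplex vector")
        if self.drift is not None:
            g, ne = self.drift
            if g <= 0 or ne <= 0:
                raise InputError("drift parameters must be positive")


def simulate_admixture(scenario: AdmixtureScenario) -> pd.Series:
    """Draw haplogroup counts for an admixed population.

    Mixture frequencies f = sum_s alpha_s f_s; optional drift applies g
    rounds of multinomial resampling at size Ne; final counts are a
    multinomial draw of size n.
    """
    rng = np.random.default_rng(scenario.seed)
    union = sorted({h for s in scenario.sources for h in s.index})
    f = np.zeros(len(union))
    for alpha, src in zip(scenario.proportions, scenario.sources):
        f += alpha * src.reindex(union, fill_value=0.0).to_numpy()
    f = f / f.sum()
    if scenario.drift is not None:
        g, ne = scenario.drift
        for _ in range(int(g)):
            f = rng.multinomial(int(ne), f) / int(ne)
    counts = rng.multinomial(scenario.n, f)
    return pd.Series(counts, index=union)


def _column_specs(table, sample_sizes, **rates):
    """PopulationSpec per population from a printed frequency table."""
    specs = {}
    for j, pop in enumerate(POPULATIONS):
        freqs = {hg: row[j] for hg, row in table.items() if row[j] is not None}
        n = sample_sizes[pop]
        counts = infer_counts_from_frequencies(pd.Series(freqs), n)
        specs[pop] = PopulationSpec(
            name=pop, n=n, haplogroup_counts=counts.to_dict(), **rates
        )
    return specs


def y_sample_sizes():
    """Male sample sizes recovered from the printed Y frequencies."""
    sizes = {}
    for j, pop in enumerate(POPULATIONS):
        freqs = pd.Series(
            {hg: row[j] for hg, row in Y_TABLE.items() if row[j] is not None}
        )
        sizes[pop] = find_sample_size(freqs)
    return sizes


def fixtures_from_tables(missing_rate=0.0, private_mutation_rate=0.0):
    """PopulationSpec pairs (Y, mtDNA) reconstructing the printed tables.

    Returns ``{population: {"y": PopulationSpec, "mt": PopulationSpec}}``.
    """
    y_specs = _column_specs(
        Y_TABLE, y_sample_sizes(), missing_rate=missing_rate
    )
    mt_specs = _column_specs(
        MT_TABLE, MT_SAMPLE_SIZES,
        private_mutation_rate=private_mutation_rate,
    )
    return {
        pop: {"y": y_specs[pop], "mt": mt_specs[pop]} for pop in POPULATIONS
    }


def fixture_frequency_tables():
    """FrequencyTables (Y and mtDNA) built directly from the reconstructed
    counts of the printed tables."""
    fx = fixtures_from_tables()
    y = pd.DataFrame(
        {pop: pd.Series(fx[pop]["y"].haplogroup_counts) for pop in POPULATIONS}
    ).T
    mt = pd.DataFrame(
        {pop: pd.Series(fx[pop]["mt"].haplogroup_counts) for pop in POPULATIONS}
    ).T
    return FrequencyTable(y.fillna(0)), FrequencyTable(mt.fillna(0))


# --------------------------------------------------------------------------
# synthetic African reference (stand-in; the published reference panel's
# frequency tables are not packaged)
# --------------------------------------------------------------------------

def synthetic_african_reference(kind="y") -> FrequencyTable:
    """Two-population synthetic African reference panel.

    Haplogroup labels are disjoint from the Indonesian panels, giving the
    mixture decomposition a well-separated non-Asian component.
    """
    if kind == "y":
        counts = pd.DataFrame(
            {
                "E1b1a": [140, 130],
                "E2": [30, 25],
                "B2": [20, 28],
                "A1b": [10, 17],
            },
            index=["AfricanRef1", "AfricanRef2"],
        )
    elif kind == "mt":
        counts = pd.DataFrame(
            {
                "L0a": [40, 35],
                "L1c": [30, 28],
                "L2a": [60, 55],
                "L3e": [70, 82],
            },
            index=["AfricanRef1", "AfricanRef2"],
        )
    else:
        raise InputError("kind must be 'y' or 'mt'")
    return FrequencyTable(counts)


# approximate sampling locations (decimal degrees) and Wallace-line side
POPULATION_METADATA = pd.DataFrame(
    {
        "region": ["west", "west", "east"],
        "lat": [2.8, -2.1, -3.97],
        "lon": [117.3, 115.1, 122.52],
    },
    index=list(POPULATIONS),
)
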