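"""End-to-end pipeline over the packaged synthetic fixtures.

Stages: typing -> frequency tables -> pairwise F_ST with permutations ->
NMDS + kriging + Mann-Whitney east/west contrast + lower-quartile affinity
-> haplotype sharing -> mixture decomposition with bootstrap.  Every run
writes its artifacts plus a manifest (seed, resolved configuration, sha256
of each output) so any output can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as htio
from .diversity import (
    DEFAULT_N_PERMUTATIONS,
    FrequencyTable,
    build_frequency_table,
    fst_matrix,
    lower_quartile_affinity,
    mann_whitney_u,
)
from .errors import HaplotraceError
from .haplotree import call_y_haplogroup
from .kriging import GridSpec, krige_surface
from .mixture import DEFAULT_BOOTSTRAP_REPS, bootstrap_mixture, build_profile_matrix, solve_mixture
from .mtdna import classify_mt_haplogroup, shared_haplotypes, align_to_rcrs
from .ordination import nmds
from .simulate import (
    POPULATION_METADATA,
    POPULATIONS,
    AdmixtureScenario,
    fixture_frequency_tables,
    fixtures_from_tables,
    make_fixture_panel,
    simulate_admixture,
    simulate_hvs1_sequences,
    simulate_y_genotypes,
    synthetic_african_reference,
    synthetic_hvs1_reference,
)

logger = logging.getLogger(__name__)

STAGES = (
    "typing", "frequencies", "fst", "ordination", "kriging",
    "sharing", "mixture",
)

# synthetic Malagasy-like admixture proportions used by the pipeline target:
# the paternal pool is ~65% African, the maternal ~30%, with the Asian part
# drawn mostly from the sea-nomad-like fixture
MALAGASY_SCENARIO = {
    "y": {"african": 0.65, "indonesian": {"Bajo": 0.20, "Lebbo": 0.10, "Maanyan": 0.05}},
    "mt": {"african": 0.30, "indonesian": {"Bajo": 0.45, "Lebbo": 0.10, "Maanyan": 0.15}},
    "n": {"y": 371, "mt": 529},
}


@dataclass
class RunConfig:
    """Resolved pipeline settings; defaults follow the study's stated
    analysis parameters (5,040 F_ST permutations, 5,000 bootstrap reps)."""

    seed: int = 0
    permutations: int = DEFAULT_N_PERMUTATIONS
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    mds_starts: int = 20
    kriging_slope: float = 1.0
    kriging_grid: tuple = (100, 100)
    comparison_window: tuple = (16051, 16365)
    skip: tuple = ()
    out_dir: str = "haplotrace_run"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _malagasy_target(tables: FrequencyTable, african: FrequencyTable,
                     kind: str, seed: int) -> FrequencyTable:
    """Synthetic pooled-Malagasy target drawn from the packaged scenario."""
    sc = MALAGASY_SCENARIO[kind]
    freqs = tables.frequencies
    af = african.counts.sum(axis=0)
    sources = [af / af.sum()]
    props = [sc["african"]]
    for pop, w in sc["indonesian"].items():
        sources.append(freqs.loc[pop])
        props.append(w)
    counts = simulate_admixture(
        AdmixtureScenario(
            sources=sources, proportions=props,
            n=MALAGASY_SCENARIO["n"][kind], seed=seed,
        )
    )
    counts = counts[counts > 0]
    merged = tables.counts.copy()
    merged = pd.concat([merged, counts.to_frame("Malagasy").T]).fillna(0)
    return FrequencyTable(merged)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic-fixture pipeline; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    artifacts = {}

    def record(stage, name, path):
        artifacts[name] = path
        manifest["stages"].setdefault(stage, []).append(str(path.name))

    def stage_enabled(stage):
        return stage not in config.skip

    try:
        y_tree, markers, mt_table = make_fixture_panel()
        reference = synthetic_hvs1_reference()
        fixtures = fixtures_from_tables()

        # --- typing ------------------------------------------------------
        y_assignments, mt_assignments = [], []
        all_sequences = {}
        if stage_enabled("typing"):
            for pop in POPULATIONS:
                genos = simulate_y_genotypes(
                    fixtures[pop]["y"], y_tree, markers,
                    seed=int(rng.integers(2**31 - 1)),
                )
                for g in genos:
                    a = call_y_haplogroup(g, y_tree)
                    y_assignments.append((g.sample_id, g.population, a.node))
                seqs, sidecar = simulate_hvs1_sequences(
                    fixtures[pop]["mt"], mt_table,
                    reference=reference,
                    seed=int(rng.integers(2**31 - 1)),
                )
                all_sequences[pop] = seqs
                for s in seqs:
                    variants = align_to_rcrs(s, reference)
                    variants += sidecar.variants_for(s.sample_id)
                    a = classify_mt_haplogroup(variants, mt_table)
                    mt_assignments.append((s.sample_id, s.population, a.haplogroup))
            path = out / "assignments.csv"
            pd.DataFrame(
                y_assignments + mt_assignments,
                columns=["sample", "population", "haplogroup"],
            ).to_csv(path, index=False)
            record("typing", "assignments", path)

        # --- frequency tables -------------------------------------------
        if y_assignments:
            y_table = build_frequency_table(y_assignments)
            mt_freq_table = build_frequency_table(mt_assignments)
        else:  # typing skipped: reconstruct directly from printed counts
            y_table, mt_freq_table = fixture_frequency_tables()
        if stage_enabled("frequencies"):
            for name, tbl in (("y", y_table), ("mt", mt_freq_table)):
                path = out / f"frequencies_{name}.csv"
                htio.write_frequency_csv(tbl, path)
                record("frequencies", f"frequencies_{name}", path)

        # --- augment with the synthetic Malagasy target ------------------
        african_y = synthetic_african_reference("y")
        african_mt = synthetic_african_reference("mt")
        y_aug = _malagasy_target(y_table, african_y, "y",
                                 int(rng.integers(2**31 - 1)))
        mt_aug = _malagasy_target(mt_freq_table, african_mt, "mt",
                                  int(rng.integers(2**31 - 1)))

        # --- F_ST ---------------------------------------------------------
        matrices = {}
        if stage_enabled("fst"):
            for name, tbl in (("y", y_aug), ("mt", mt_aug)):
                m = fst_matrix(
                    tbl, n_perm=config.permutations,
                    seed=int(rng.integers(2**31 - 1)),
                )
                matrices[name] = m
                path = out / f"fst_{name}.csv"
                htio.write_fst_csv(m, path, out / f"fst_{name}_p.csv")
                record("fst", f"fst_{name}", path)
                record("fst", f"fst_{name}_p", out / f"fst_{name}_p.csv")

        # --- ordination + affinity + Mann-Whitney -------------------------
        if stage_enabled("ordination") and matrices:
            summary = {}
            for name, m in matrices.items():
                ord_ = nmds(
                    m.fst.values, n_starts=config.mds_starts,
                    seed=int(rng.integers(2**31 - 1)),
                )
                coords = pd.DataFrame(
                    ord_.coordinates, index=m.populations, columns=["dim1", "dim2"]
                )
                path = out / f"mds_{name}.csv"
                coords.to_csv(path)
                record("ordination", f"mds_{name}", path)
                row = m.row("Malagasy")
                # the range-quartile filter needs >= 4 comparison populations
                affinity = (
                    sorted(lower_quartile_affinity(row))
                    if len(row) >= 4 else [row.idxmin()]
                )
                meta = POPULATION_METADATA
                west = row[[p for p in row.index if
                            p in meta.index and meta.loc[p, "region"] == "west"]]
                east = row[[p for p in row.index if
                            p in meta.index and meta.loc[p, "region"] == "east"]]
                if len(west) and len(east):
                    u, p_val = mann_whitney_u(west, east)
                else:
                    u, p_val = float("nan"), float("nan")
                summary[name] = {
                    "stress": ord_.stress,
                    "converged": ord_.converged,
                    "lower_quartile_affinity": affinity,
                    "mann_whitney_U": u,
                    "mann_whitney_p": p_val,
                }
            path = out / "ordination_summary.json"
            path.write_text(json.dumps(summary, indent=2))
            record("ordination", "ordination_summary", path)

        # --- kriging ------------------------------------------------------
        if stage_enabled("kriging") and matrices:
            meta = POPULATION_METADATA
            for name, m in matrices.items():
                row = m.row("Malagasy")
                pts = [
                    (meta.loc[p, "lon"], meta.loc[p, "lat"], row[p])
                    for p in row.index if p in meta.index
                ]
                surface = krige_surface(
                    pts,
                    GridSpec(nx=config.kriging_grid[0], ny=config.kriging_grid[1]),
                    slope=config.kriging_slope,
                )
                asc = out / f"fst_surface_{name}.asc"
                htio.write_esri_ascii_grid(surface, asc)
                record("kriging", f"fst_surface_{name}", asc)
                csv = out / f"fst_surface_{name}.csv"
                htio.write_grid_csv(surface, csv)
                record("kriging", f"fst_surface_{name}_csv", csv)

        # --- haplotype sharing -------------------------------------------
        if stage_enabled("sharing") and all_sequences:
            rows = []
            pops = list(all_sequences)
            for i, a in enumerate(pops):
                for b in pops[i + 1:]:
                    res = shared_haplotypes(
                        all_sequences[a], all_sequences[b], reference,
                        window=config.comparison_window,
                    )
                    rows.append({"pop_a": a, "pop_b": b, "shared": res.count})
            path = out / "haplotype_sharing.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            record("sharing", "haplotype_sharing", path)

        # --- mixture ------------------------------------------------------
        if stage_enabled("mixture"):
            for name, tbl, ref in (
                ("y", y_aug, african_y), ("mt", mt_aug, african_mt)
            ):
                matrix, target = build_profile_matrix(
                    tbl, "Malagasy", list(POPULATIONS), ref
                )
                sol = solve_mixture(matrix, target)
                boot = bootstrap_mixture(
                    tbl, "Malagasy", list(POPULATIONS), ref,
                    n_rep=config.bootstrap_reps,
                    seed=int(rng.integers(2**31 - 1)),
                )
                coeffs = boot.summaries.copy()
                coeffs.insert(0, "estimate", sol.as_series())
                path = out / f"mixture_{name}.csv"
                coeffs.to_csv(path)
                record("mixture", f"mixture_{name}", path)
    except HaplotraceError as exc:
        raise HaplotraceError(f"pipeline stage failed: {exc}") from exc

    for name, path in artifacts.items():
        manifest.setdefault("sha256", {})[path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
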