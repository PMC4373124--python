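"""Haplogroup-frequency tables and population differentiation statistics.

F_ST between two populations is estimated by a haploid AMOVA on haplogroup
(allele-class) frequencies with inter-individual distance delta = 1 for
different haplogroups and 0 otherwise:

    SSD_within(i) = (n_i^2 - sum_k c_ik^2) / (2 n_i)
    SSD_total     = analogous on pooled counts
    SSD_among     = SSD_total - SSD_within
    n_c           = (N - sum_i n_i^2 / N) / (P - 1)
    sigma2_a      = (MSD_among - MSD_within) / n_c,   sigma2_w = MSD_within
    F_ST          = sigma2_a / (sigma2_a + sigma2_w)

Significance is assessed by permuting individuals between the two
populations (sizes preserved) and counting permuted F_ST values at least as
large as the observed one; the default replicate count is 5,040.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ReconstructionError

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 5040


class FrequencyTable:
    """Population x haplogroup counts with per-population sample sizes.

    ``counts`` is a pandas DataFrame (rows = populations, columns =
    haplogroups, non-negative integers); the haplogroup set is the union
    across populations with zeros for absences.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.fillna(0).astype(int)
        if (counts.values < 0).any():
            raise InputError("negative haplogroup counts")
        if (counts.sum(axis=1) == 0).any():
            empty = counts.index[counts.sum(axis=1) == 0].tolist()
            raise InputError(f"populations with zero samples: {empty}")
        self.counts = counts

    @property
    def populations(self):
        return list(self.counts.index)

    @property
    def haplogroups(self):
        return list(self.counts.columns)

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.n, axis=0)

    def subset(self, populations):
        return FrequencyTable(self.counts.loc[list(populations)])

    def pool(self, populations, name):
        """Pool populations by summing counts (e.g. the Malagasy groups,
        which are genetically highly similar)."""
        pooled = self.counts.loc[list(populations)].sum(axis=0)
        rest = self.counts.drop(index=list(populations))
        out = pd.concat([rest, pooled.to_frame(name).T])
        return FrequencyTable(out)

    def collapse(self, mapping):
        """Collapse haplogroup labels to a shared resolution via ``mapping``
        (old label -> new label); unmapped labels are kept."""
        new = self.counts.T.groupby(
            lambda h: mapping.get(h, h)
        ).sum().T
        return FrequencyTable(new)

    def __eq__(self, other):
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        a = self.counts.sort_index(axis=0).sort_index(axis=1)
        b = other.counts.sort_index(axis=0).sort_index(axis=1)
        return a.equals(b)


def build_frequency_table(assignments) -> FrequencyTable:
    """Build a FrequencyTable from (sample, population, haplogroup) triples."""
    rows = list(assignments)
    if not rows:
        raise InputError("no assignments")
    df = pd.DataFrame(rows, columns=["sample", "population", "haplogroup"])
    counts = pd.crosstab(df["population"], df["haplogroup"])
    counts.index.name = None
    counts.columns.name = None
    return FrequencyTable(counts)


def infer_counts_from_frequencies(frequencies, n, decimals=4):
    """Recover integer counts from printed frequencies and a sample size.

    Each frequency times ``n`` must round to an integer count that
    reproduces the printed frequency at its printed precision
    (``decimals``), and the counts must sum to ``n``.
    """
    frequencies = pd.Series(frequencies, dtype=float)
    counts = (frequencies * n).round().astype(int)
    for hg, f in frequencies.items():
        c = counts[hg]
        if abs(f * n - c) > 0.5:
            raise ReconstructionError(
                f"{hg}: {f} x {n} = {f * n:.4f} is not near an integer"
            )
        if round(c / n, decimals) != round(f, decimals):
            raise ReconstructionError(
                f"{hg}: count {c}/{n} does not reproduce frequency {f} "
                f"at {decimals} decimals"
            )
    if counts.sum() != n:
        raise ReconstructionError(
            f"rounded counts sum to {counts.sum()}, expected {n}"
        )
    return counts


def find_sample_size(frequencies, n_max=1000, decimals=4):
    """Smallest n for which the printed frequencies reconstruct to integer
    counts (used to recover unprinted male sample sizes)."""
    for n in range(2, n_max + 1):
        try:
            infer_counts_from_frequencies(frequencies, n, decimals=decimals)
            return n
        except ReconstructionError:
            continue
    raise ReconstructionError(f"no sample size up to {n_max} fits the frequencies")


@dataclass
class AmovaComponents:
    """Sums of squares, degrees of freedom and variance components of the
    two-population haploid AMOVA."""

    ssd_total: float
    ssd_within: float
    ssd_among: float
    df_among: int
    df_within: int
    n_c: float
    sigma2_a: float
    sigma2_w: float

    @property
    def fst_raw(self) -> float:
        denom = self.sigma2_a + self.sigma2_w
        return 0.0 if denom == 0 else self.sigma2_a / denom


def _amova_from_counts(c_a, c_b):
    """Vectorised AMOVA F_ST over paired count arrays (..., K).

    Returns raw (unclipped) F_ST; callers decide the clip convention.
    """
    c_a = np.asarray(c_a, dtype=float)
    c_b = np.asarray(c_b, dtype=float)
    n_a = c_a.sum(axis=-1)
    n_b = c_b.sum(axis=-1)
    n_tot = n_a + n_b
    ssd_w = (n_a**2 - (c_a**2).sum(axis=-1)) / (2 * n_a) + (
        n_b**2 - (c_b**2).sum(axis=-1)
    ) / (2 * n_b)
    pooled = c_a + c_b
    ssd_t = (n_tot**2 - (pooled**2).sum(axis=-1)) / (2 * n_tot)
    ssd_a = ssd_t - ssd_w
    msd_a = ssd_a  # df_among = 1
    msd_w = ssd_w / (n_tot - 2)
    n_c = (n_tot - (n_a**2 + n_b**2) / n_tot)  # / (P - 1) with P = 2
    sigma_a = (msd_a - msd_w) / n_c
    sigma_w = msd_w
    denom = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom == 0, 0.0, sigma_a / np.where(denom == 0, 1.0, denom))
    return fst, (ssd_t, ssd_w, ssd_a, n_tot, n_c, sigma_a, sigma_w)


def _pair_counts(table: FrequencyTable, pop_a, pop_b):
    for p in (pop_a, pop_b):
        if p not in table.populations:
            raise InputError(f"unknown population {p!r}")
        if table.n[p] < 2:
            raise InputError(f"population {p!r} has n < 2")
    return (
        table.counts.loc[pop_a].to_numpy(float),
        table.counts.loc[pop_b].to_numpy(float),
    )


def pairwise_fst(table: FrequencyTable, pop_a, pop_b, clip=True):
    """Haploid AMOVA F_ST between two populations.

    Returns ``(fst, AmovaComponents)``.  With ``clip=True`` (default) a
    negative variance-component estimate yields F_ST = 0; the raw value
    remains available as ``components.fst_raw``.
    """
    c_a, c_b = _pair_counts(table, pop_a, pop_b)
    fst, (ssd_t, ssd_w, ssd_a, n_tot, n_c, s_a, s_w) = _amova_from_counts(c_a, c_b)
    comp = AmovaComponents(
        ssd_total=float(ssd_t),
        ssd_within=float(ssd_w),
        ssd_among=float(ssd_a),
        df_among=1,
        df_within=int(n_tot) - 2,
        n_c=float(n_c),
        sigma2_a=float(s_a),
        sigma2_w=float(s_w),
    )
    value = float(fst)
    if clip:
        value = max(0.0, value)
    return value, comp


def fst_permutation_test(
    table: FrequencyTable,
    pop_a,
    pop_b,
    n_perm=DEFAULT_N_PERMUTATIONS,
    seed=None,
    plus_one=False,
):
    """Permutation p-value for the pairwise F_ST.

    Individuals are permuted between the two populations (sizes preserved);
    p is the proportion of permuted raw F_ST values >= the observed raw
    value.  ``plus_one`` switches to the (b+1)/(n_perm+1) convention.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    c_a, c_b = _pair_counts(table, pop_a, pop_b)
    obs, _ = _amova_from_counts(c_a, c_b)
    obs = float(obs)

    k = len(c_a)
    n_a = int(c_a.sum())
    labels = np.repeat(np.arange(k), (c_a + c_b).astype(int))
    rng = np.random.default_rng(seed)
    # one independent shuffle per replicate
    order = np.argsort(rng.random((n_perm, labels.size)), axis=1)
    perm = labels[order]
    part_a, part_b = perm[:, :n_a], perm[:, n_a:]
    cnt_a = np.stack([(part_a == i).sum(axis=1) for i in range(k)], axis=1)
    cnt_b = np.stack([(part_b == i).sum(axis=1) for i in range(k)], axis=1)
    perm_fst, _ = _amova_from_counts(cnt_a, cnt_b)
    b = int((perm_fst >= obs - 1e-12).sum())
    if plus_one:
        return (b + 1) / (n_perm + 1)
    return b / n_perm


@dataclass
class FstMatrix:
    """Pairwise F_ST values and permutation p-values over populations."""

    populations: list
    fst: pd.DataFrame
    p: pd.DataFrame | None = None
    n_perm: int = 0
    seed: int | None = None

    def row(self, population) -> pd.Series:
        return self.fst.loc[population].drop(population)


def fst_matrix(
    table: FrequencyTable,
    populations=None,
    n_perm=DEFAULT_N_PERMUTATIONS,
    seed=None,
    clip=True,
    permutations=True,
) -> FstMatrix:
    """All pairwise F_ST values (and optional permutation p-values)."""
    pops = list(populations) if populations is not None else table.populations
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pmat = pd.DataFrame(np.nan, index=pops, columns=pops) if permutations else None
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            value, _ = pairwise_fst(table, a, b, clip=clip)
            fst.loc[a, b] = fst.loc[b, a] = value
            if permutations:
                pv = fst_permutation_test(
                    table, a, b, n_perm=n_perm,
                    seed=int(rng.integers(2**31 - 1)),
                )
                pmat.loc[a, b] = pmat.loc[b, a] = pv
    if permutations:
        np.fill_diagonal(pmat.values, 0.0)
    return FstMatrix(pops, fst, pmat, n_perm if permutations else 0, seed)


def lower_quartile_affinity(fst_row: pd.Series):
    """Populations whose F_ST to the target falls in the lower quartile of
    the *range*: F_ST <= min + 0.25 (max - min)."""
    row = pd.Series(fst_row, dtype=float)
    if len(row) < 4:
        raise InputError("need at least 4 populations")
    lo, hi = row.min(), row.max()
    if hi == lo:
        warnings.warn("constant F_ST row: all populations selected")
        return set(row.index)
    threshold = lo + 0.25 * (hi - lo)
    return set(row.index[row <= threshold])


def mann_whitney_u(group_a, group_b, alternative="two-sided"):
    """Mann-Whitney U test of two F_ST samples.

    Exact enumeration when n_A + n_B <= 12 and there are no ties, else the
    normal approximation with tie and continuity corrections.  Returns
    ``(U, p)`` with U the statistic of ``group_a``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
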