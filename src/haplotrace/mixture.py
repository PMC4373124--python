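"""Simplex-constrained least-squares admixture decomposition.

The target haplogroup profile b (e.g. the pooled Malagasy) is decomposed
over candidate source profiles (columns of A: Indonesian populations plus a
pooled African reference) by solving

    min ||A x - b||^2   subject to   sum(x) = 1,  x >= 0,

the least-squares-with-equalities-and-inequalities (lsei) formulation.
Uncertainty is quantified by a parametric bootstrap: every population's
counts are redrawn multinomially at its observed sample size and the
decomposition re-solved (5,000 replicates by default), yielding
box-plot-ready coefficient distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .diversity import FrequencyTable
from .errors import InputError

DEFAULT_BOOTSTRAP_REPS = 5000
_EQUALITY_WEIGHT = 1e6
_CONSTRAINT_TOL = 1e-9
_KKT_TOL = 1e-7


@dataclass
class SourceProfileMatrix:
    """Haplogroup x source frequency matrix; columns sum to 1."""

    A: np.ndarray
    sources: list
    haplogroups: list

    def __post_init__(self):
        if not np.allclose(self.A.sum(axis=0), 1.0, atol=1e-9):
            raise InputError("source profile columns must sum to 1")
        if ((self.A < -1e-12) | (self.A > 1 + 1e-12)).any():
            raise InputError("profile entries must lie in [0, 1]")


@dataclass
class TargetProfile:
    """Haplogroup frequency vector of the target population."""

    b: np.ndarray
    n_target: int

    def __post_init__(self):
        if not np.isclose(self.b.sum(), 1.0, atol=1e-9):
            raise InputError("target profile must sum to 1")


@dataclass
class MixtureSolution:
    """Simplex-constrained coefficients with the residual and KKT status."""

    x: np.ndarray
    sources: list
    residual_norm: float
    degenerate: bool = False

    @property
    def objective(self) -> float:
        return self.residual_norm**2

    @property
    def active_bounds(self):
        return [s for s, v in zip(self.sources, self.x) if v <= _CONSTRAINT_TOL]

    def as_series(self) -> pd.Series:
        return pd.Series(self.x, index=self.sources)


def _pooled_frequencies(table: FrequencyTable):
    pooled = table.counts.sum(axis=0)
    return pooled / pooled.sum()


def build_profile_matrix(
    tables: FrequencyTable,
    target_pop: str,
    source_pops,
    african_reference: FrequencyTable | None = None,
    reference_label="African reference",
):
    """Assemble the source matrix A and target vector b on the haplogroup
    union (zero-filled), pooling the African reference by summing counts
    across its constituent populations before frequency conversion."""
    source_pops = list(source_pops)
    cols = {}
    freqs = tables.frequencies
    for p in source_pops:
        if p not in tables.populations:
            raise InputError(f"unknown source population {p!r}")
        cols[p] = freqs.loc[p]
    if target_pop not in tables.populations:
        raise InputError(f"unknown target population {target_pop!r}")
    target = freqs.loc[target_pop]
    if african_reference is not None:
        cols[reference_label] = _pooled_frequencies(african_reference)

    union = sorted(
        set(target.index)
        | {h for c in cols.values() for h in c.index}
    )
    if not union:
        raise InputError("empty haplogroup union")
    a = np.column_stack(
        [cols[s].reindex(union, fill_value=0.0).to_numpy() for s in cols]
    )
    b = target.reindex(union, fill_value=0.0).to_numpy()
    matrix = SourceProfileMatrix(A=a, sources=list(cols), haplogroups=union)
    profile = TargetProfile(b=b, n_target=int(tables.n[target_pop]))
    return matrix, profile


def _simplex_nnls(a, b):
    """Minimise ||a x - b|| over the probability simplex via an active-set
    non-negative solver on the equality-augmented system."""
    n_h, n_s = a.shape
    scale = _EQUALITY_WEIGHT * max(1.0, np.abs(a).max())
    a_aug = np.vstack([a, scale * np.ones((1, n_s))])
    b_aug = np.append(b, scale)
    x, _ = nnls(a_aug, b_aug)
    total = x.sum()
    if total <= 0:  # pragma: no cover - cannot happen for scale >> data
        x = np.full(n_s, 1.0 / n_s)
    else:
        x = x / total
    return x


def _kkt_satisfied(a, b, x, tol=_KKT_TOL):
    g = 2 * a.T @ (a @ x - b)
    support = x > _CONSTRAINT_TOL
    if not support.any():
        return False
    nu = g[support].mean()
    if np.abs(g[support] - nu).max() > max(tol, 1e-6 * (1 + abs(nu))):
        return False
    return bool((g[~support] >= nu - tol * (1 + abs(nu)) - 1e-6).all())


def solve_mixture(matrix: SourceProfileMatrix, target: TargetProfile) -> MixtureSolution:
    """Global minimiser of the simplex-constrained least-squares problem.

    Identical source columns are detected and the coefficient mass split
    equally among them (flagged ``degenerate``); general rank deficiency is
    flagged the same way with the minimal-norm representative returned.
    """
    a = np.asarray(matrix.A, dtype=float)
    b = np.asarray(target.b, dtype=float)
    n_s = a.shape[1]
    if n_s < 1:
        raise InputError("need at least one source")

    # group exactly-identical columns and solve on the unique set
    groups = []
    assigned = {}
    for j in range(n_s):
        for gi, g in enumerate(groups):
            if np.allclose(a[:, j], a[:, g[0]], atol=1e-12, rtol=0):
                g.append(j)
                assigned[j] = gi
                break
        else:
            assigned[j] = len(groups)
            groups.append([j])
    a_u = a[:, [g[0] for g in groups]]
    x_u = _simplex_nnls(a_u, b)
    x = np.zeros(n_s)
    for gi, g in enumerate(groups):
        for j in g:
            x[j] = x_u[gi] / len(g)

    degenerate = len(groups) < n_s or (
        np.linalg.matrix_rank(a_u) < min(a_u.shape)
    )
    residual = float(np.linalg.norm(a @ x - b))
    assert abs(x.sum() - 1.0) < 1e-9 and (x >= -1e-12).all()
    return MixtureSolution(
        x=np.clip(x, 0.0, None),
        sources=list(matrix.sources),
        residual_norm=residual,
        degenerate=degenerate,
    )


@dataclass
class BootstrapResult:
    """Bootstrap coefficient draws plus per-source summaries."""

    draws: pd.DataFrame  # n_rep x sources
    summaries: pd.DataFrame
    n_rep: int
    seed: int | None

    @property
    def median(self) -> pd.Series:
        return self.summaries["median"]


def bootstrap_mixture(
    tables: FrequencyTable,
    target_pop: str,
    source_pops,
    african_reference: FrequencyTable | None = None,
    n_rep=DEFAULT_BOOTSTRAP_REPS,
    seed=None,
    resample_target=True,
) -> BootstrapResult:
    """Parametric bootstrap of the mixture coefficients.

    Per replicate every population's counts (target, sources, and African
    reference constituents) are redrawn multinomially at the observed sample
    size, the profile matrix is rebuilt, and the decomposition re-solved.
    ``resample_target=False`` restricts resampling to the sources.
    """
    if n_rep < 1:
        raise InputError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    base_matrix, _ = build_profile_matrix(
        tables, target_pop, source_pops, african_reference
    )
    union = base_matrix.haplogroups

    def _vec(series):
        v = series.reindex(union, fill_value=0).to_numpy(float)
        return v, int(v.sum())

    source_counts = [_vec(tables.counts.loc[p]) for p in source_pops]
    target_counts, n_target = _vec(tables.counts.loc[target_pop])
    ref_counts = (
        [_vec(african_reference.counts.loc[p]) for p in african_reference.populations]
        if african_reference is not None
        else []
    )

    def _redraw(counts, n):
        return rng.multinomial(n, counts / counts.sum()).astype(float)

    rows = np.empty((n_rep, len(base_matrix.sources)))
    for r in range(n_rep):
        cols = [_redraw(c, n) for c, n in source_counts]
        if ref_counts:
            pooled = sum(_redraw(c, n) for c, n in ref_counts)
            cols.append(pooled)
        a = np.column_stack([c / c.sum() for c in cols])
        b_counts = (
            _redraw(target_counts, n_target) if resample_target else target_counts
        )
        rows[r] = _simplex_nnls(a, b_counts / b_counts.sum())
    draws = pd.DataFrame(rows, columns=base_matrix.sources)
    summaries = pd.DataFrame(
        {
            "mean": draws.mean(),
            "median": draws.median(),
            "q25": draws.quantile(0.25),
            "q75": draws.quantile(0.75),
            "p2.5": draws.quantile(0.025),
            "p97.5": draws.quantile(0.975),
        }
    )
    return BootstrapResult(draws=draws, summaries=summaries, n_rep=n_rep, seed=seed)
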