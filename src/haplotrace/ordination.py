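"""Nonmetric multidimensional scaling with Kruskal stress-1.

The configuration is found by iterative majorization (SMACOF-style Guttman
transforms) alternated with monotone regression: at each step disparities
d-hat are fitted to the configuration distances by pool-adjacent-violators
(primary approach to ties), and the configuration is updated by the Guttman
transform.  Stress-1,

    stress = sqrt( sum_{i<j} (dhat_ij - d_ij)^2 / sum_{i<j} d_ij^2 ),

is tracked every iteration; the iteration stops as soon as stress fails to
decrease, so the reported stress path is non-increasing by construction.
One start comes from classical (metric) scaling, the rest are random; the
best final stress wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .errors import InputError


def _validate_dissimilarities(d):
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InputError("dissimilarity matrix must be symmetric")
    if (d < 0).any():
        raise InputError("dissimilarities must be non-negative")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise InputError("diagonal must be zero")
    return 0.5 * (d + d.T)


def _fit_disparities(delta_vec, d_vec):
    """Monotone (PAVA) regression of configuration distances on the
    dissimilarity order; primary tie approach (ties in the dissimilarities
    are sub-ordered by the current distances, leaving them free)."""
    order = np.lexsort((d_vec, delta_vec))
    fitted = isotonic_regression(d_vec[order]).x
    dhat = np.empty_like(d_vec)
    dhat[order] = fitted
    return dhat


def kruskal_stress(coordinates, dissimilarities) -> float:
    """Kruskal stress-1 of a configuration, with PAVA-fitted disparities."""
    delta = _validate_dissimilarities(dissimilarities)
    x = np.asarray(coordinates, dtype=float)
    if x.shape[0] != delta.shape[0]:
        raise InputError("coordinate and dissimilarity shapes disagree")
    d = pdist(x)
    denom = (d**2).sum()
    if denom == 0:
        warnings.warn("degenerate configuration: all points coincide")
        return 0.0
    dhat = _fit_disparities(squareform(delta), d)
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def _classical_mds(delta, dim):
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


@dataclass
class Ordination:
    """NMDS solution: centered coordinates, final Kruskal stress-1, and the
    per-iteration stress path of the winning start."""

    coordinates: np.ndarray
    stress: float
    n_starts: int
    seed: int | None
    converged: bool
    stress_path: list = field(default_factory=list)


def _smacof_run(delta, x0, max_iter, tol):
    n = delta.shape[0]
    delta_vec = squareform(delta)
    x = x0 - x0.mean(axis=0)
    d = pdist(x)
    if (d**2).sum() == 0:
        return x, np.inf, [np.inf], False
    dhat = _fit_disparities(delta_vec, d)
    stress = np.sqrt(((dhat - d) ** 2).sum() / (d**2).sum())
    path = [float(stress)]
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = (b @ x) / n
        d_new = pdist(x_new)
        if (d_new**2).sum() == 0:
            break
        dhat_new = _fit_disparities(delta_vec, d_new)
        stress_new = np.sqrt(((dhat_new - d_new) ** 2).sum() / (d_new**2).sum())
        if stress_new > stress - 1e-15:
            converged = True
            break
        x, d, dhat = x_new, d_new, dhat_new
        path.append(float(stress_new))
        if stress - stress_new < tol:
            stress = stress_new
            converged = True
            break
        stress = stress_new
    x = x - x.mean(axis=0)
    return x, float(stress), path, converged


def nmds(
    dissimilarities,
    dim=2,
    n_starts=20,
    max_iter=500,
    tol=1e-6,
    seed=None,
) -> Ordination:
    """Nonmetric MDS of a dissimilarity matrix (e.g. clipped pairwise F_ST).

    One start from classical metric scaling plus ``n_starts - 1`` random
    Gaussian starts; the lowest-stress solution is returned.  A run that
    exhausts ``max_iter`` without the stress change dropping below ``tol``
    is flagged ``converged=False`` (best iterate still returned).
    """
    delta = _validate_dissimilarities(dissimilarities)
    n = delta.shape[0]
    if n_starts < 1:
        raise InputError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    scale = delta[delta > 0].mean() if (delta > 0).any() else 1.0
    inits = [_classical_mds(delta, dim)]
    inits += [rng.normal(scale=scale, size=(n, dim)) for _ in range(n_starts - 1)]

    best = None
    for x0 in inits:
        x, stress, path, conv = _smacof_run(delta, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, path, conv)
    x, stress, path, conv = best
    if not conv:
        warnings.warn("NMDS did not converge; best iterate returned")
    return Ordination(
        coordinates=x,
        stress=stress,
        n_starts=n_starts,
        seed=seed,
        converged=conv,
        stress_path=path,
    )
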