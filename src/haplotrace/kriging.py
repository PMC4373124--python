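"""Ordinary kriging of genetic-distance values over geographic coordinates.

Coordinates are treated as planar decimal degrees (adequate at archipelago
scale).  The variogram is linear, gamma(h) = slope * h with no nugget, so
the interpolator is exact at data points and the weights at every node sum
to 1 (the ordinary-kriging unbiasedness constraint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist

from .errors import InputError


@dataclass
class GridSpec:
    """Interpolation grid: nx x ny nodes over explicit bounds, or the
    bounding box of the data padded by ``pad`` (fraction of each span)."""

    nx: int = 100
    ny: int = 100
    bounds: tuple | None = None  # (xmin, xmax, ymin, ymax)
    pad: float = 0.05


@dataclass
class GeoSurface:
    """Interpolated surface: grid[iy, ix] over x_coords/y_coords axes."""

    grid: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    variogram: dict


def _kriging_system(xy, slope):
    n = xy.shape[0]
    gamma = slope * cdist(xy, xy)
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = gamma
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    lhs[n, n] = 0.0
    return lhs


def kriging_weights(points_xy, values_xy_targets, slope=1.0):
    """Ordinary-kriging weight vectors (one row per target point)."""
    xy = np.asarray(points_xy, dtype=float)
    targets = np.atleast_2d(np.asarray(values_xy_targets, dtype=float))
    lhs = _kriging_system(xy, slope)
    try:
        factor = lu_factor(lhs)
    except Exception as exc:  # pragma: no cover - scipy raises LinAlgError
        raise InputError(f"singular kriging system: {exc}") from exc
    n = xy.shape[0]
    rhs = np.empty((n + 1, targets.shape[0]))
    rhs[:n] = slope * cdist(xy, targets).reshape(n, -1)
    rhs[n] = 1.0
    sol = lu_solve(factor, rhs)
    return sol[:n].T  # weights; row per target


def krige_surface(points, grid_spec: GridSpec | None = None, slope=1.0) -> GeoSurface:
    """Interpolate (lon, lat, value) points onto a regular grid by ordinary
    kriging with a linear variogram.

    Raises :class:`InputError` for fewer than two distinct locations, for
    duplicate coordinates carrying different values, or for a singular
    kriging system (coincident points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError("points must be (lon, lat, value) triples")
    if slope <= 0:
        raise InputError("variogram slope must be positive")

    # collapse exact duplicates; conflicting duplicates are an error
    seen = {}
    for lon, lat, val in pts:
        key = (lon, lat)
        if key in seen and seen[key] != val:
            raise InputError(
                f"duplicate coordinates {key} with different values "
                f"({seen[key]} vs {val})"
            )
        seen[key] = val
    xy = np.array([k for k in seen], dtype=float)
    z = np.array([seen[k] for k in seen], dtype=float)
    if xy.shape[0] < 2:
        raise InputError("need at least 2 non-coincident points")

    spec = grid_spec or GridSpec()
    if spec.bounds is not None:
        xmin, xmax, ymin, ymax = spec.bounds
    else:
        xmin, xmax = xy[:, 0].min(), xy[:, 0].max()
        ymin, ymax = xy[:, 1].min(), xy[:, 1].max()
        px = spec.pad * (xmax - xmin or 1.0)
        py = spec.pad * (ymax - ymin or 1.0)
        xmin, xmax, ymin, ymax = xmin - px, xmax + px, ymin - py, ymax + py
    x_axis = np.linspace(xmin, xmax, spec.nx)
    y_axis = np.linspace(ymin, ymax, spec.ny)
    gx, gy = np.meshgrid(x_axis, y_axis)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    lhs = _kriging_system(xy, slope)
    if abs(np.linalg.det(lhs)) < 1e-300:
        raise InputError(f"singular kriging system; coincident points among {xy.tolist()}")
    factor = lu_factor(lhs)
    n = xy.shape[0]
    rhs = np.empty((n + 1, nodes.shape[0]))
    rhs[:n] = slope * cdist(xy, nodes)
    rhs[n] = 1.0
    sol = lu_solve(factor, rhs)
    values = sol[:n].T @ z
    if not np.isfinite(values).all():
        raise InputError("non-finite kriging output")
    return GeoSurface(
        grid=values.reshape(spec.ny, spec.nx),
        x_coords=x_axis,
        y_coords=y_axis,
        variogram={"model": "linear", "slope": slope, "nugget": 0.0},
    )
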