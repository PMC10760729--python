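"""Weighted kernel density surfaces with the quartic (biweight) kernel.

The planar quartic kernel with bandwidth (search radius) h puts, for each
point with weight w, a density contribution at distance d of

    w * (3 / (pi h^2)) * (1 - (d/h)^2)^2      for d < h, else 0.

The kernel integrates to 1 over the plane, so the raster integral equals
the total weight whenever every point's support disc lies inside the grid
(up to discretisation error).  No boundary correction is applied: mass of
points near the grid edge falls partly outside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .city import CityBundle
from .raster import GridRaster

__all__ = [
    "KernelSpec",
    "QuarticKernelDensity",
    "kernel_density",
    "density_for_beds",
    "density_for_population",
    "default_bandwidth",
]


@dataclass(frozen=True)
class KernelSpec:
    """Bandwidth h (km) of the quartic kernel; support radius equals h."""

    bandwidth_h_km: float
    kernel: str = "quartic"

    def __post_init__(self) -> None:
        if self.bandwidth_h_km <= 0:
            raise ValueError("bandwidth must be positive")
        if self.kernel != "quartic":
            raise ValueError("only the quartic kernel is supported")


def default_bandwidth(grid: GridRaster) -> float:
    """One-sixth of the shorter grid extent — a visible-smoothing default."""
    return min(grid.n_cols, grid.n_rows) * grid.cell_size_km / 6.0


class QuarticKernelDensity(BaseEstimator):
    """Weighted planar KDE with the quartic kernel, evaluated on a grid.

    Parameters
    ----------
    bandwidth : float
        Search radius h in km.

    Attributes
    ----------
    points_ : ndarray of shape (n, 2)
        Fitted point coordinates (km).
    weights_ : ndarray of shape (n,)
        Fitted non-negative weights.
    """

    def __init__(self, bandwidth: float = 5.0):
        self.bandwidth = bandwidth

    def fit(self, X, sample_weight=None):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_points, 2)")
        if not np.all(np.isfinite(X)):
            raise ValueError("point coordinates must be finite")
        w = (np.ones(len(X)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if w.shape != (len(X),):
            raise ValueError("sample_weight length mismatch")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and >= 0")
        self.points_ = X
        self.weights_ = w
        return self

    def evaluate(self, grid: GridRaster) -> GridRaster:
        """Density (weight units per km^2) at every cell centre of ``grid``."""
        h = float(self.bandwidth)
        norm = 3.0 / (np.pi * h * h)
        xs, ys = grid.centers()
        out = np.zeros((grid.n_rows, grid.n_cols))
        cell = grid.cell_size_km
        for (px, py), w in zip(self.points_, self.weights_):
            if w == 0:
                continue
            # bounding-box slice: cells possibly within the support disc
            c0 = max(int(np.floor((px - h - grid.x0_km) / cell)) - 1, 0)
            c1 = min(int(np.ceil((px + h - grid.x0_km) / cell)) + 1, grid.n_cols)
            r0 = max(int(np.floor((py - h - grid.y0_km) / cell)) - 1, 0)
            r1 = min(int(np.ceil((py + h - grid.y0_km) / cell)) + 1, grid.n_rows)
            if c0 >= c1 or r0 >= r1:
                continue
            dx = xs[c0:c1] - px
            dy = ys[r0:r1] - py
            d2 = dy[:, None] ** 2 + dx[None, :] ** 2
            u = d2 / (h * h)
            k = np.where(u < 1.0, (1.0 - u) ** 2, 0.0)
            out[r0:r1, c0:c1] += w * norm * k
        return grid.copy_with(out)


def kernel_density(points, spec: KernelSpec, grid: GridRaster) -> GridRaster:
    """Functional form: ``points`` is a list of (x, y, weight) triples."""
    pts = np.array([(p[0], p[1]) for p in points], dtype=float).reshape(-1, 2)
    w = np.array([p[2] for p in points], dtype=float)
    est = QuarticKernelDensity(bandwidth=spec.bandwidth_h_km)
    if len(pts) == 0:
        return grid.copy_with(np.zeros((grid.n_rows, grid.n_cols)))
    return est.fit(pts, sample_weight=w).evaluate(grid)


def density_for_beds(bundle: CityBundle, spec: KernelSpec,
                     grid: GridRaster) -> GridRaster:
    """Hospital-bed density surface (supply side of the overlay)."""
    return kernel_density(
        [(f.x_km, f.y_km, f.beds) for f in bundle.facilities], spec, grid
    )


def density_for_population(bundle: CityBundle, spec: KernelSpec,
                           grid: GridRaster) -> GridRaster:
    """Population density surface (demand side of the overlay)."""
    return kernel_density(
        [(d.x_km, d.y_km, d.population) for d in bundle.demands], spec, grid
    )
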