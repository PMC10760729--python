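"""Fuzzy membership scaling and fuzzy-overlay combination of rasters.

Raster values are rescaled to memberships mu in [0, 1] with a clamped
linear function, then combined cellwise.  The AND operator is the
cellwise minimum: a cell scores high only if *every* input layer scores
high, which is what "well served" means when the layers are supply
(bed density) and demand (population density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = [
    "FuzzyLayer",
    "fuzzy_linear",
    "fuzzy_combine",
    "suitability_map",
    "underserved_mask",
]

_OPS = ("AND", "OR", "PRODUCT", "SUM", "GAMMA")


class FuzzyLayer(GridRaster):
    """A GridRaster whose values are memberships in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


def _as_layer(grid: GridRaster, values: np.ndarray) -> FuzzyLayer:
    return FuzzyLayer(grid.x0_km, grid.y0_km, grid.cell_size_km, values)


def fuzzy_linear(raster: GridRaster, lo: float, hi: float) -> FuzzyLayer:
    """Clamped linear membership: mu = clip((x - lo) / (hi - lo), 0, 1).

    ``hi < lo`` gives a decreasing membership (high raw value -> mu 0).
    """
    if hi == lo:
        raise ValueError("lo and hi must differ")
    mu = np.clip((raster.values - lo) / (hi - lo), 0.0, 1.0)
    return _as_layer(raster, mu)


def fuzzy_combine(layers, op: str, gamma: float | None = None) -> FuzzyLayer:
    """Cellwise overlay of >= 2 same-geometry layers.

    AND = min, OR = max, PRODUCT = prod(mu_k), SUM = 1 - prod(1 - mu_k),
    GAMMA = SUM^gamma * PRODUCT^(1-gamma) with gamma in [0, 1].
    """
    op = op.upper()
    if op not in _OPS:
        raise ValueError(f"unknown operator {op!r}")
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    base = layers[0]
    for lay in layers[1:]:
        if not base.same_geometry(lay):
            raise ValueError("layer geometry mismatch")
    stack = np.stack([lay.values for lay in layers])
    if op == "AND":
        out = stack.min(axis=0)
    elif op == "OR":
        out = stack.max(axis=0)
    elif op == "PRODUCT":
        out = stack.prod(axis=0)
    elif op == "SUM":
        out = 1.0 - (1.0 - stack).prod(axis=0)
    else:  # GAMMA
        if gamma is None:
            raise ValueError("gamma required for the GAMMA operator")
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        fsum = 1.0 - (1.0 - stack).prod(axis=0)
        fprod = stack.prod(axis=0)
        out = fsum**gamma * fprod ** (1.0 - gamma)
    return _as_layer(base, out)


def suitability_map(
    bed_density: GridRaster,
    pop_density: GridRaster,
    anchors_pct: tuple[float, float] = (5.0, 95.0),
    bed_anchors: tuple[float, float] | None = None,
    pop_anchors: tuple[float, float] | None = None,
) -> FuzzyLayer:
    """Provider-to-population suitability: AND of the two memberships.

    High output marks cells that are near BOTH high bed density and high
    population density — well-served locations; low output flags cells
    where added capacity is worth considering (read alongside population:
    unpopulated cells also score low).

    Anchors default to each raster's 5th/95th percentile, robust to the
    long upper tails KDE surfaces have.
    """
    if not bed_density.same_geometry(pop_density):
        raise ValueError("raster geometry mismatch")

    def anchors(raster, override):
        if override is not None:
            return override
        lo, hi = np.percentile(raster.values, anchors_pct)
        if hi == lo:  # flat raster: degenerate, all-or-nothing membership
            hi = lo + 1.0
        return float(lo), float(hi)

    blo, bhi = anchors(bed_density, bed_anchors)
    plo, phi = anchors(pop_density, pop_anchors)
    mu_beds = fuzzy_linear(bed_density, blo, bhi)
    mu_pop = fuzzy_linear(pop_density, plo, phi)
    return fuzzy_combine([mu_beds, mu_pop], "AND")


@dataclass(frozen=True)
class UnderservedResult:
    mask: np.ndarray  # boolean, True = flagged under-served
    n_flagged: int
    fraction: float


def underserved_mask(suitability: FuzzyLayer,
                     threshold: float = 0.33) -> UnderservedResult:
    """Cells with membership strictly below ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = suitability.values < threshold
    n = int(mask.sum())
    return UnderservedResult(mask=mask, n_flagged=n, fraction=n / mask.size)
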