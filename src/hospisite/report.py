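"""Cumulative coverage tables and end-to-end pipeline orchestration.

The coverage table mirrors the standard accessibility report: one row per
facility, one column per impedance cut-off, entry = number of that
facility's allocated demand districts reachable within the cut-off
(cumulative, hence nondecreasing along the row), plus per-facility shares
of allocated demand and a cumulative-percentage total row.  Percentages
are rounded half-up to two decimals.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import mc_p_median_optimize, Allocation, OptimizedAllocation
from .city import CityBundle, generate_city, read_city, write_city
from .density import KernelSpec, default_bandwidth, density_for_beds, density_for_population
from .fuzzy import suitability_map, underserved_mask
from .network import ODMatrix, od_matrix
from .raster import make_grid, write_ascii_grid

__all__ = [
    "CoverageTable",
    "coverage_table",
    "facility_shares",
    "table_from_count_rows",
    "default_cutoffs",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def default_cutoffs(start: float = 0.5, stop: float = 6.0,
                    step: float = 0.5) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + k * step, 10) for k in range(n)]


@dataclass
class CoverageTable:
    facility_ids: list[int]
    cutoffs_h: list[float]
    counts: dict[int, list[int]]  # facility -> cumulative counts per cutoff
    allocated_count: dict[int, int]
    share_pct: dict[int, float]
    total_counts: list[int]
    cumulative_pct: list[float]

    @property
    def total_allocated(self) -> int:
        return sum(self.allocated_count.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.facility_ids:
            rows.append(
                [f, self.allocated_count[f], self.share_pct[f], *self.counts[f]]
            )
        cols = ["facility_id", "allocated", "share_pct",
                *[f"within_{c}h" for c in self.cutoffs_h]]
        df = pd.DataFrame(rows, columns=cols)
        total = ["Total", self.total_allocated, 100.0, *self.cumulative_pct]
        df.loc[len(df)] = total
        return df

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def coverage_table(allocation: Allocation, od: ODMatrix,
                   cutoffs_h: list[float] | None = None) -> CoverageTable:
    """Per-facility cumulative reachable-demand counts across cut-offs.

    Only allocated demands appear (unallocated/inaccessible demands are
    reported separately in the run manifest), so the cumulative percentage
    reaches exactly 100.0 at the last cut-off.
    """
    if cutoffs_h is None:
        cutoffs_h = default_cutoffs()
    cutoffs_h = sorted(cutoffs_h)
    di = {d: i for i, d in enumerate(od.demand_ids)}
    fi = {f: j for j, f in enumerate(od.facility_ids)}

    facility_ids = sorted(allocation.chosen_sites)
    counts = {f: [0] * len(cutoffs_h) for f in facility_ids}
    allocated = {f: 0 for f in facility_ids}
    for d, f in allocation.assignment.items():
        if f is None:
            continue
        if d not in di or f not in fi:
            raise ValueError(f"assignment ({d} -> {f}) missing from the OD matrix")
        t = od.times[di[d], fi[f]]
        allocated[f] += 1
        for k, cut in enumerate(cutoffs_h):
            if t <= cut:
                counts[f][k] += 1

    total_allocated = sum(allocated.values())
    total_counts = [sum(counts[f][k] for f in facility_ids)
                    for k in range(len(cutoffs_h))]
    if total_allocated:
        share = {f: round_half_up(100.0 * allocated[f] / total_allocated)
                 for f in facility_ids}
        cum = [round_half_up(100.0 * t / total_allocated) for t in total_counts]
    else:
        share = {f: 0.0 for f in facility_ids}
        cum = [0.0] * len(cutoffs_h)
    return CoverageTable(
        facility_ids=facility_ids, cutoffs_h=cutoffs_h, counts=counts,
        allocated_count=allocated, share_pct=share,
        total_counts=total_counts, cumulative_pct=cum,
    )


def facility_shares(allocation: Allocation) -> list[tuple[int, int, float]]:
    """(facility_id, allocated count, share %) sorted by facility id."""
    if not allocation.assignment:
        raise ValueError("empty allocation")
    counts: dict[int, int] = {f: 0 for f in sorted(allocation.chosen_sites)}
    for f in allocation.assignment.values():
        if f is not None:
            counts[f] = counts.get(f, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("allocation has no allocated demand")
    return [(f, c, round_half_up(100.0 * c / total))
            for f, c in sorted(counts.items())]


def table_from_count_rows(count_rows: dict[int, list[int]],
                          cutoffs_h: list[float]) -> CoverageTable:
    """Recompute a coverage table from per-facility cumulative count rows.

    Useful for validating a published report: the minimal allocation
    consistent with the rows is reconstructed (each demand first reachable
    at cut-off t is assigned to its facility at travel time t) and pushed
    through :func:`coverage_table`, so shares and cumulative percentages
    are recomputed from scratch rather than copied.
    """
    cutoffs_h = list(cutoffs_h)
    n_cut = len(cutoffs_h)
    facility_ids = sorted(count_rows)
    demand_ids: list[int] = []
    assignment: dict[int, int | None] = {}
    times_rows: list[list[float]] = []
    next_d = 0
    for f in facility_ids:
        row = count_rows[f]
        if len(row) != n_cut:
            raise ValueError(f"facility {f}: expected {n_cut} counts")
        prev = 0
        for k, c in enumerate(row):
            if c < prev:
                raise ValueError(f"facility {f}: counts must be nondecreasing")
            for _ in range(c - prev):
                demand_ids.append(next_d)
                assignment[next_d] = f
                t_row = [float("inf")] * len(facility_ids)
                t_row[facility_ids.index(f)] = cutoffs_h[k]
                times_rows.append(t_row)
                next_d += 1
            prev = c
    od = ODMatrix(demand_ids=demand_ids, facility_ids=facility_ids,
                  times=np.array(times_rows).reshape(len(demand_ids),
                                                     len(facility_ids)))
    alloc = Allocation(chosen_sites=tuple(facility_ids), assignment=assignment,
                       objective=float(len(demand_ids)),
                       cutoff_h=cutoffs_h[-1], kind="mclp")
    return coverage_table(alloc, od, cutoffs_h)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything one run needs; ``city_path`` loads instead of generating."""

    seed: int = 0
    city_path: str | None = None
    generator: dict = field(default_factory=dict)  # kwargs for generate_city
    cell_size_km: float = 0.5
    bandwidth_km: float | None = None  # None -> one-sixth of shorter extent
    underserved_threshold: float = 0.33
    p: int | None = None  # None -> all facilities
    cutoff_h: float = 6.0
    cutoffs_h: list[float] = field(default_factory=default_cutoffs)
    pmedian_method: str = "auto"
    mclp_method: str = "exact"
    unit_demand_weights: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run city -> densities -> suitability -> OD -> MC-P-Median -> report.

    Writes all artefacts plus a JSON manifest (parameters, seed, version,
    stage outputs) under ``out_dir`` and returns that directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in vars(config).items()},
                      "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            manifest["stages"][name] = {}
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name].update(status="failed", error=str(exc))
                _write_manifest(manifest, out, partial=True)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name].update(
                status="ok", seconds=round(time.perf_counter() - t0, 4))
            logger.info("stage %s done in %.3fs", name,
                        time.perf_counter() - t0)
            return result
        return deco

    @stage("city")
    def city() -> CityBundle:
        if config.city_path:
            return read_city(config.city_path)
        bundle = generate_city(seed=config.seed, **config.generator)
        write_city(bundle, out / "city", csv_tables=True)
        return bundle

    @stage("density")
    def rasters():
        xs = [n[1] for n in city.network.nodes]
        ys = [n[2] for n in city.network.nodes]
        pad = config.cell_size_km
        grid = make_grid((min(xs) - pad, min(ys) - pad,
                          max(xs) + pad, max(ys) + pad), config.cell_size_km)
        bw = config.bandwidth_km or default_bandwidth(grid)
        spec = KernelSpec(bandwidth_h_km=bw)
        beds = density_for_beds(city, spec, grid)
        pop = density_for_population(city, spec, grid)
        write_ascii_grid(beds, out / "bed_density.asc")
        write_ascii_grid(pop, out / "pop_density.asc")
        manifest["stages"]["density"]["bandwidth_km"] = bw
        return beds, pop

    @stage("suitability")
    def suit():
        beds, pop = rasters
        layer = suitability_map(beds, pop)
        write_ascii_grid(layer, out / "suitability.asc")
        res = underserved_mask(layer, config.underserved_threshold)
        manifest["underserved"] = {
            "threshold": config.underserved_threshold,
            "n_flagged": res.n_flagged,
            "fraction": round(res.fraction, 6),
        }
        return layer

    @stage("odmatrix")
    def od() -> ODMatrix:
        m = od_matrix(city.network, city.demands, city.facilities,
                      cutoff_h=config.cutoff_h)
        m.write_csv(out / "od_matrix.csv")
        return m

    @stage("allocate")
    def optimized() -> OptimizedAllocation:
        p = config.p if config.p is not None else len(city.facilities)
        if not 1 <= p <= len(city.facilities):
            raise ValueError(f"p={p} out of range for "
                             f"{len(city.facilities)} candidate facilities")
        weights = {d.demand_id: (1.0 if config.unit_demand_weights
                                 else float(d.population))
                   for d in city.demands}
        return mc_p_median_optimize(
            od, weights, p=p, cutoff_h=config.cutoff_h,
            pmedian_method=config.pmedian_method,
            mclp_method=config.mclp_method, seed=config.seed,
        )

    @stage("report")
    def table() -> CoverageTable:
        tbl = coverage_table(optimized.final, od, config.cutoffs_h)
        tbl.write_csv(out / "coverage.csv")
        _write_allocation_csv(optimized.final, od, out / "allocation_final.csv")
        _write_allocation_csv(optimized.p_median, od, out / "allocation_pmedian.csv")
        with open(out / "audit_log.json", "w") as fh:
            json.dump(optimized.audit_log, fh, indent=1, sort_keys=True)
        return tbl

    manifest["results"] = {
        "n_demands": len(city.demands),
        "n_facilities": len(city.facilities),
        "chosen_sites": list(optimized.final.chosen_sites),
        "allocated": optimized.final.allocated_count,
        "inaccessible": len(optimized.inaccessible),
        "pmedian_objective": optimized.p_median.objective,
        "covered_weight": optimized.final.objective,
        "cumulative_pct": table.cumulative_pct,
        "cutoffs_h": table.cutoffs_h,
    }
    _write_manifest(manifest, out)
    return out


def _write_allocation_csv(alloc: Allocation, od: ODMatrix, path: Path) -> None:
    di = {d: i for i, d in enumerate(od.demand_ids)}
    fi = {f: j for j, f in enumerate(od.facility_ids)}
    rows = []
    for d in od.demand_ids:
        f = alloc.assignment.get(d)
        if f is None:
            rows.append((d, "", "", "unallocated"))
        else:
            rows.append((d, f, od.times[di[d], fi[f]], "allocated"))
    pd.DataFrame(rows, columns=["demand_id", "facility_id", "hours", "status"]
                 ).to_csv(path, index=False)


def _write_manifest(manifest: dict, out: Path, partial: bool = False) -> None:
    manifest["partial"] = partial
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
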