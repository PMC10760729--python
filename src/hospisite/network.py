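"""Shortest-path travel times and demand x facility OD matrices.

Impedance is travel time in hours along the road network
(edge length_km / speed_kmh), computed with Dijkstra's algorithm from
each facility's snapped node.  Off-network access time from a point to
its snapped node is treated as zero.  Pairs with no connecting path are
UNREACHABLE (stored as +inf); supplying a cut-off additionally masks
finite entries above it without altering them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .city import CityBundle, DemandPoint, FacilitySite, RoadNetwork

__all__ = ["ODMatrix", "UNREACHABLE", "od_matrix", "reachable_demands"]

UNREACHABLE = float("inf")


@dataclass
class ODMatrix:
    """Travel-time matrix: rows = demand points, cols = facilities (hours)."""

    demand_ids: list[int]
    facility_ids: list[int]
    times: np.ndarray = field(repr=False)  # raw shortest-path hours, inf = no path
    cutoff_h: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.demand_ids), len(self.facility_ids)):
            raise ValueError("times shape mismatch")
        finite = self.times[np.isfinite(self.times)]
        if np.any(finite < 0):
            raise ValueError("travel times must be >= 0")

    def effective(self) -> np.ndarray:
        """Times with entries above the cut-off masked to UNREACHABLE."""
        if self.cutoff_h is None:
            return self.times
        return np.where(self.times <= self.cutoff_h, self.times, UNREACHABLE)

    def with_cutoff(self, cutoff_h: float | None) -> "ODMatrix":
        return ODMatrix(self.demand_ids, self.facility_ids, self.times, cutoff_h)

    def row(self, demand_id: int) -> np.ndarray:
        return self.effective()[self.demand_ids.index(demand_id)]

    def col(self, facility_id: int) -> np.ndarray:
        if facility_id not in self.facility_ids:
            raise KeyError(f"unknown facility {facility_id}")
        return self.effective()[:, self.facility_ids.index(facility_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (demand_id, facility_id, hours); inf kept as inf."""
        rows = []
        eff = self.effective()
        for i, d in enumerate(self.demand_ids):
            for j, f in enumerate(self.facility_ids):
                rows.append((d, f, eff[i, j]))
        return pd.DataFrame(rows, columns=["demand_id", "facility_id", "hours"])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path, cutoff_h: float | None = None) -> "ODMatrix":
        df = pd.read_csv(path)
        demand_ids = sorted(df["demand_id"].unique().tolist())
        facility_ids = sorted(df["facility_id"].unique().tolist())
        times = np.full((len(demand_ids), len(facility_ids)), UNREACHABLE)
        di = {d: i for i, d in enumerate(demand_ids)}
        fi = {f: j for j, f in enumerate(facility_ids)}
        for _, r in df.iterrows():
            times[di[r["demand_id"]], fi[r["facility_id"]]] = r["hours"]
        return cls(demand_ids, facility_ids, times, cutoff_h)


def od_matrix(
    network: RoadNetwork,
    demands: list[DemandPoint],
    facilities: list[FacilitySite],
    cutoff_h: float | None = None,
) -> ODMatrix:
    """Shortest-path travel times between snapped demand and facility nodes.

    Runs one Dijkstra per facility (facilities are few, demands many).
    Result is independent of evaluation order; entries above ``cutoff_h``
    are masked via :meth:`ODMatrix.effective` when a cut-off is given.
    """
    node_ids = {n[0] for n in network.nodes}
    for d in demands:
        if d.snapped_node not in node_ids:
            raise ValueError(f"demand {d.demand_id} not snapped to the network")
    for f in facilities:
        if f.snapped_node not in node_ids:
            raise ValueError(f"facility {f.facility_id} not snapped to the network")

    g = network.to_networkx()
    times = np.full((len(demands), len(facilities)), UNREACHABLE)
    for j, f in enumerate(facilities):
        dist = nx.single_source_dijkstra_path_length(
            g, f.snapped_node, weight="travel_time_h"
        )
        for i, d in enumerate(demands):
            t = dist.get(d.snapped_node)
            if t is not None:
                times[i, j] = t
    return ODMatrix(
        demand_ids=[d.demand_id for d in demands],
        facility_ids=[f.facility_id for f in facilities],
        times=times,
        cutoff_h=cutoff_h,
    )


def reachable_demands(od: ODMatrix, facility_id: int, cutoff_h: float) -> set[int]:
    """Demand ids within ``cutoff_h`` hours of the given facility."""
    if cutoff_h < 0:
        raise ValueError("cutoff must be >= 0")
    if facility_id not in od.facility_ids:
        raise KeyError(f"unknown facility {facility_id}")
    col = od.times[:, od.facility_ids.index(facility_id)]
    return {d for d, t in zip(od.demand_ids, col) if t <= cutoff_h}
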