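"""Synthetic city generation and GeoJSON/CSV I/O.

A "city" here is the minimal geodata a network accessibility analysis
needs: a connected road network (nodes in planar km, edges carrying
length and design speed), population districts reduced to weighted
demand points, and hospital sites with bed counts.  Defaults target the
scale of a large Middle-Eastern metropolis: ~110 districts, ~3.4 million
people, five hospitals whose capacities span 109-900 beds.

Coordinates are planar kilometres, not lon/lat; edge impedance is
``length_km / speed_kmh`` hours.  All generators are deterministic given
their seed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "RoadNetwork",
    "DemandPoint",
    "FacilitySite",
    "CityBundle",
    "CityParseError",
    "generate_road_network",
    "generate_districts",
    "generate_facilities",
    "generate_city",
    "write_city",
    "read_city",
    "snap_to_node",
]


class CityParseError(ValueError):
    """Raised when a city file is malformed; message names file and record."""


@dataclass(frozen=True)
class RoadNetwork:
    """Undirected road graph in planar km.

    nodes: list of (node_id, x_km, y_km); edges: list of
    (node_u, node_v, length_km, speed_kmh).  Edge travel time in hours is
    derived as length/speed.
    """

    nodes: list[tuple[int, float, float]]
    edges: list[tuple[int, int, float, float]]

    def __post_init__(self) -> None:
        ids = [n[0] for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        idset = set(ids)
        for u, v, length, speed in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if u not in idset or v not in idset:
                raise ValueError(f"edge ({u},{v}) references missing node")
            if not (length > 0 and speed > 0):
                raise ValueError(f"edge ({u},{v}) needs positive length and speed")

    @property
    def node_xy(self) -> dict[int, tuple[float, float]]:
        return {nid: (x, y) for nid, x, y in self.nodes}

    def travel_time_h(self, u: int, v: int, length: float, speed: float) -> float:
        return length / speed

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for nid, x, y in self.nodes:
            g.add_node(nid, x=x, y=y)
        for u, v, length, speed in self.edges:
            g.add_edge(u, v, length_km=length, speed_kmh=speed,
                       travel_time_h=length / speed)
        return g

    def is_connected(self) -> bool:
        if not self.nodes:
            return False
        adj: dict[int, list[int]] = {n[0]: [] for n in self.nodes}
        for u, v, *_ in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        start = self.nodes[0][0]
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.nodes)


@dataclass(frozen=True)
class DemandPoint:
    """A population district reduced to one weighted point."""

    demand_id: int
    x_km: float
    y_km: float
    population: int
    snapped_node: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")


@dataclass(frozen=True)
class FacilitySite:
    """A hospital site (existing or candidate) with a bed count."""

    facility_id: int
    x_km: float
    y_km: float
    beds: int
    status: str  # "existing" | "candidate"
    snapped_node: int

    def __post_init__(self) -> None:
        if self.beds < 0:
            raise ValueError("beds must be >= 0")
        if self.status not in ("existing", "candidate"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class CityBundle:
    network: RoadNetwork
    demands: list[DemandPoint]
    facilities: list[FacilitySite]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_ids = {n[0] for n in self.network.nodes}
        for d in self.demands:
            if d.snapped_node not in node_ids:
                raise ValueError(f"demand {d.demand_id} snapped to missing node")
        for f in self.facilities:
            if f.snapped_node not in node_ids:
                raise ValueError(f"facility {f.facility_id} snapped to missing node")
        did = [d.demand_id for d in self.demands]
        fid = [f.facility_id for f in self.facilities]
        if len(set(did)) != len(did) or len(set(fid)) != len(fid):
            raise ValueError("duplicate demand or facility ids")


def snap_to_node(network: RoadNetwork, x: float, y: float) -> int:
    """Nearest network node by Euclidean distance; ties break on lowest id."""
    best_id, best_d2 = None, math.inf
    for nid, nx_, ny_ in sorted(network.nodes):
        d2 = (nx_ - x) ** 2 + (ny_ - y) ** 2
        if d2 < best_d2 - 1e-15:
            best_id, best_d2 = nid, d2
    assert best_id is not None
    return best_id


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def generate_road_network(
    n_nodes: int,
    area_km: float = 40.0,
    mean_degree: float = 3.0,
    speed_kmh: float | tuple[float, float] = (20.0, 60.0),
    seed: int = 0,
) -> RoadNetwork:
    """Random connected planar-ish road network in an ``area_km`` square.

    Nodes are sampled uniformly; candidate edges come from the Delaunay
    triangulation (complete graph for n < 4); edges are kept shortest-first
    on top of a minimum spanning tree until the target mean degree is met,
    so the result is always connected.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if area_km <= 0:
        raise ValueError("area_km must be positive")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    lo_s, hi_s = (speed_kmh, speed_kmh) if np.isscalar(speed_kmh) else speed_kmh
    if lo_s <= 0 or hi_s <= 0:
        raise ValueError("speed_kmh must be positive")

    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, area_km, size=(n_nodes, 2))

    if n_nodes < 4:
        cand = {(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)}
    else:
        tri = Delaunay(xy)
        cand = set()
        for simplex in tri.simplices:
            for a in range(3):
                cand.add(_edge_key(int(simplex[a]), int(simplex[(a + 1) % 3])))

    def dist(e: tuple[int, int]) -> float:
        return float(np.hypot(*(xy[e[0]] - xy[e[1]])))

    # Kruskal MST over candidate edges keeps connectivity guaranteed
    # (Delaunay of distinct points is connected).
    parent = list(range(n_nodes))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ordered = sorted(cand, key=lambda e: (dist(e), e))
    mst: list[tuple[int, int]] = []
    for e in ordered:
        ra, rb = find(e[0]), find(e[1])
        if ra != rb:
            parent[ra] = rb
            mst.append(e)
    kept = set(mst)
    target_edges = max(n_nodes - 1, int(round(mean_degree * n_nodes / 2)))
    for e in ordered:
        if len(kept) >= min(target_edges, len(cand)):
            break
        kept.add(e)

    edges = []
    for u, v in sorted(kept):
        length = max(dist((u, v)), 1e-9)
        speed = float(lo_s) if lo_s == hi_s else float(rng.uniform(lo_s, hi_s))
        edges.append((u, v, length, speed))
    nodes = [(i, float(xy[i, 0]), float(xy[i, 1])) for i in range(n_nodes)]
    return RoadNetwork(nodes=nodes, edges=edges)


def generate_districts(
    network: RoadNetwork,
    n_districts: int = 110,
    total_population: int = 3_400_000,
    concentration: float = 5.0,
    center_bias: float = 0.6,
    seed: int = 0,
) -> list[DemandPoint]:
    """Weighted demand points with a centre-biased density gradient.

    Populations are Dirichlet(concentration) shares of ``total_population``;
    integer rounding residual goes to the largest district so the total is
    conserved exactly.  With probability ``center_bias`` a district falls in
    a Gaussian blob around the network centroid (denser downtown), else
    uniformly over the network's bounding box.  Each point snaps to its
    nearest node.
    """
    if n_districts < 1:
        raise ValueError("n_districts must be >= 1")
    if total_population <= 0:
        raise ValueError("total_population must be positive")
    if not network.nodes:
        raise ValueError("network has no nodes")
    rng = np.random.default_rng(seed)

    node_arr = np.array([[x, y] for _, x, y in network.nodes])
    cx, cy = node_arr.mean(axis=0)
    xmin, ymin = node_arr.min(axis=0)
    xmax, ymax = node_arr.max(axis=0)
    span = max(xmax - xmin, ymax - ymin, 1e-9)

    shares = rng.dirichlet(np.full(n_districts, concentration))
    pops = np.floor(shares * total_population).astype(int)
    pops[int(np.argmax(pops))] += total_population - int(pops.sum())

    tree = cKDTree(node_arr)
    node_ids = [nid for nid, _, _ in network.nodes]
    demands = []
    for i in range(n_districts):
        if rng.uniform() < center_bias:
            x = float(rng.normal(cx, span / 6))
            y = float(rng.normal(cy, span / 6))
            x = min(max(x, xmin), xmax)
            y = min(max(y, ymin), ymax)
        else:
            x = float(rng.uniform(xmin, xmax))
            y = float(rng.uniform(ymin, ymax))
        _, idx = tree.query([x, y])
        demands.append(
            DemandPoint(
                demand_id=i,
                x_km=x,
                y_km=y,
                population=int(pops[i]),
                snapped_node=node_ids[int(idx)],
            )
        )
    return demands


def generate_facilities(
    network: RoadNetwork,
    n_sites: int = 5,
    bed_range: tuple[int, int] = (109, 900),
    n_existing: int | None = None,
    seed: int = 0,
) -> list[FacilitySite]:
    """Hospital sites with bed counts sampled in ``bed_range`` (inclusive)."""
    if bed_range[0] > bed_range[1]:
        raise ValueError("bed_range inverted")
    if bed_range[0] < 0:
        raise ValueError("beds must be >= 0")
    if n_existing is None:
        n_existing = n_sites
    if n_existing > n_sites:
        raise ValueError("n_existing cannot exceed n_sites")
    if n_sites == 0:
        return []
    rng = np.random.default_rng(seed)
    node_arr = np.array([[x, y] for _, x, y in network.nodes])
    xmin, ymin = node_arr.min(axis=0)
    xmax, ymax = node_arr.max(axis=0)
    tree = cKDTree(node_arr)
    node_ids = [nid for nid, _, _ in network.nodes]

    sites = []
    for j in range(n_sites):
        x = float(rng.uniform(xmin, xmax))
        y = float(rng.uniform(ymin, ymax))
        beds = int(rng.integers(bed_range[0], bed_range[1] + 1))
        _, idx = tree.query([x, y])
        sites.append(
            FacilitySite(
                facility_id=j,
                x_km=x,
                y_km=y,
                beds=beds,
                status="existing" if j < n_existing else "candidate",
                snapped_node=node_ids[int(idx)],
            )
        )
    return sites


def generate_city(
    n_nodes: int = 300,
    area_km: float = 40.0,
    n_districts: int = 110,
    total_population: int = 3_400_000,
    n_facilities: int = 5,
    n_existing: int | None = None,
    bed_range: tuple[int, int] = (109, 900),
    mean_degree: float = 3.0,
    speed_kmh: float | tuple[float, float] = (20.0, 60.0),
    concentration: float = 5.0,
    center_bias: float = 0.6,
    n_remote: int = 0,
    remote_travel_h: float = 8.0,
    seed: int = 0,
) -> CityBundle:
    """One-call synthetic city at the default study scale.

    ``n_remote`` > 0 attaches a far chain of nodes behind a single edge
    whose travel time is ``remote_travel_h`` hours and relocates the last
    ``n_remote`` districts there, so exactly those districts lie beyond any
    cut-off below ``remote_travel_h`` — a controlled stand-in for the
    inaccessible periphery of a real city.
    """
    if n_remote >= n_districts:
        raise ValueError("n_remote must be less than n_districts")
    net = generate_road_network(n_nodes, area_km, mean_degree, speed_kmh, seed=seed)

    # districts and facilities are placed on the in-town network so the
    # remote chain attracts exactly the relocated districts and nothing else
    demands = generate_districts(
        net, n_districts, total_population, concentration, center_bias, seed=seed + 1
    )
    facilities = generate_facilities(
        net, n_facilities, bed_range, n_existing, seed=seed + 2
    )

    if n_remote > 0:
        nodes = list(net.nodes)
        edges = list(net.edges)
        next_id = max(n[0] for n in nodes) + 1
        # slow access road: travel time fixed regardless of nominal speed
        gate_speed = 10.0
        gate_len = remote_travel_h * gate_speed
        anchor = nodes[0][0]
        ax, ay = nodes[0][1], nodes[0][2]
        remote_ids = []
        prev = anchor
        for k in range(max(1, math.ceil(n_remote / 4))):
            rx, ry = ax + area_km * 3 + k * 1.0, ay + area_km * 3
            nodes.append((next_id, rx, ry))
            if prev == anchor:
                edges.append((anchor, next_id, gate_len, gate_speed))
            else:
                edges.append((prev, next_id, 0.5, 50.0))
            remote_ids.append(next_id)
            prev = next_id
            next_id += 1
        net = RoadNetwork(nodes=nodes, edges=edges)
        xy = net.node_xy
        moved = []
        for k, d in enumerate(demands[-n_remote:]):
            node = remote_ids[k % len(remote_ids)]
            x, y = xy[node]
            moved.append(
                DemandPoint(d.demand_id, x, y, d.population, snapped_node=node)
            )
        demands = demands[: n_districts - n_remote] + moved

    return CityBundle(
        network=net,
        demands=demands,
        facilities=facilities,
        seed=seed,
        params={
            "n_nodes": n_nodes,
            "area_km": area_km,
            "n_districts": n_districts,
            "total_population": total_population,
            "n_facilities": n_facilities,
            "bed_range": list(bed_range),
            "mean_degree": mean_degree,
            "n_remote": n_remote,
            "remote_travel_h": remote_travel_h,
        },
    )


# ---------------------------------------------------------------------------
# I/O: GeoJSON FeatureCollections + JSON metadata, optional CSV attribute dump


def _network_geojson(net: RoadNetwork) -> dict:
    feats = []
    for nid, x, y in net.nodes:
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"node_id": nid},
            }
        )
    xy = net.node_xy
    for u, v, length, speed in net.edges:
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(xy[u]), list(xy[v])],
                },
                "properties": {
                    "node_u": u,
                    "node_v": v,
                    "length_km": length,
                    "speed_kmh": speed,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def _points_geojson(items, kind: str) -> dict:
    feats = []
    for it in items:
        if kind == "demand":
            props = {
                "demand_id": it.demand_id,
                "population": it.population,
                "snapped_node": it.snapped_node,
            }
        else:
            props = {
                "facility_id": it.facility_id,
                "beds": it.beds,
                "status": it.status,
                "snapped_node": it.snapped_node,
            }
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [it.x_km, it.y_km]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_city(bundle: CityBundle, path: str | Path, csv_tables: bool = False) -> Path:
    """Write a city as a directory of GeoJSON files plus meta.json.

    Output is byte-deterministic for identical bundles (sorted keys, repr
    floats), so identical seeds give identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def dump(obj, name):
        with open(path / name, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1)
            fh.write("\n")

    dump(_network_geojson(bundle.network), "network.geojson")
    dump(_points_geojson(bundle.demands, "demand"), "demands.geojson")
    dump(_points_geojson(bundle.facilities, "facility"), "facilities.geojson")
    dump({"seed": bundle.seed, "params": bundle.params}, "meta.json")

    if csv_tables:
        with open(path / "demands.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["demand_id", "x_km", "y_km", "population", "snapped_node"])
            for d in bundle.demands:
                w.writerow([d.demand_id, d.x_km, d.y_km, d.population, d.snapped_node])
        with open(path / "facilities.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["facility_id", "x_km", "y_km", "beds", "status", "snapped_node"])
            for f in bundle.facilities:
                w.writerow([f.facility_id, f.x_km, f.y_km, f.beds, f.status,
                            f.snapped_node])
    return path


def read_city(path: str | Path) -> CityBundle:
    """Read a city directory written by :func:`write_city`.

    Malformed files raise :class:`CityParseError` naming the file and the
    offending record.
    """
    path = Path(path)

    def load(name):
        p = path / name
        if not p.exists():
            raise CityParseError(f"{p}: file missing")
        with open(p) as fh:
            try:
                return json.load(fh)
            except json.JSONDecodeError as exc:
                raise CityParseError(f"{p}: invalid JSON ({exc})") from exc

    netjson = load("network.geojson")
    nodes, edges = [], []
    for i, feat in enumerate(netjson.get("features", [])):
        props = feat.get("properties", {})
        geom = feat.get("geometry", {})
        if geom.get("type") == "Point":
            if "node_id" not in props:
                raise CityParseError(f"network.geojson: feature {i} missing node_id")
            x, y = geom["coordinates"]
            nodes.append((int(props["node_id"]), float(x), float(y)))
        elif geom.get("type") == "LineString":
            try:
                edges.append(
                    (int(props["node_u"]), int(props["node_v"]),
                     float(props["length_km"]), float(props["speed_kmh"]))
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise CityParseError(
                    f"network.geojson: edge feature {i} malformed ({exc})"
                ) from exc
    node_ids = {n[0] for n in nodes}
    for u, v, *_ in edges:
        if u not in node_ids or v not in node_ids:
            raise CityParseError(
                f"network.geojson: edge ({u},{v}) references missing node"
            )
    try:
        net = RoadNetwork(nodes=nodes, edges=edges)
    except ValueError as exc:
        raise CityParseError(f"network.geojson: {exc}") from exc

    demands = []
    for i, feat in enumerate(load("demands.geojson").get("features", [])):
        props = feat.get("properties", {})
        x, y = feat["geometry"]["coordinates"]
        try:
            d = DemandPoint(int(props["demand_id"]), float(x), float(y),
                            int(props["population"]), int(props["snapped_node"]))
        except (KeyError, ValueError) as exc:
            raise CityParseError(f"demands.geojson: feature {i} malformed ({exc})") from exc
        if d.snapped_node not in node_ids:
            raise CityParseError(
                f"demands.geojson: demand {d.demand_id} snapped to missing node"
            )
        demands.append(d)

    facilities = []
    for i, feat in enumerate(load("facilities.geojson").get("features", [])):
        props = feat.get("properties", {})
        x, y = feat["geometry"]["coordinates"]
        try:
            f = FacilitySite(int(props["facility_id"]), float(x), float(y),
                             int(props["beds"]), str(props["status"]),
                             int(props["snapped_node"]))
        except (KeyError, ValueError) as exc:
            raise CityParseError(
                f"facilities.geojson: feature {i} malformed ({exc})"
            ) from exc
        if f.snapped_node not in node_ids:
            raise CityParseError(
                f"facilities.geojson: facility {f.facility_id} snapped to missing node"
            )
        facilities.append(f)

    meta = load("meta.json")
    return CityBundle(network=net, demands=demands, facilities=facilities,
                      seed=meta.get("seed"), params=meta.get("params", {}))
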