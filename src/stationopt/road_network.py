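"""Embedded road graph with exact shortest-path distance and travel time.

This is the ground truth that the overhead-graph estimator approximates.
The graph is undirected; each edge carries a length in metres and an average
speed in km/h.  Travel time is accumulated along the *length*-optimal path
(distance is primary; times are derived from distances via segment speeds).

Off-network points (patients, stations, bus stops) are attached by snapping
to the Euclidean-nearest graph node, applied identically to all layers so
the missing access leg cancels in comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

from .geodata import GeoPoint, PointLayer

# minutes per (metre at km/h): t[min] = (L[m] / 1000) / v[km/h] * 60
def _edge_minutes(length_m: float, speed_kmh: float) -> float:
    return length_m / 1000.0 / speed_kmh * 60.0


@dataclass
class PathResult:
    """Shortest-path query result: metres, minutes, reachability flag."""

    distance: float
    time: float
    reachable: bool


@dataclass
class RoadNetwork:
    nodes: np.ndarray  # (n, 2) planar metres
    edges: list[tuple[int, int, float, float]]  # (u, v, length_m, speed_kmh)
    n_components: int = 1
    graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    def __len__(self) -> int:
        return len(self.nodes)

    def length_matrix(self) -> csr_matrix:
        return _sparse_matrix(self, attr="length")

    def time_matrix(self) -> csr_matrix:
        return _sparse_matrix(self, attr="time")

    def mean_speed(self) -> float:
        """Length-weighted average segment speed (km/h)."""
        total_len = sum(e[2] for e in self.edges)
        total_time = sum(_edge_minutes(e[2], e[3]) for e in self.edges)
        return total_len / 1000.0 / (total_time / 60.0)


def build_road_network(
    nodes: np.ndarray | Sequence[GeoPoint],
    edges: Sequence[tuple[int, int, float, float]],
) -> RoadNetwork:
    """Validate geometry and assemble the graph.

    Rejects self-loops and edges shorter than the straight-line chord between
    their endpoints (corrupt geometry: a road cannot beat a straight line).
    Parallel edges keep only the shortest.
    """
    if not isinstance(nodes, np.ndarray):
        nodes = np.asarray([(p.x, p.y) for p in nodes], dtype=float)
    nodes = np.asarray(nodes, dtype=float).reshape(-1, 2)
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    clean: dict[tuple[int, int], tuple[int, int, float, float]] = {}
    for u, v, length, speed in edges:
        u, v = int(u), int(v)
        if not (0 <= u < n and 0 <= v < n):
            raise ValueError(f"edge ({u},{v}): node index out of range")
        if u == v:
            raise ValueError(f"edge ({u},{v}): self-loop")
        if length <= 0 or speed <= 0:
            raise ValueError(f"edge ({u},{v}): length and speed must be > 0")
        chord = float(np.hypot(*(nodes[u] - nodes[v])))
        if length < chord - 1e-6:
            raise ValueError(
                f"edge ({u},{v}): length {length:.1f} m shorter than its chord {chord:.1f} m"
            )
        key = (min(u, v), max(u, v))
        if key not in clean or length < clean[key][2]:
            clean[key] = (u, v, float(length), float(speed))
    kept = list(clean.values())
    for u, v, length, speed in kept:
        g.add_edge(u, v, length=length, time=_edge_minutes(length, speed), speed=speed)
    net = RoadNetwork(nodes=nodes, edges=kept, graph=g)
    net.n_components = nx.number_connected_components(g) if n else 0
    return net


def _sparse_matrix(net: RoadNetwork, attr: str) -> csr_matrix:
    n = len(net.nodes)
    rows, cols, vals = [], [], []
    for u, v, length, speed in net.edges:
        w = length if attr == "length" else _edge_minutes(length, speed)
        rows += [u, v]
        cols += [v, u]
        vals += [w, w]
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def shortest_path(net: RoadNetwork, a: int, b: int) -> PathResult:
    """Exact Dijkstra distance (m) and the time (min) along that same path."""
    if a == b:
        return PathResult(0.0, 0.0, True)
    try:
        length, path = nx.single_source_dijkstra(net.graph, a, b, weight="length")
    except nx.NetworkXNoPath:
        return PathResult(math.nan, math.nan, False)
    time = sum(net.graph.edges[u, v]["time"] for u, v in zip(path[:-1], path[1:]))
    return PathResult(float(length), float(time), True)


def dijkstra_from(
    net: RoadNetwork, sources: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path distances and along-path times from many sources at once.

    Returns (dist, time) arrays of shape (len(sources), n_nodes), in metres
    and minutes; unreachable entries are +inf.  Times are accumulated along
    the length-optimal predecessor tree, consistent with :func:`shortest_path`.
    """
    sources = np.asarray(sources, dtype=int)
    L = net.length_matrix()
    dist, pred = dijkstra(L, directed=False, indices=sources, return_predecessors=True)
    edge_time = {}
    for u, v, length, speed in net.edges:
        t = _edge_minutes(length, speed)
        edge_time[(u, v)] = t
        edge_time[(v, u)] = t
    time = np.full_like(dist, np.inf)
    n = len(net.nodes)
    for si in range(len(sources)):
        order = np.argsort(dist[si])
        t_row = time[si]
        t_row[sources[si]] = 0.0
        for v in order:
            if not np.isfinite(dist[si, v]):
                break
            p = pred[si, v]
            if p >= 0:
                t_row[v] = t_row[p] + edge_time[(int(p), int(v))]
    return dist, time


def snap(net: RoadNetwork, p: GeoPoint | np.ndarray) -> int:
    """Index of the Euclidean-nearest graph node; ties break to lowest index."""
    if len(net.nodes) == 0:
        raise ValueError("cannot snap to an empty network")
    q = np.asarray(p, dtype=float)
    d2 = np.sum((net.nodes - q) ** 2, axis=1)
    return int(np.argmin(d2))


def snap_many(net: RoadNetwork, xy: np.ndarray) -> np.ndarray:
    """Vectorized :func:`snap` for an (m, 2) array of points."""
    if len(net.nodes) == 0:
        raise ValueError("cannot snap to an empty network")
    d2 = cdist(np.asarray(xy, dtype=float), net.nodes, metric="sqeuclidean")
    return np.argmin(d2, axis=1)


def nearest_point_distance(layer: PointLayer, p: GeoPoint | np.ndarray) -> float:
    """Euclidean distance (m) from p to the closest point of the layer."""
    if len(layer) == 0:
        raise ValueError(f"layer {layer.kind!r} is empty")
    q = np.asarray(p, dtype=float)
    return float(np.sqrt(np.min(np.sum((layer.coords() - q) ** 2, axis=1))))


def nearest_point_distances(layer: PointLayer, xy: np.ndarray) -> np.ndarray:
    """Vectorized nearest-layer-point distance for an (m, 2) array."""
    if len(layer) == 0:
        raise ValueError(f"layer {layer.kind!r} is empty")
    d = cdist(np.asarray(xy, dtype=float), layer.coords())
    return np.min(d, axis=1)


# ---------------------------------------------------------------------------
# I/O


def read_network_geojson(path) -> RoadNetwork:
    """Build a network from GeoJSON LineStrings with a ``speed_kmh`` property.

    Consecutive vertices of each LineString become nodes and edges; vertices
    shared between features (within 1e-6 m) are merged into one node.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    node_index: dict[tuple[float, float], int] = {}
    nodes: list[tuple[float, float]] = []
    edges: list[tuple[int, int, float, float]] = []

    def node_id(x: float, y: float) -> int:
        key = (round(x, 6), round(y, 6))
        if key not in node_index:
            node_index[key] = len(nodes)
            nodes.append((x, y))
        return node_index[key]

    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValueError(f"{path}: non-LineString geometry {geom.get('type')!r}")
        speed = float((feat.get("properties") or {}).get("speed_kmh", 50.0))
        coords = geom["coordinates"]
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            u, v = node_id(x0, y0), node_id(x1, y1)
            if u == v:
                continue
            length = math.hypot(x1 - x0, y1 - y0)
            edges.append((u, v, length, speed))
    return build_road_network(np.asarray(nodes, dtype=float), edges)


def read_network_csv(nodes_path, edges_path) -> RoadNetwork:
    """Read a node CSV (``node_id,x,y``) and an edge CSV (``u,v,length_m,speed_kmh``)."""
    ndf = pd.read_csv(nodes_path)
    edf = pd.read_csv(edges_path)
    order = {int(i): k for k, i in enumerate(ndf["node_id"])}
    nodes = ndf[["x", "y"]].to_numpy(dtype=float)
    edges = [
        (order[int(r.u)], order[int(r.v)], float(r.length_m), float(r.speed_kmh))
        for r in edf.itertuples()
    ]
    return build_road_network(nodes, edges)


def write_network_csv(net: RoadNetwork, nodes_path, edges_path) -> None:
    pd.DataFrame(
        {"node_id": range(len(net.nodes)), "x": net.nodes[:, 0], "y": net.nodes[:, 1]}
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        [(u, v, length, speed) for u, v, length, speed in net.edges],
        columns=["u", "v", "length_m", "speed_kmh"],
    ).to_csv(edges_path, index=False)
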