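"""Overhead graph: constant-time travel distance/time estimation.

Computing exact network shortest paths inside a location-optimization loop is
prohibitively slow (millions of queries against moving facility locations).
The overhead graph trades exactness for speed: K anchor nodes are placed
where demand is dense, and for every anchor pair the *overhead ratio*
(network shortest-path distance / straight-line distance — the detour index)
and the effective speed along that path are precomputed into K x K matrices.

A query then costs one nearest-anchor scan and one multiplication:

    travel_distance(p, q) ~= d_L2(p, q) * ratio[anchor(p), anchor(q)]
    travel_time(p, q)     ~= travel_distance / speed[anchor(p), anchor(q)]

On simple street grids the ratio approaches the Manhattan diagonal sqrt(2);
around lakes and rivers it is locally much larger, which is exactly the
structure a single global detour factor (the classic 1.4) cannot capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .road_network import RoadNetwork, dijkstra_from, snap_many

DEFAULT_K = 256
DEFAULT_EPS_ANCHOR = 1.0  # metres; closer anchor pairs get ratio 1


class UnreachableError(RuntimeError):
    """Raised when a query falls on an anchor pair with no network path."""


@dataclass
class OverheadGraph:
    anchors: np.ndarray  # (K, 2) anchor coordinates (road-node positions)
    anchor_nodes: np.ndarray  # (K,) road-node index of each anchor
    ratio: np.ndarray  # (K, K) detour ratios, symmetric, >= 1 where meaningful
    speed: np.ndarray  # (K, K) effective speeds along anchor-pair paths, km/h
    reachable: np.ndarray  # (K, K) bool
    eps_anchor: float = DEFAULT_EPS_ANCHOR

    @property
    def k(self) -> int:
        return len(self.anchors)

    def nearest_anchor(self, xy: np.ndarray) -> np.ndarray:
        """Nearest-anchor index for each row of an (m, 2) array (linear scan)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = cdist(xy, self.anchors, metric="sqeuclidean")
        return np.argmin(d2, axis=1)


def select_anchors(
    patients_xy: np.ndarray,
    net: RoadNetwork,
    k: int = DEFAULT_K,
    seed: int = 0,
    swap_trials: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Place K anchors where the patients are.

    Patient locations are clustered (squared-Euclidean objective, random-swap
    optimized so sparse demand pockets are not missed) and each centroid is
    snapped to its nearest road node.  Anchors are therefore dense exactly
    where most travel queries will originate.

    Returns (anchors (K, 2) node coordinates, anchor node indices (K,)).
    """
    from .cost_model import Objective
    from .optimizer import random_swap_xy

    patients_xy = np.asarray(patients_xy, dtype=float)
    n_distinct = len(np.unique(patients_xy, axis=0))
    if k < 2:
        raise ValueError("need at least 2 anchors")
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct patient locations")
    if k == n_distinct:
        centroids = np.unique(patients_xy, axis=0)
    else:
        sol = random_swap_xy(
            patients_xy,
            k=k,
            objective=Objective.squared_euclidean(),
            trials=swap_trials,
            seed=seed,
        )
        centroids = sol.stations_xy
    anchor_nodes = snap_many(net, centroids)
    return net.nodes[anchor_nodes].copy(), anchor_nodes


def build_overhead_matrix(
    net: RoadNetwork,
    anchor_nodes: np.ndarray,
    eps_anchor: float = DEFAULT_EPS_ANCHOR,
) -> OverheadGraph:
    """Precompute the K x K ratio and speed matrices by multi-source Dijkstra.

    ratio[i, j] = network distance / Euclidean distance between anchors i, j;
    pairs closer than ``eps_anchor`` (including the diagonal) get ratio 1 to
    avoid a division blow-up.  speed[i, j] is the harmonic (distance / time)
    mean speed along the exact anchor-pair path.  Unreachable pairs are
    flagged, never silently infinite.
    """
    anchor_nodes = np.asarray(anchor_nodes, dtype=int)
    anchors = net.nodes[anchor_nodes].copy()
    dist, time = dijkstra_from(net, anchor_nodes)
    dist = dist[:, anchor_nodes]
    time = time[:, anchor_nodes]
    # Dijkstra is symmetric on an undirected graph; enforce it bit-exactly.
    dist = np.minimum(dist, dist.T)
    time = np.minimum(time, time.T)
    reachable = np.isfinite(dist)

    euclid = cdist(anchors, anchors)
    near = euclid < eps_anchor
    ratio = np.full_like(euclid, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[reachable] = dist[reachable] / euclid[reachable]
    ratio[near] = 1.0
    ratio[~reachable & ~near] = np.nan

    fallback = net.mean_speed()
    speed = np.full_like(euclid, np.nan)
    positive = reachable & (dist > 0) & (time > 0)
    speed[positive] = dist[positive] / 1000.0 / (time[positive] / 60.0)
    speed[reachable & ~positive] = fallback  # coincident anchors
    speed[near & ~reachable] = fallback
    reachable = reachable | near

    return OverheadGraph(
        anchors=anchors,
        anchor_nodes=anchor_nodes,
        ratio=ratio,
        speed=speed,
        reachable=reachable,
        eps_anchor=eps_anchor,
    )


def build_overhead_graph(
    patients_xy: np.ndarray,
    net: RoadNetwork,
    k: int = DEFAULT_K,
    seed: int = 0,
    swap_trials: int = 500,
    eps_anchor: float = DEFAULT_EPS_ANCHOR,
) -> OverheadGraph:
    """Anchor selection + matrix build in one call (the ``build-graph`` step)."""
    _, anchor_nodes = select_anchors(patients_xy, net, k=k, seed=seed, swap_trials=swap_trials)
    return build_overhead_matrix(net, anchor_nodes, eps_anchor=eps_anchor)


def estimate_travel(og: OverheadGraph, p, q) -> tuple[float, float]:
    """Estimated (distance m, time min) between two arbitrary points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d_l2 = float(np.hypot(*(p - q)))
    if d_l2 == 0.0:
        return 0.0, 0.0
    i = int(og.nearest_anchor(p)[0])
    j = int(og.nearest_anchor(q)[0])
    if not og.reachable[i, j]:
        raise UnreachableError(f"anchor pair ({i}, {j}) is not connected by the network")
    dist = d_l2 * float(og.ratio[i, j])
    time = dist / 1000.0 / float(og.speed[i, j]) * 60.0
    return dist, time


def estimate_distance_matrix(
    og: OverheadGraph,
    p_xy: np.ndarray,
    s_xy: np.ndarray,
    p_anchor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized estimates for all point-station pairs.

    Returns (distance (n,k) m, speed (n,k) km/h, reachable (n,k) bool).
    ``p_anchor`` lets callers cache the nearest-anchor index of static points
    (patients never move during optimization).
    """
    if p_anchor is None:
        p_anchor = og.nearest_anchor(p_xy)
    s_anchor = og.nearest_anchor(s_xy)
    d_l2 = cdist(np.asarray(p_xy, dtype=float), np.asarray(s_xy, dtype=float))
    ix = np.ix_(p_anchor, s_anchor)
    dist = d_l2 * og.ratio[ix]
    return dist, og.speed[ix], og.reachable[ix]


# ---------------------------------------------------------------------------
# persistence: a directory with a JSON header, an anchor table and two matrices


def save_overhead_graph(og: OverheadGraph, path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "header.json", "w") as fh:
        json.dump(
            {
                "k": og.k,
                "eps_anchor": og.eps_anchor,
                "crs_note": "planar metres, CRS chosen by the user; never reprojected",
                "files": {
                    "anchors": "anchors.csv",
                    "ratio": "ratio.csv",
                    "speed": "speed.csv",
                },
                "unreachable_encoding": "nan",
            },
            fh,
            indent=2,
        )
    header = "x,y,node"
    table = np.column_stack([og.anchors, og.anchor_nodes])
    np.savetxt(out / "anchors.csv", table, fmt="%.17g", delimiter=",", header=header, comments="")
    np.savetxt(out / "ratio.csv", og.ratio, fmt="%.17g", delimiter=",")
    np.savetxt(out / "speed.csv", og.speed, fmt="%.17g", delimiter=",")


def load_overhead_graph(path) -> OverheadGraph:
    src = Path(path)
    with open(src / "header.json") as fh:
        header = json.load(fh)
    table = np.loadtxt(src / "anchors.csv", delimiter=",", skiprows=1, ndmin=2)
    ratio = np.loadtxt(src / "ratio.csv", delimiter=",", ndmin=2)
    speed = np.loadtxt(src / "speed.csv", delimiter=",", ndmin=2)
    return OverheadGraph(
        anchors=table[:, :2],
        anchor_nodes=table[:, 2].astype(int),
        ratio=ratio,
        speed=speed,
        reachable=np.isfinite(ratio),
        eps_anchor=float(header.get("eps_anchor", DEFAULT_EPS_ANCHOR)),
    )
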