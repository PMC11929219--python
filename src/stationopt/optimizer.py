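"""Random-swap clustering over patient locations.

K-means alone is unreliable for facility location: it cannot move a centroid
across an empty area, so with many well-separated demand clusters it
routinely leaves some clusters with too many stations and others with none.
Random swap wraps k-means in a trial-and-error loop that *can* jump:

    start from k random patient locations, polish with two k-means iterations
    repeat T times:
        replace one random station with a random patient location
        run two k-means iterations
        keep the new solution iff it strictly lowers the objective

T = 5000 trials is the standard recommendation; the algorithm is not
sensitive to it.  Centroids are (visit-weighted) arithmetic means for every
objective, including travel cost — a deliberate simplification; an optional
post-processing step snaps stations to the nearest existing building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cost_model import CostParams, Objective
from .geodata import (
    Patient,
    PointLayer,
    Station,
    patients_to_arrays,
    stations_from_array,
    stations_to_array,
)
from .overhead import OverheadGraph

DEFAULT_TRIALS = 5000
DEFAULT_KMEANS_ITERS = 2


@dataclass
class Solution:
    """A station configuration with its assignment, objective value and trace."""

    stations_xy: np.ndarray
    assignment: np.ndarray
    cost: float
    history: list[tuple[int, float, bool]] = field(default_factory=list)

    def stations(self, prefix: str = "opt") -> list[Station]:
        return stations_from_array(self.stations_xy, prefix=prefix)


@dataclass
class RSConfig:
    k: int
    objective: Objective
    trials: int = DEFAULT_TRIALS
    kmeans_iters_per_swap: int = DEFAULT_KMEANS_ITERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.trials < 0:
            raise ValueError("trials must be >= 0")


# ---------------------------------------------------------------------------
# array-level engine


def _as_xyw(patients) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(patients, np.ndarray):
        xy = np.asarray(patients, dtype=float)
        return xy, np.zeros(len(xy)), np.ones(len(xy))
    return patients_to_arrays(list(patients))


def _as_s_xy(stations) -> np.ndarray:
    if isinstance(stations, np.ndarray):
        return np.asarray(stations, dtype=float)
    return stations_to_array(list(stations))


def _update_centroids_xy(
    xy: np.ndarray,
    weight: np.ndarray,
    labels: np.ndarray,
    k: int,
    prev_xy: np.ndarray | None = None,
    mincost: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted arithmetic-mean centroid per cluster.

    A cluster that receives no patients shrinks k in effect; if the previous
    centroids and the per-patient assignment costs are available, each empty
    cluster is repaired by relocating its station to the patient currently
    farthest (most costly, under the active metric) from its own station.
    """
    wsum = np.bincount(labels, weights=weight, minlength=k)
    sx = np.bincount(labels, weights=weight * xy[:, 0], minlength=k)
    sy = np.bincount(labels, weights=weight * xy[:, 1], minlength=k)
    out = np.empty((k, 2), dtype=float)
    ok = wsum > 0
    out[ok, 0] = sx[ok] / wsum[ok]
    out[ok, 1] = sy[ok] / wsum[ok]
    empties = np.flatnonzero(~ok)
    if len(empties) > 0:
        if prev_xy is None:
            raise ValueError(f"clusters {empties.tolist()} are empty and no repair context given")
        if mincost is None:
            out[~ok] = prev_xy[~ok]
        else:
            pool = np.where(np.isfinite(mincost), mincost, np.finfo(float).max)
            pool = pool.copy()
            for j in empties:
                far = int(np.argmax(pool))
                out[j] = xy[far]
                pool[far] = -np.inf  # each repair takes a different patient
    return out


def kmeans_xy(
    xy: np.ndarray,
    weight: np.ndarray,
    init_xy: np.ndarray,
    bound,
    iters: int,
) -> Solution:
    """Alternate assignment and centroid update ``iters`` times, then score."""
    if iters < 1:
        raise ValueError("iters must be >= 1")
    s = np.array(init_xy, dtype=float, copy=True)
    k = len(s)
    for _ in range(iters):
        labels, mincost = bound.assign(s)
        s = _update_centroids_xy(xy, weight, labels, k, prev_xy=s, mincost=mincost)
    labels, mincost = bound.assign(s)
    cost = float(np.dot(weight, mincost))
    return Solution(stations_xy=s, assignment=labels, cost=cost, history=[(0, cost, True)])


def random_swap_xy(
    xy: np.ndarray,
    k: int,
    objective: Objective,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    age: np.ndarray | None = None,
    weight: np.ndarray | None = None,
    kmeans_iters: int = DEFAULT_KMEANS_ITERS,
) -> Solution:
    """Random-swap optimization on raw coordinate arrays (seed-deterministic)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    age = np.zeros(n) if age is None else np.asarray(age, dtype=float)
    weight = np.ones(n) if weight is None else np.asarray(weight, dtype=float)
    n_distinct = len(np.unique(xy, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct patient locations")
    rng = np.random.default_rng(seed)
    bound = objective.bind(xy, age, weight)

    init = xy[rng.choice(n, size=k, replace=False)]
    current = kmeans_xy(xy, weight, init, bound, kmeans_iters)
    history: list[tuple[int, float, bool]] = [(0, current.cost, True)]

    for t in range(1, trials + 1):
        j = int(rng.integers(k))
        r = int(rng.integers(n))
        trial_init = current.stations_xy.copy()
        trial_init[j] = xy[r]
        trial = kmeans_xy(xy, weight, trial_init, bound, kmeans_iters)
        accepted = trial.cost < current.cost  # strict: ties rejected
        if accepted:
            current = trial
        history.append((t, trial.cost, accepted))
    current.history = history
    return current


# ---------------------------------------------------------------------------
# spec-level operations on domain objects


def assign(patients, stations, obj: Objective) -> np.ndarray:
    """Per-patient index of its cost-minimizing station (ties -> lowest index)."""
    xy, age, weight = _as_xyw(patients)
    labels, _ = obj.bind(xy, age, weight).assign(_as_s_xy(stations))
    return labels


def update_centroids(patients, assignment: np.ndarray, k: int, prev=None) -> list[Station]:
    """Visit-weighted arithmetic-mean centroid of each cluster."""
    xy, _, weight = _as_xyw(patients)
    prev_xy = _as_s_xy(prev) if prev is not None else None
    out = _update_centroids_xy(xy, weight, np.asarray(assignment, dtype=int), k, prev_xy=prev_xy)
    return stations_from_array(out)


def kmeans(patients, init, obj: Objective, iters: int = DEFAULT_KMEANS_ITERS) -> Solution:
    xy, age, weight = _as_xyw(patients)
    return kmeans_xy(xy, weight, _as_s_xy(init), obj.bind(xy, age, weight), iters)


def random_swap(patients, cfg: RSConfig) -> Solution:
    xy, age, weight = _as_xyw(patients)
    return random_swap_xy(
        xy,
        k=cfg.k,
        objective=cfg.objective,
        trials=cfg.trials,
        seed=cfg.seed,
        age=age,
        weight=weight,
        kmeans_iters=cfg.kmeans_iters_per_swap,
    )


def snap_to_buildings(stations, buildings: PointLayer):
    """Move each station to its Euclidean-nearest building (post-processing).

    Keeps stations off lakes and other places without infrastructure.  Two
    stations may snap to the same building; no uniqueness is enforced.
    """
    if buildings is None or len(buildings) == 0:
        raise ValueError("building layer is empty")
    s_xy = _as_s_xy(stations)
    b = buildings.coords()
    idx = np.argmin(cdist(s_xy, b, metric="sqeuclidean"), axis=1)
    snapped = b[idx]
    if isinstance(stations, np.ndarray):
        return snapped
    return [
        Station(id=s.id, loc=type(s.loc)(*snapped[i]), label=s.label)
        for i, s in enumerate(stations)
    ]


def centroid_index(found, truth) -> int:
    """Cluster-level error: truth centres that attract no found centre.

    Each found centre maps to its Euclidean-nearest truth centre; the index
    counts orphaned truth centres.  0 means every true cluster was detected.
    """
    f = _as_s_xy(found)
    t = _as_s_xy(truth)
    if len(f) == 0 or len(t) == 0:
        raise ValueError("both station sets must be non-empty")
    nearest = np.argmin(cdist(f, t, metric="sqeuclidean"), axis=1)
    covered = np.zeros(len(t), dtype=bool)
    covered[nearest] = True
    return int(np.sum(~covered))


def evaluate(
    patients,
    stations,
    og: OverheadGraph,
    bus_stops: PointLayer,
    params: CostParams | None = None,
) -> dict:
    """Accessibility report for a station configuration.

    Patients are assigned by the travel-cost metric; the report gives
    visit-weighted mean travel time (min) and distance (km) per visit, the
    annual total travel cost (EUR, weights = visits/year), per-station
    patient counts and cost subtotals, and the travel-mode split.
    Network-unreachable patients are listed and excluded from the means.
    """
    params = params or CostParams()
    xy, age, weight = _as_xyw(patients)
    s_xy = _as_s_xy(stations)
    obj = Objective.travel_cost(og, bus_stops, params)
    detail = obj.bind(xy, age, weight).per_patient(s_xy)
    ok = detail["reachable"]
    w = weight[ok]
    wsum = float(np.sum(w))
    labels = detail["labels"]
    k = len(s_xy)
    per_station_patients = np.bincount(labels[ok], minlength=k)
    per_station_cost = np.bincount(
        labels[ok], weights=w * detail["visit_cost"][ok], minlength=k
    )
    modes = {m: float(np.sum(w[detail["mode"][ok] == m]) / wsum) for m in ("walk", "taxi", "bus", "car")}
    report = {
        "n_patients": int(len(xy)),
        "n_stations": int(k),
        "annual_visits": float(np.sum(weight)),
        "mean_travel_time_min": float(np.dot(w, detail["time_min"][ok]) / wsum),
        "mean_travel_distance_km": float(np.dot(w, detail["distance_m"][ok]) / wsum / 1000.0),
        "mean_visit_cost_eur": float(np.dot(w, detail["visit_cost"][ok]) / wsum),
        "total_annual_cost_eur": float(np.dot(w, detail["visit_cost"][ok])),
        "mode_share_by_visits": modes,
        "per_station_patients": per_station_patients.tolist(),
        "per_station_annual_cost_eur": per_station_cost.tolist(),
        "unreachable_patients": np.flatnonzero(~ok).tolist(),
    }
    return report
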