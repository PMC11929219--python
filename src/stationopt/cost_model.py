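"""Objective functions and the rule-based patient travel-cost model.

Three objectives are supported, each summed over patients (optionally
weighted by annual visits) at their objective-minimizing station:

* ``euclidean``          sum of straight-line distances (metres)
* ``squared_euclidean``  the k-means objective (metres^2)
* ``travel_cost``        sum of per-visit monetary travel costs (EUR), using
                         overhead-graph distance estimates

The travel-cost model assigns each patient a travel mode by rules:
patients within 1 km of their station walk (0 EUR); patients aged 80+ take a
taxi; patients with a bus stop within 200 m take the bus at a flat
5.10 EUR/trip; everyone else drives.  Per-visit costs count a round trip
(``trips_per_visit = 2``).  Rule precedence, thresholds and tariffs are all
configuration, not code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import overhead as _oh
from .geodata import (
    Patient,
    PointLayer,
    Station,
    patients_to_arrays,
    stations_to_array,
)
from .road_network import nearest_point_distance, nearest_point_distances

logger = logging.getLogger(__name__)

MODES = ("walk", "taxi", "bus", "car")


@dataclass(frozen=True)
class CostParams:
    """Thresholds and tariffs of the travel-cost model (EUR, metres, years)."""

    walk_threshold: float = 1000.0  # m, straight-line patient -> station
    bus_stop_threshold: float = 200.0  # m, straight-line patient -> nearest stop
    bus_fare: float = 5.10  # EUR per one-way trip, flat (no fare zones)
    taxi_age: float = 80.0  # years
    car_cost_per_km: float = 0.25  # EUR/km
    taxi_base: float = 5.90  # EUR per trip
    taxi_cost_per_km: float = 1.50  # EUR/km
    trips_per_visit: int = 2  # round trip
    mode_precedence: tuple[str, ...] = ("walk", "taxi", "bus", "car")

    def __post_init__(self) -> None:
        for name in (
            "walk_threshold",
            "bus_stop_threshold",
            "bus_fare",
            "taxi_age",
            "car_cost_per_km",
            "taxi_base",
            "taxi_cost_per_km",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trips_per_visit < 1:
            raise ValueError("trips_per_visit must be >= 1")
        if sorted(self.mode_precedence) != sorted(MODES):
            raise ValueError(f"mode_precedence must be a permutation of {MODES}")

    def replace(self, **kw) -> "CostParams":
        return replace(self, **kw)


def travel_mode(
    p: Patient | float,
    dist_to_station: float,
    dist_to_bus_stop: float,
    params: CostParams,
) -> str:
    """First matching rule in ``params.mode_precedence`` wins."""
    age = p.age if isinstance(p, Patient) else float(p)
    if dist_to_station < 0 or dist_to_bus_stop < 0:
        raise ValueError("distances must be >= 0")
    for mode in params.mode_precedence:
        if mode == "walk" and dist_to_station < params.walk_threshold:
            return "walk"
        if mode == "taxi" and age >= params.taxi_age:
            return "taxi"
        if mode == "bus" and dist_to_bus_stop < params.bus_stop_threshold:
            return "bus"
        if mode == "car":
            return "car"
    return "car"


def mode_cost(mode: str, travel_distance_m: float, params: CostParams) -> float:
    """Per-visit EUR cost of a mode over an estimated travel distance."""
    km = travel_distance_m / 1000.0
    t = params.trips_per_visit
    if mode == "walk":
        return 0.0
    if mode == "bus":
        return t * params.bus_fare
    if mode == "car":
        return t * params.car_cost_per_km * km
    if mode == "taxi":
        return t * (params.taxi_base + params.taxi_cost_per_km * km)
    raise ValueError(f"unknown mode {mode!r}")


def visit_cost(
    p: Patient,
    s: Station,
    og: _oh.OverheadGraph,
    bus_stops: PointLayer,
    params: CostParams,
) -> float:
    """Per-visit EUR cost for one patient-station pair.

    The mode decision uses straight-line distances (patient -> station for
    the walk rule, patient -> nearest stop for the bus rule); the car/taxi
    distance-proportional part uses the overhead-graph travel estimate.
    """
    if bus_stops is None or len(bus_stops) == 0:
        raise ValueError("travel-cost model needs a non-empty bus-stop layer")
    d_l2 = math.hypot(p.loc.x - s.loc.x, p.loc.y - s.loc.y)
    d_stop = nearest_point_distance(bus_stops, p.loc)
    mode = travel_mode(p, d_l2, d_stop, params)
    dist, _ = _oh.estimate_travel(og, p.loc, s.loc)  # raises if unreachable
    return mode_cost(mode, dist, params)


# ---------------------------------------------------------------------------
# Objectives


@dataclass
class Objective:
    """One of the three optimization criteria, fully configured."""

    kind: str  # euclidean | squared_euclidean | travel_cost
    params: CostParams | None = None
    og: _oh.OverheadGraph | None = None
    bus_stops: PointLayer | None = None

    @staticmethod
    def euclidean() -> "Objective":
        return Objective(kind="euclidean")

    @staticmethod
    def squared_euclidean() -> "Objective":
        return Objective(kind="squared_euclidean")

    @staticmethod
    def travel_cost(
        og: _oh.OverheadGraph,
        bus_stops: PointLayer,
        params: CostParams | None = None,
    ) -> "Objective":
        if og is None:
            raise ValueError("travel-cost objective requires an overhead graph")
        if bus_stops is None or len(bus_stops) == 0:
            raise ValueError("travel-cost objective requires a non-empty bus-stop layer")
        return Objective(
            kind="travel_cost", params=params or CostParams(), og=og, bus_stops=bus_stops
        )

    def bind(self, xy: np.ndarray, age: np.ndarray, weight: np.ndarray):
        """Precompute per-patient caches and return a fast evaluator."""
        if self.kind in ("euclidean", "squared_euclidean"):
            return _BoundGeometric(self.kind, xy, weight)
        if self.kind == "travel_cost":
            return _BoundTravelCost(xy, age, weight, self.og, self.bus_stops, self.params)
        raise ValueError(f"unknown objective kind {self.kind!r}")

    def bind_patients(self, patients: Sequence[Patient]):
        xy, age, weight = patients_to_arrays(list(patients))
        return self.bind(xy, age, weight)


class _BoundGeometric:
    """Euclidean / squared-Euclidean evaluator over a fixed patient array."""

    def __init__(self, kind: str, xy: np.ndarray, weight: np.ndarray):
        self.kind = kind
        self.xy = np.asarray(xy, dtype=float)
        self.weight = np.asarray(weight, dtype=float)

    def cost_matrix(self, s_xy: np.ndarray) -> np.ndarray:
        d2 = cdist(self.xy, np.asarray(s_xy, dtype=float), metric="sqeuclidean")
        return d2 if self.kind == "squared_euclidean" else np.sqrt(d2)

    def assign(self, s_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-patient argmin station and its cost; exact ties -> lowest index."""
        s_xy = np.asarray(s_xy, dtype=float)
        snorm = np.einsum("ij,ij->i", s_xy, s_xy)
        # argmin of ||p - s||^2 over s: the ||p||^2 term is constant per row
        key = self.xy @ s_xy.T
        key *= -2.0
        key += snorm[None, :]
        labels = np.argmin(key, axis=1)
        # recompute the selected pair exactly (the matmul form carries
        # cancellation error that must not leak into reported costs)
        diff = self.xy - s_xy[labels]
        mind2 = np.einsum("ij,ij->i", diff, diff)
        cost = mind2 if self.kind == "squared_euclidean" else np.sqrt(mind2)
        return labels, cost

    def total(self, s_xy: np.ndarray) -> float:
        _, cost = self.assign(s_xy)
        return float(np.dot(self.weight, cost))


class _BoundTravelCost:
    """Travel-cost evaluator with cached per-patient statics.

    Patients never move during optimization, so their nearest anchor, their
    distance to the closest bus stop and their taxi eligibility are computed
    once.  Only station-dependent quantities are evaluated per call.
    """

    kind = "travel_cost"

    def __init__(self, xy, age, weight, og, bus_stops, params):
        self.xy = np.asarray(xy, dtype=float)
        self.weight = np.asarray(weight, dtype=float)
        self.og = og
        self.params = params
        self.p_anchor = og.nearest_anchor(self.xy)
        self.bus_ok = nearest_point_distances(bus_stops, self.xy) < params.bus_stop_threshold
        self.taxi = np.asarray(age, dtype=float) >= params.taxi_age

    def _matrices(self, s_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(cost, est distance, speed, reachable) for all pairs."""
        s_xy = np.asarray(s_xy, dtype=float)
        d_l2 = cdist(self.xy, s_xy)
        dist, speed, reach = _oh.estimate_distance_matrix(self.og, self.xy, s_xy, self.p_anchor)
        p = self.params
        km = dist / 1000.0
        t = p.trips_per_visit
        cost = np.empty_like(dist)
        # apply rules in reverse precedence so the first rule wins
        for mode in reversed(p.mode_precedence):
            if mode == "car":
                cost[:] = t * p.car_cost_per_km * km
            elif mode == "bus":
                cost[self.bus_ok, :] = t * p.bus_fare
            elif mode == "taxi":
                cost[self.taxi, :] = t * (p.taxi_base + p.taxi_cost_per_km * km[self.taxi, :])
            elif mode == "walk":
                cost[d_l2 < p.walk_threshold] = 0.0
        cost[~reach] = np.inf
        dist = np.where(reach, dist, np.inf)
        return cost, dist, speed, reach

    def cost_matrix(self, s_xy: np.ndarray) -> np.ndarray:
        return self._matrices(s_xy)[0]

    def assign(self, s_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Argmin station per patient.

        The flat bus fare and the free walk make exact cost ties common, so
        ties break by smaller estimated travel distance, then lowest index.
        """
        cost, dist, _, _ = self._matrices(s_xy)
        cmin = np.min(cost, axis=1)
        tied = cost == cmin[:, None]
        dist_tied = np.where(tied, dist, np.inf)
        labels = np.argmin(dist_tied, axis=1)
        n = len(labels)
        out = cost[np.arange(n), labels]
        bad = ~np.isfinite(cmin)
        if bad.any():  # patient unreachable from every station
            out[bad] = np.inf
        return labels, out

    def total(self, s_xy: np.ndarray) -> float:
        _, cost = self.assign(s_xy)
        return float(np.dot(self.weight, cost))

    def per_patient(self, s_xy: np.ndarray) -> dict:
        """Per-patient detail for accessibility reports."""
        cost, dist, speed, reach = self._matrices(s_xy)
        cmin = np.min(cost, axis=1)
        tied = cost == cmin[:, None]
        dist_tied = np.where(tied, dist, np.inf)
        labels = np.argmin(dist_tied, axis=1)
        n = len(labels)
        rows = np.arange(n)
        d = dist[rows, labels]
        v = speed[rows, labels]
        time_min = np.where(np.isfinite(d), d / 1000.0 / v * 60.0, np.inf)
        s_xy = np.asarray(s_xy, dtype=float)
        d_l2 = np.hypot(*(self.xy - s_xy[labels]).T)
        mode = np.full(n, "car", dtype=object)
        p = self.params
        for m in reversed(p.mode_precedence):
            if m == "bus":
                mode[self.bus_ok] = "bus"
            elif m == "taxi":
                mode[self.taxi] = "taxi"
            elif m == "walk":
                mode[d_l2 < p.walk_threshold] = "walk"
        reachable = reach[rows, labels]
        return {
            "labels": labels,
            "distance_m": d,
            "time_min": time_min,
            "mode": mode,
            "visit_cost": cost[rows, labels],
            "reachable": reachable,
        }


# ---------------------------------------------------------------------------
# spec-level scalar operations


def pair_cost(obj: Objective, p: Patient, s: Station) -> float:
    """Cost of serving one patient from one station under the objective."""
    if obj.kind == "euclidean":
        return math.hypot(p.loc.x - s.loc.x, p.loc.y - s.loc.y)
    if obj.kind == "squared_euclidean":
        return (p.loc.x - s.loc.x) ** 2 + (p.loc.y - s.loc.y) ** 2
    if obj.kind == "travel_cost":
        return visit_cost(p, s, obj.og, obj.bus_stops, obj.params)
    raise ValueError(f"unknown objective kind {obj.kind!r}")


def total_cost(
    obj: Objective,
    patients: Sequence[Patient] | np.ndarray,
    stations: Sequence[Station] | np.ndarray,
) -> float:
    """Weighted sum over patients of the cost to their best station."""
    if isinstance(stations, np.ndarray):
        s_xy = np.asarray(stations, dtype=float)
    else:
        s_xy = stations_to_array(list(stations))
    if len(s_xy) == 0:
        raise ValueError("station set is empty")
    if isinstance(patients, np.ndarray):
        xy = np.asarray(patients, dtype=float)
        age = np.zeros(len(xy))
        weight = np.ones(len(xy))
    else:
        xy, age, weight = patients_to_arrays(list(patients))
    if len(xy) == 0:
        logger.warning("total_cost over an empty patient set is 0")
        return 0.0
    return obj.bind(xy, age, weight).total(s_xy)
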