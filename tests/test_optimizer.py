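import numpy as np
import pytest

from stationopt import (
    GeoPoint,
    Objective,
    Patient,
    PointLayer,
    RSConfig,
    Station,
    assign,
    centroid_index,
    evaluate,
    generate_grid_clusters,
    kmeans,
    random_swap,
    snap_to_buildings,
    total_cost,
    update_centroids,
)
from stationopt.optimizer import _update_centroids_xy, kmeans_xy, random_swap_xy


def _p(x, y, weight=1.0, pid=None, age=50):
    return Patient(pid or f"p{x}_{y}", GeoPoint(float(x), float(y)), age=age, weight=weight)


def _s(x, y, sid="s"):
    return Station(sid, GeoPoint(float(x), float(y)))


# --- assignment -------------------------------------------------------------


def test_assign_single_station_all_zero():
    patients = [_p(0, 0, pid="a"), _p(100, 200, pid="b")]
    assert assign(patients, [_s(50, 50)], Objective.euclidean()).tolist() == [0, 0]


def test_assign_tie_breaks_to_lowest_index():
    patients = [_p(0, 0, pid="a")]
    stations = [_s(-1000, 0, sid="s0"), _s(1000, 0, sid="s1")]
    assert assign(patients, stations, Objective.euclidean())[0] == 0
    assert assign(patients, stations, Objective.squared_euclidean())[0] == 0


@pytest.mark.parametrize("kind", ["euclidean", "squared_euclidean"])
def test_assign_matches_brute_force(kind):
    rng = np.random.default_rng(12)
    xy = rng.uniform(0, 10_000, (200, 2))
    s = rng.uniform(0, 10_000, (7, 2))
    obj = Objective(kind=kind)
    labels = assign(xy, s, obj)
    d = np.linalg.norm(xy[:, None, :] - s[None, :, :], axis=2)
    brute = np.argmin(d if kind == "euclidean" else d**2, axis=1)
    assert np.array_equal(labels, brute)


# --- centroid update --------------------------------------------------------


def test_update_centroids_means():
    patients = [_p(0, 0, pid="a"), _p(2, 2, pid="b")]
    out = update_centroids(patients, np.array([0, 0]), k=1)
    assert out[0].loc == GeoPoint(1.0, 1.0)


def test_update_centroids_singleton_cluster():
    patients = [_p(5, 7, pid="a"), _p(100, 100, pid="b")]
    out = update_centroids(patients, np.array([0, 1]), k=2)
    assert out[0].loc == GeoPoint(5.0, 7.0)
    assert out[1].loc == GeoPoint(100.0, 100.0)


def test_update_centroids_weighted_mean():
    # weights 1 and 3 on x = 0 and x = 4 pull the centroid to x = 3
    patients = [_p(0, 0, weight=1.0, pid="a"), _p(4, 0, weight=3.0, pid="b")]
    out = update_centroids(patients, np.array([0, 0]), k=1)
    assert out[0].loc == GeoPoint(3.0, 0.0)


def test_empty_cluster_repair_relocates_to_farthest_patient():
    xy = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0]])
    labels = np.array([0, 0, 0])  # cluster 1 is empty
    prev = np.array([[0.0, 0.0], [500.0, 500.0]])
    mincost = np.array([0.0, 1.0, 10.0])  # costs to the assigned station
    out = _update_centroids_xy(xy, np.ones(3), labels, k=2, prev_xy=prev, mincost=mincost)
    assert np.allclose(out[1], [10.0, 0.0])  # farthest patient claims the idle station


def test_update_centroids_empty_cluster_without_context_raises():
    with pytest.raises(ValueError, match="empty"):
        update_centroids([_p(0, 0, pid="a")], np.array([0]), k=2)


# --- k-means ----------------------------------------------------------------


def test_kmeans_two_cluster_enumeration():
    """1-D patients {0,1,9,10}, k=2: the optimal 2-partition has cost 1.0."""
    patients = np.array([[0.0, 0.0], [1.0, 0.0], [9.0, 0.0], [10.0, 0.0]])
    init = np.array([[1.0, 0.0], [9.0, 0.0]])
    sol = kmeans(patients, init, Objective.squared_euclidean(), iters=2)
    assert np.allclose(np.sort(sol.stations_xy[:, 0]), [0.5, 9.5])
    assert sol.cost == pytest.approx(1.0)


def test_kmeans_perfect_cover_zero_cost():
    pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
    for obj in (Objective.euclidean(), Objective.squared_euclidean()):
        sol = kmeans(pts, pts.copy(), obj, iters=1)
        assert sol.cost == 0.0


def test_kmeans_descent_property():
    rng = np.random.default_rng(3)
    xy = rng.uniform(0, 1000, (300, 2))
    obj = Objective.squared_euclidean()
    bound = obj.bind(xy, np.zeros(300), np.ones(300))
    init = xy[rng.choice(300, 5, replace=False)]
    prev = np.inf
    for iters in range(1, 8):
        cost = kmeans_xy(xy, np.ones(300), init, bound, iters).cost
        assert cost <= prev + 1e-9
        prev = cost


# --- random swap ------------------------------------------------------------


def test_random_swap_t0_equals_kmeans():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 1000, (50, 2))
    obj = Objective.squared_euclidean()
    sol = random_swap_xy(xy, k=3, objective=obj, trials=0, seed=7)
    init = xy[np.random.default_rng(7).choice(50, 3, replace=False)]
    ref = kmeans(xy, init, obj, iters=2)
    assert np.array_equal(sol.stations_xy, ref.stations_xy)
    assert sol.cost == ref.cost


def test_random_swap_accepted_costs_strictly_decrease():
    pts, _ = generate_grid_clusters(g=3, n=600, sd=30.0, seed=5, pitch=1000.0)
    sol = random_swap_xy(pts, k=9, objective=Objective.squared_euclidean(), trials=300, seed=2)
    accepted = [c for _, c, acc in sol.history if acc]
    assert all(b < a for a, b in zip(accepted, accepted[1:]))
    assert sol.cost <= accepted[0]
    assert sol.cost == pytest.approx(accepted[-1])


def test_random_swap_deterministic():
    pts, _ = generate_grid_clusters(g=2, n=200, sd=50.0, seed=1, pitch=1000.0)
    a = random_swap_xy(pts, k=4, objective=Objective.euclidean(), trials=100, seed=3)
    b = random_swap_xy(pts, k=4, objective=Objective.euclidean(), trials=100, seed=3)
    assert np.array_equal(a.stations_xy, b.stations_xy)
    assert np.array_equal(a.assignment, b.assignment)
    assert a.history == b.history


def test_random_swap_cost_matches_recomputation():
    pts, _ = generate_grid_clusters(g=3, n=400, sd=40.0, seed=9, pitch=1000.0)
    obj = Objective.euclidean()
    sol = random_swap_xy(pts, k=5, objective=obj, trials=50, seed=4)
    assert sol.cost == pytest.approx(total_cost(obj, pts, sol.stations_xy), rel=1e-12)


def test_random_swap_k_exceeding_distinct_locations_rejected():
    xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="distinct"):
        random_swap_xy(xy, k=3, objective=Objective.euclidean(), trials=0, seed=0)


def test_random_swap_single_blob_station_at_weighted_mean():
    rng = np.random.default_rng(6)
    xy = rng.normal(0.0, 50.0, (400, 2)) + 1000.0
    w = rng.uniform(0.5, 5.0, 400)
    sol = random_swap_xy(xy, k=1, objective=Objective.squared_euclidean(), trials=5, seed=1, weight=w)
    mean = np.average(xy, axis=0, weights=w)
    assert np.allclose(sol.stations_xy[0], mean)


def test_random_swap_domain_wrapper():
    patients = [_p(x, y, pid=f"p{i}") for i, (x, y) in enumerate(np.random.default_rng(0).uniform(0, 100, (30, 2)))]
    cfg = RSConfig(k=3, objective=Objective.euclidean(), trials=20, seed=1)
    sol = random_swap(patients, cfg)
    assert len(sol.stations()) == 3
    assert len(sol.assignment) == 30


# --- building snap ----------------------------------------------------------


def test_snap_to_buildings():
    buildings = PointLayer("buildings", [GeoPoint(0.0, 0.0), GeoPoint(100.0, 0.0)])
    stations = [_s(1, 1, "a"), _s(90, 5, "b"), _s(0, 0, "c")]
    out = snap_to_buildings(stations, buildings)
    assert out[0].loc == GeoPoint(0.0, 0.0)
    assert out[1].loc == GeoPoint(100.0, 0.0)
    assert out[2].loc == GeoPoint(0.0, 0.0)  # already on a building: unchanged
    # two stations may share one building
    shared = snap_to_buildings([_s(1, 0, "a"), _s(2, 0, "b")], buildings)
    assert shared[0].loc == shared[1].loc == GeoPoint(0.0, 0.0)
    with pytest.raises(ValueError):
        snap_to_buildings(stations, PointLayer("buildings", []))


def test_snap_to_buildings_matches_brute_force():
    rng = np.random.default_rng(2)
    b = PointLayer("buildings", [GeoPoint(*p) for p in rng.uniform(0, 1000, (40, 2))])
    s_xy = rng.uniform(0, 1000, (10, 2))
    out = snap_to_buildings(s_xy, b)
    coords = b.coords()
    for i in range(10):
        brute = coords[np.argmin(np.sum((coords - s_xy[i]) ** 2, axis=1))]
        assert np.array_equal(out[i], brute)


# --- centroid index ---------------------------------------------------------


def test_centroid_index_exact_match_is_zero():
    t = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    assert centroid_index(t, t) == 0


def test_centroid_index_duplicate_corner():
    truth = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    found = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.01, 0.0]])
    assert centroid_index(found, truth) == 1


def test_centroid_index_all_on_one_truth():
    truth = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    found = np.array([[0.1, 0.0], [0.2, 0.0], [0.0, 0.1]])
    assert centroid_index(found, truth) == 2


# --- evaluation report ------------------------------------------------------


def test_evaluate_report_conservation(small_region, tmp_path):
    from stationopt import build_overhead_graph
    from stationopt.geodata import patients_to_arrays

    region = small_region
    xy, _, _ = patients_to_arrays(region.patients)
    og = build_overhead_graph(xy, region.network, k=32, seed=1, swap_trials=100)
    report = evaluate(region.patients, region.baseline_stations, og, region.bus_stops)
    assert report["n_patients"] == len(region.patients)
    assert sum(report["per_station_patients"]) + len(report["unreachable_patients"]) == len(
        region.patients
    )
    assert report["total_annual_cost_eur"] == pytest.approx(
        sum(report["per_station_annual_cost_eur"])
    )
    shares = report["mode_share_by_visits"]
    assert sum(shares.values()) == pytest.approx(1.0)
    assert report["mean_travel_time_min"] > 0
    assert report["mean_travel_distance_km"] > 0


def test_evaluate_all_walk_zero_cost():
    from stationopt.overhead import OverheadGraph

    og = OverheadGraph(
        anchors=np.array([[0.0, 0.0], [1000.0, 1000.0]]),
        anchor_nodes=np.array([0, 1]),
        ratio=np.ones((2, 2)),
        speed=np.full((2, 2), 50.0),
        reachable=np.ones((2, 2), dtype=bool),
    )
    patients = [_p(0, 0, pid="a"), _p(500, 0, pid="b", age=85)]
    stations = [_s(100, 0)]
    stops = PointLayer("bus_stops", [GeoPoint(0.0, 10_000.0)])
    report = evaluate(patients, stations, og, stops)
    assert report["total_annual_cost_eur"] == 0.0
    assert report["mode_share_by_visits"]["walk"] == pytest.approx(1.0)


# --- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st

_coords = st.lists(
    st.tuples(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6)), min_size=1, max_size=12
)
# integer grid keeps "distinct" meaningful (no sub-resolution float pairs)
_distinct_coords = st.lists(
    st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
    min_size=1,
    max_size=12,
    unique=True,
)


@settings(derandomize=True, max_examples=100)
@given(found=_coords, truth=_distinct_coords)
def test_centroid_index_bounds(found, truth):
    """CI lies in [0, |truth| - 1]; a perfect match of distinct centres is 0."""
    f = np.asarray(found, dtype=float)
    t = np.asarray(truth, dtype=float)
    ci = centroid_index(f, t)
    assert 0 <= ci <= len(t) - 1
    assert centroid_index(t, t) == 0
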