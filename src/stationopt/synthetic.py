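"""Seeded synthetic-region generator.

Real patient registries cannot be redistributed, so every input layer the
optimizer needs is emulated here with the statistical structure the method
assumes: ~9,333 patients clustered around population hubs of very unequal
size (one dominant "city" hub holding ~40% of patients and a long rural
tail), an elderly age profile (mean 67 y with a mass above 80, which drives
the taxi rule), ~4.7 visits per patient per year, a sparse grid road network
with square "lakes" knocked out so the local detour ratio varies, bus stops
strung along the major roads that pass through the hubs, candidate buildings
clustered at the hubs, and a plausible administrative baseline station set
to compare optimized configurations against.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geodata import (
    GeoPoint,
    Patient,
    PointLayer,
    Station,
    write_patients,
    write_point_layer,
    write_stations,
)
from .road_network import RoadNetwork, build_road_network, write_network_csv


@dataclass
class RegionSpec:
    """Parameters of the synthetic study region (metres, years, counts)."""

    extent: tuple[float, float] = (100_000.0, 100_000.0)
    n_hubs: int = 15
    hub_weights: tuple[float, ...] | None = None  # None -> one 40% city + equal rest
    hub_sd: float = 2_000.0
    n_patients: int = 9333
    age_mean: float = 67.0
    age_sd: float = 12.0
    age_min: int = 18
    p_over_80: float = 0.15
    visits_per_year: float = 4.7
    grid_pitch: float = 5_000.0
    obstacle_fraction: float = 0.12
    major_road_speed: float = 80.0
    minor_road_speed: float = 50.0
    curvature: float = 0.03  # fractional edge meander above the straight chord
    bus_stop_spacing: float = 800.0
    buildings_per_hub: int = 40
    n_stations: int = 23  # size of the administrative baseline configuration
    seed: int = 0

    def resolved_hub_weights(self) -> np.ndarray:
        if self.hub_weights is not None:
            w = np.asarray(self.hub_weights, dtype=float)
            if len(w) != self.n_hubs:
                raise ValueError("hub_weights length must equal n_hubs")
        elif self.n_hubs == 1:
            w = np.array([1.0])
        else:
            rest = 0.6 / (self.n_hubs - 1)
            w = np.array([0.4] + [rest] * (self.n_hubs - 1))
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("hub_weights must be non-negative and sum to 1")
        return w / w.sum()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if not 0 <= self.obstacle_fraction <= 0.5:
            raise ValueError("obstacle_fraction must be in [0, 0.5]")
        for name in ("p_over_80",):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.grid_pitch <= 0 or self.hub_sd <= 0:
            raise ValueError("grid_pitch and hub_sd must be > 0")
        self.resolved_hub_weights()


@dataclass
class Region:
    """All generated layers of one synthetic problem instance."""

    spec: RegionSpec
    patients: list[Patient]
    network: RoadNetwork
    bus_stops: PointLayer
    buildings: PointLayer
    truth_hubs: np.ndarray  # (n_hubs, 2) ground-truth hub centres
    baseline_stations: list[Station] = field(default_factory=list)


def _pick_hub_nodes(nodes: np.ndarray, n_hubs: int, min_sep: float, rng) -> np.ndarray:
    """Greedy max-separation sample of grid nodes; relaxes if infeasible."""
    sep = min_sep
    for _ in range(20):
        order = rng.permutation(len(nodes))
        chosen: list[int] = []
        for i in order:
            if all(np.hypot(*(nodes[i] - nodes[j])) >= sep for j in chosen):
                chosen.append(int(i))
                if len(chosen) == n_hubs:
                    return np.asarray(chosen)
        sep *= 0.8
    raise ValueError(f"cannot place {n_hubs} hubs with any usable separation")


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def generate_region(spec: RegionSpec | None = None, seed: int | None = None) -> Region:
    """Generate every layer of a synthetic problem instance (seed-deterministic)."""
    spec = spec or RegionSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ex, ey = spec.extent

    # --- grid road skeleton -------------------------------------------------
    gx = int(round(ex / spec.grid_pitch)) + 1
    gy = int(round(ey / spec.grid_pitch)) + 1
    ii, jj = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    grid_xy = np.column_stack([ii.ravel() * spec.grid_pitch, jj.ravel() * spec.grid_pitch])

    def nid(i: int, j: int) -> int:
        return i * gy + j

    # --- hubs ---------------------------------------------------------------
    min_sep = max(3.0 * spec.grid_pitch, 5.0 * spec.hub_sd)
    hub_nodes = _pick_hub_nodes(grid_xy, spec.n_hubs, min_sep, rng)
    hubs = grid_xy[hub_nodes]

    # --- lakes: remove grid nodes (never a hub) -----------------------------
    removable = np.setdiff1d(np.arange(len(grid_xy)), hub_nodes)
    n_remove = int(round(spec.obstacle_fraction * len(grid_xy)))
    removed = set(rng.choice(removable, size=min(n_remove, len(removable)), replace=False).tolist())

    # major roads are the rows/columns that pass through a hub
    major_rows = {int(h // gy) for h in hub_nodes}
    major_cols = {int(h % gy) for h in hub_nodes}

    keep = [i for i in range(len(grid_xy)) if i not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    nodes = grid_xy[keep]

    edges: list[tuple[int, int, float, float]] = []
    major_edge_segments: list[tuple[int, int]] = []  # indices into `nodes`
    for i in range(gx):
        for j in range(gy):
            a = nid(i, j)
            if a in removed:
                continue
            for di, dj in ((1, 0), (0, 1)):
                i2, j2 = i + di, j + dj
                if i2 >= gx or j2 >= gy:
                    continue
                b = nid(i2, j2)
                if b in removed:
                    continue
                major = (dj == 1 and i in major_rows) or (di == 1 and j in major_cols)
                speed = spec.major_road_speed if major else spec.minor_road_speed
                length = spec.grid_pitch * (1.0 + spec.curvature * rng.random())
                u, v = remap[a], remap[b]
                edges.append((u, v, length, speed))
                if major:
                    major_edge_segments.append((u, v))

    net = build_road_network(nodes, edges)
    # re-link any components the lakes cut off (bridge at the narrowest gap)
    while net.n_components > 1:
        import networkx as nx

        comps = sorted(nx.connected_components(net.graph), key=len)
        small = np.asarray(sorted(comps[0]))
        rest = np.asarray(sorted(set(range(len(nodes))) - set(comps[0])))
        d = np.linalg.norm(nodes[small][:, None, :] - nodes[rest][None, :, :], axis=2)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        u, v = int(small[a]), int(rest[b])
        edges.append((u, v, float(d[a, b]) * 1.001, spec.minor_road_speed))
        net = build_road_network(nodes, edges)

    hub_node_idx = np.asarray([remap[h] for h in hub_nodes])

    # --- patients -----------------------------------------------------------
    weights = spec.resolved_hub_weights()
    counts = rng.multinomial(spec.n_patients, weights)
    locs = []
    for h, c in zip(hubs, counts):
        locs.append(h + rng.normal(0.0, spec.hub_sd, size=(c, 2)))
    xy = np.clip(np.vstack(locs), [0.0, 0.0], [ex, ey])
    order = rng.permutation(len(xy))
    xy = xy[order]

    ages = np.rint(
        _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_min, 99, spec.n_patients)
    ).astype(int)
    frac80 = float(np.mean(ages >= 80))
    if frac80 < spec.p_over_80:
        deficit = int(round((spec.p_over_80 - frac80) * spec.n_patients))
        young = np.flatnonzero(ages < 80)
        bump = rng.choice(young, size=min(deficit, len(young)), replace=False)
        ages[bump] = rng.integers(80, 96, size=len(bump))
    visits = rng.gamma(shape=4.0, scale=spec.visits_per_year / 4.0, size=spec.n_patients)
    visits = np.maximum(visits, 0.1)

    patients = [
        Patient(id=f"p{i:05d}", loc=GeoPoint(float(x), float(y)), age=int(a), weight=float(w))
        for i, ((x, y), a, w) in enumerate(zip(xy, ages, visits))
    ]

    # --- bus stops along major roads ---------------------------------------
    stops: list[GeoPoint] = [GeoPoint(*nodes[h]) for h in hub_node_idx]
    for u, v in major_edge_segments:
        a, b = nodes[u], nodes[v]
        seg = float(np.hypot(*(b - a)))
        n_stops = int(seg // spec.bus_stop_spacing)
        for s in range(1, n_stops + 1):
            t = s * spec.bus_stop_spacing / seg
            if t < 1.0:
                p = a + t * (b - a)
                stops.append(GeoPoint(float(p[0]), float(p[1])))
    bus_stops = PointLayer(kind="bus_stops", points=stops)

    # --- buildings ----------------------------------------------------------
    bldg: list[GeoPoint] = []
    for h in hubs:
        pts = h + rng.normal(0.0, spec.hub_sd * 0.7, size=(spec.buildings_per_hub, 2))
        bldg += [GeoPoint(float(p[0]), float(p[1])) for p in np.clip(pts, [0, 0], [ex, ey])]
    n_rural = max(1, spec.buildings_per_hub * spec.n_hubs // 10)
    rural = rng.uniform([0, 0], [ex, ey], size=(n_rural, 2))
    bldg += [GeoPoint(float(p[0]), float(p[1])) for p in rural]
    buildings = PointLayer(kind="buildings", points=bldg)
    b_xy = buildings.coords()

    # --- administrative baseline stations -----------------------------------
    # one station near every hub centre regardless of size (the historical,
    # border-respecting pattern), extra stations spread by population
    targets = [h for h in hubs]
    extra = spec.n_stations - spec.n_hubs
    if extra > 0:
        extra_counts = rng.multinomial(extra, weights)
        for h, c, w in zip(hubs, extra_counts, weights):
            for _ in range(c):
                targets.append(h + rng.normal(0.0, spec.hub_sd, size=2))
    elif extra < 0:
        keep_idx = np.argsort(weights)[::-1][: spec.n_stations]
        targets = [hubs[i] for i in sorted(keep_idx)]
    baseline = []
    for i, tgt in enumerate(targets):
        bi = int(np.argmin(np.sum((b_xy - np.asarray(tgt)) ** 2, axis=1)))
        baseline.append(Station(id=f"hs{i:02d}", loc=GeoPoint(*b_xy[bi]), label=f"hub{i}"))

    return Region(
        spec=spec,
        patients=patients,
        network=net,
        bus_stops=bus_stops,
        buildings=buildings,
        truth_hubs=hubs.astype(float),
        baseline_stations=baseline,
    )


def generate_grid_clusters(
    g: int, n: int, sd: float, seed: int = 0, pitch: float = 10_000.0
) -> tuple[np.ndarray, np.ndarray]:
    """A g x g regular grid of Gaussian clusters (a Birch1-style instance).

    Returns (points (n, 2), truth centroids (g*g, 2)); the truth centroids
    are the grid nodes themselves.
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    rng = np.random.default_rng(seed)
    ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    centers = np.column_stack([ii.ravel() * pitch, jj.ravel() * pitch]).astype(float)
    counts = rng.multinomial(n, np.full(g * g, 1.0 / (g * g)))
    pts = np.vstack(
        [c + rng.normal(0.0, sd, size=(k, 2)) for c, k in zip(centers, counts)]
    )
    return pts[rng.permutation(len(pts))], centers


def write_region(region: Region, outdir) -> None:
    """Write every layer in the formats the other modules read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_patients(region.patients, out / "patients.csv")
    write_network_csv(region.network, out / "nodes.csv", out / "edges.csv")
    write_point_layer(region.bus_stops, out / "bus_stops.csv")
    write_point_layer(region.buildings, out / "buildings.csv")
    write_stations(region.baseline_stations, out / "stations_baseline.csv")
    np.savetxt(
        out / "truth_hubs.csv",
        region.truth_hubs,
        fmt="%.17g",
        delimiter=",",
        header="x,y",
        comments="",
    )
    with open(out / "region_spec.json", "w") as fh:
        json.dump(asdict(region.spec), fh, indent=2)
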