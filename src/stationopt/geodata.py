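"""Domain types and readers/writers for the point layers of a location problem.

All coordinates are planar metres in a single projected CRS chosen by the
user (for Finnish data ETRS-TM35FIN is the natural choice).  The tool never
reprojects: Euclidean distances in the objectives only make sense when every
layer of one problem shares one plane.

Layers
------
patients    CSV ``id,x,y[,age][,weight]`` -- demand points; ``weight`` is the
            annual visit count used to annualize objectives (default 1.0,
            i.e. per-visit optimization).
stations    CSV ``id,x,y[,label]`` or GeoJSON Point FeatureCollection.
bus_stops / buildings
            CSV ``x,y`` (an ``id`` column is ignored) or GeoJSON Points.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POINT_LAYER_KINDS = ("bus_stops", "buildings")


class GeoPoint(NamedTuple):
    """A location in planar projected metres (easting, northing)."""

    x: float
    y: float


@dataclass
class Patient:
    """A demand point: home location, age in years, annual visit weight."""

    id: str
    loc: GeoPoint
    age: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.loc.x) and math.isfinite(self.loc.y)):
            raise ValueError(f"patient {self.id!r}: non-finite coordinates")
        if self.age < 0:
            raise ValueError(f"patient {self.id!r}: negative age")
        if not self.weight > 0:
            raise ValueError(f"patient {self.id!r}: weight must be > 0")


@dataclass
class Station:
    """A (candidate) health-station location."""

    id: str
    loc: GeoPoint
    label: str = ""


@dataclass
class PointLayer:
    """A named collection of points (bus stops or candidate buildings)."""

    kind: str
    points: list[GeoPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in POINT_LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return points_to_array(self.points)


# ---------------------------------------------------------------------------
# array conversion helpers (the numeric core works on ndarrays)


def points_to_array(points: Sequence[GeoPoint]) -> np.ndarray:
    """(n, 2) float64 array of coordinates; empty input gives shape (0, 2)."""
    if len(points) == 0:
        return np.empty((0, 2), dtype=float)
    return np.asarray([(p.x, p.y) for p in points], dtype=float)


def patients_to_arrays(
    patients: Sequence[Patient],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a patient list into (xy (n,2), age (n,), weight (n,)) arrays."""
    xy = points_to_array([p.loc for p in patients])
    age = np.asarray([p.age for p in patients], dtype=float)
    weight = np.asarray([p.weight for p in patients], dtype=float)
    return xy, age, weight


def stations_to_array(stations: Sequence[Station]) -> np.ndarray:
    return points_to_array([s.loc for s in stations])


def stations_from_array(xy: np.ndarray, prefix: str = "s") -> list[Station]:
    xy = np.asarray(xy, dtype=float)
    return [Station(id=f"{prefix}{i}", loc=GeoPoint(float(x), float(y))) for i, (x, y) in enumerate(xy)]


# ---------------------------------------------------------------------------
# readers / writers


def _check_unique_ids(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


def _numeric_column(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.index[values.isna() & df[col].notna()]
    if len(bad) > 0:
        raise ValueError(f"{what}: non-numeric {col!r} in row {int(bad[0])}")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ValueError(f"{what}: missing {col!r} in row {row}")
    return values.to_numpy(dtype=float)


def read_patients(path) -> list[Patient]:
    """Read a patient CSV with columns ``id,x,y`` and optional ``age,weight``.

    Missing ``age`` defaults to 0 (never the taxi rule) with a logged warning;
    missing ``weight`` defaults to 1.0 (per-visit optimization).
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"patients CSV {path}: required column {col!r} missing")
    _check_unique_ids(df["id"], "patient")
    x = _numeric_column(df, "x", f"patients CSV {path}")
    y = _numeric_column(df, "y", f"patients CSV {path}")
    if "age" in df.columns:
        age = _numeric_column(df, "age", f"patients CSV {path}")
    else:
        logger.warning("patients CSV %s has no 'age' column; defaulting to 0 (taxi rule never fires)", path)
        age = np.zeros(len(df))
    if "weight" in df.columns:
        weight = _numeric_column(df, "weight", f"patients CSV {path}")
    else:
        weight = np.ones(len(df))
    return [
        Patient(id=str(i), loc=GeoPoint(float(xi), float(yi)), age=int(a), weight=float(w))
        for i, xi, yi, a, w in zip(df["id"], x, y, age, weight)
    ]


def write_patients(patients: Sequence[Patient], path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in patients],
            "x": [p.loc.x for p in patients],
            "y": [p.loc.y for p in patients],
            "age": [p.age for p in patients],
            "weight": [p.weight for p in patients],
        }
    ).to_csv(path, index=False)


def _geojson_points(path) -> list[GeoPoint]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    pts = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: non-Point geometry {geom.get('type')!r}")
        x, y = geom["coordinates"][:2]
        pts.append(GeoPoint(float(x), float(y)))
    return pts


def _geojson_features(path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj.get("features", [])


def read_point_layer(path, kind: str) -> PointLayer:
    """Read bus stops or buildings from CSV (``x,y`` headers) or GeoJSON Points."""
    if str(path).lower().endswith((".geojson", ".json")):
        return PointLayer(kind=kind, points=_geojson_points(path))
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"point CSV {path}: required column {col!r} missing")
    x = _numeric_column(df, "x", f"point CSV {path}")
    y = _numeric_column(df, "y", f"point CSV {path}")
    return PointLayer(kind=kind, points=[GeoPoint(float(a), float(b)) for a, b in zip(x, y)])


def write_point_layer(layer: PointLayer, path) -> None:
    if str(path).lower().endswith((".geojson", ".json")):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                    "properties": {"kind": layer.kind},
                }
                for p in layer.points
            ],
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)
    else:
        pd.DataFrame({"x": [p.x for p in layer.points], "y": [p.y for p in layer.points]}).to_csv(
            path, index=False
        )


def read_stations(path) -> list[Station]:
    """Read stations from CSV ``id,x,y[,label]`` or a GeoJSON Point collection."""
    if str(path).lower().endswith((".geojson", ".json")):
        stations = []
        for i, feat in enumerate(_geojson_features(path)):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"{path}: non-Point geometry {geom.get('type')!r}")
            props = feat.get("properties") or {}
            x, y = geom["coordinates"][:2]
            stations.append(
                Station(
                    id=str(props.get("id", i)),
                    loc=GeoPoint(float(x), float(y)),
                    label=str(props.get("label", "")),
                )
            )
        _check_unique_ids((s.id for s in stations), "station")
        return stations
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"stations CSV {path}: required column {col!r} missing")
    _check_unique_ids(df["id"], "station")
    x = _numeric_column(df, "x", f"stations CSV {path}")
    y = _numeric_column(df, "y", f"stations CSV {path}")
    labels = df["label"].fillna("").astype(str) if "label" in df.columns else [""] * len(df)
    return [
        Station(id=str(i), loc=GeoPoint(float(xi), float(yi)), label=str(lb))
        for i, xi, yi, lb in zip(df["id"], x, y, labels)
    ]


def write_stations(stations: Sequence[Station], path) -> None:
    if str(path).lower().endswith((".geojson", ".json")):
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [s.loc.x, s.loc.y]},
                    "properties": {"id": s.id, "label": s.label},
                }
                for s in stations
            ],
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)
    else:
        pd.DataFrame(
            {
                "id": [s.id for s in stations],
                "x": [s.loc.x for s in stations],
                "y": [s.loc.y for s in stations],
                "label": [s.label for s in stations],
            }
        ).to_csv(path, index=False)
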