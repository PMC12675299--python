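"""Plaque-edge proximity analysis.

Each amyloid plaque is recorded as four points along its perimeter; the four
points, re-ordered counter-clockwise about their centroid, define a closed
quadrilateral outline.  A microglia is *plaque-associated* when its centroid
lies within ``cutoff_um`` (default 15 um) of the nearest plaque edge, and
*distal* otherwise; cells whose centroid is on or inside a plaque outline get
distance 0.  Classification is restricted to cells inside a traced tissue
region (e.g. the cortex).

Geometric primitives are backed by shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .containers import InputError

PLAQUE_ASSOCIATED = "plaque_associated"
DISTAL = "distal"

#: Distance cutoff (um) separating plaque-associated from distal microglia.
DEFAULT_CUTOFF_UM = 15.0


class DegenerateGeometryError(InputError):
    """Collinear/duplicate plaque points or an invalid region polygon."""


def canonical_quadrilateral(points: np.ndarray) -> np.ndarray:
    """Re-order 4 perimeter points counter-clockwise about their centroid.

    The resulting quadrilateral is simple (non-self-intersecting) for any
    4 distinct, non-collinear input points, regardless of the order in which
    the perimeter points were recorded.

    Returns a (4, 2) float array; raises :class:`DegenerateGeometryError` for
    duplicated or collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (4, 2):
        raise DegenerateGeometryError(f"expected 4 two-dimensional points, got shape {pts.shape}")
    if not np.isfinite(pts).all():
        raise DegenerateGeometryError("non-finite plaque perimeter coordinates")
    if len({tuple(p) for p in pts}) != 4:
        raise DegenerateGeometryError("duplicated plaque perimeter points")
    centroid = pts.mean(axis=0)
    angles = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    # tie-break equal angles by radius so near-degenerate inputs stay ordered
    radii = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    order = np.lexsort((radii, angles))
    ordered = pts[order]
    poly = Polygon(ordered)
    if not poly.is_valid or poly.area <= 0:
        raise DegenerateGeometryError("plaque perimeter points are collinear or degenerate")
    return ordered


@dataclass(frozen=True)
class Plaque:
    """An amyloid plaque outlined by exactly 4 perimeter points (um)."""

    plaque_id: int
    perimeter: np.ndarray  # (4, 2), canonical CCW order

    @classmethod
    def from_points(cls, plaque_id: int, points) -> "Plaque":
        return cls(int(plaque_id), canonical_quadrilateral(np.asarray(points, dtype=float)))

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.perimeter)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)


@dataclass(frozen=True)
class RegionPolygon:
    """A manually traced tissue region boundary (e.g. the cortex), in um."""

    name: str
    vertices: np.ndarray  # (n>=3, 2)

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
            raise DegenerateGeometryError("region polygon needs >= 3 two-dimensional vertices")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise DegenerateGeometryError(f"region polygon {self.name!r} is not simple or has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    def to_geojson(self) -> dict:
        ring = [[float(x), float(y)] for x, y in self.vertices]
        ring.append(ring[0])
        return {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "RegionPolygon":
        if obj.get("type") == "FeatureCollection":
            obj = obj["features"][0]
        if obj.get("type") == "Feature":
            name = obj.get("properties", {}).get("name", "region")
            geom = obj["geometry"]
        else:
            name, geom = "region", obj
        if geom.get("type") != "Polygon":
            raise InputError(f"expected a GeoJSON Polygon, got {geom.get('type')!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) > 3 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        return cls(name, ring)

    @classmethod
    def read_geojson(cls, path) -> "RegionPolygon":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


# ---------------------------------------------------------------------------
# point/polygon primitives
# ---------------------------------------------------------------------------

def point_in_polygon(point, polygon) -> bool:
    """Even-odd point-in-polygon test; boundary points count as inside."""
    poly = polygon.polygon if isinstance(polygon, (Plaque, RegionPolygon)) else Polygon(polygon)
    if not poly.is_valid or poly.area <= 0:
        raise DegenerateGeometryError("degenerate polygon in point_in_polygon")
    return bool(poly.covers(Point(point)))


def polygon_area(polygon) -> float:
    """Absolute (shoelace) area of a simple polygon, in um^2."""
    poly = polygon.polygon if isinstance(polygon, (Plaque, RegionPolygon)) else Polygon(polygon)
    if not poly.is_valid or poly.area <= 0:
        raise DegenerateGeometryError("degenerate polygon in polygon_area")
    return float(poly.area)


def distance_to_plaque_edge(point, plaque: Plaque, *, vertices_only: bool = False) -> float:
    """Distance (um) from a cell centroid to the edge of one plaque.

    0 for centroids on or inside the outline; otherwise the minimum Euclidean
    distance to the four boundary segments.  ``vertices_only=True`` measures to
    the 4 recorded perimeter points instead of the segments (sensitivity
    analysis for how the outline is interpreted).
    """
    p = np.asarray(point, dtype=float)
    if vertices_only:
        return float(np.min(np.hypot(*(plaque.perimeter - p).T)))
    return float(plaque.polygon.distance(Point(p)))


def nearest_plaque(point, plaques: list[Plaque], *, vertices_only: bool = False) -> tuple[int, float]:
    """Nearest plaque id and edge distance; ties go to the smallest id."""
    if not plaques:
        raise InputError("no plaques given; request distal-only mode explicitly")
    best_id, best_d = None, np.inf
    for plq in sorted(plaques, key=lambda q: q.plaque_id):
        d = distance_to_plaque_edge(point, plq, vertices_only=vertices_only)
        if d < best_d:
            best_id, best_d = plq.plaque_id, d
    return best_id, float(best_d)


def classify_proximity(distance: float, cutoff: float = DEFAULT_CUTOFF_UM) -> str:
    """Label a cell from its plaque-edge distance.

    Distances up to and including ``cutoff`` are plaque-associated ("within
    15 um"); strictly greater distances are distal ("further than 15 um").
    """
    if not np.isfinite(distance) or distance < 0:
        raise InputError(f"invalid distance {distance!r}; must be a non-negative number")
    return PLAQUE_ASSOCIATED if distance <= cutoff else DISTAL


# ---------------------------------------------------------------------------
# per-cell proximity records
# ---------------------------------------------------------------------------

def compute_proximity(
    cells: pd.DataFrame,
    plaques: list[Plaque],
    region: RegionPolygon | None = None,
    cutoff: float = DEFAULT_CUTOFF_UM,
    *,
    vertices_only: bool = False,
) -> pd.DataFrame:
    """Per-cell nearest-plaque distance and plaque-associated/distal label.

    Returns a DataFrame with columns ``cell_id, nearest_plaque_id,
    distance_um, in_region, label``.  The label is defined only for cells
    inside ``region`` (NA outside); with ``region=None`` every cell is treated
    as in-region.  Distances are computed with vectorized shapely calls.
    """
    if cutoff < 0:
        raise InputError("cutoff must be non-negative")
    if not plaques:
        raise InputError("no plaques given; request distal-only mode explicitly")
    ids = sorted(p.plaque_id for p in plaques)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate plaque ids")

    pts = shapely.points(cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float))
    ordered = sorted(plaques, key=lambda q: q.plaque_id)
    if vertices_only:
        xy = cells[["x_um", "y_um"]].to_numpy(float)
        dists = np.stack(
            [np.min(np.hypot(xy[:, 0, None] - q.perimeter[None, :, 0],
                             xy[:, 1, None] - q.perimeter[None, :, 1]), axis=1)
             for q in ordered]
        )
    else:
        dists = np.stack([shapely.distance(pts, q.polygon) for q in ordered])
    best = np.argmin(dists, axis=0)  # argmin returns the first (= smallest id) on ties
    distance_um = dists[best, np.arange(len(cells))]
    nearest_ids = np.asarray([q.plaque_id for q in ordered])[best]

    if region is None:
        in_region = np.ones(len(cells), dtype=bool)
    else:
        in_region = shapely.covers(region.polygon, pts)

    label = pd.array(
        [classify_proximity(d, cutoff) if ok else pd.NA for d, ok in zip(distance_um, in_region)],
        dtype="string",
    )
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "nearest_plaque_id": nearest_ids,
            "distance_um": distance_um,
            "in_region": in_region,
            "label": label,
        }
    )


def summarize_proximity(
    records: pd.DataFrame,
    plaques: list[Plaque],
    region: RegionPolygon,
) -> dict:
    """Per-plaque associated-cell counts and plaque-free distal density.

    The distal density divides the distal cell count by the region area minus
    the summed plaque areas — the two-dimensional analogue of normalizing
    distal counts to cortex volume minus total plaque volume (the dimension,
    cells per um^2, is recorded in the output).
    """
    in_region = records[records["in_region"]]
    assoc = in_region[in_region["label"] == PLAQUE_ASSOCIATED]
    n_distal = int((in_region["label"] == DISTAL).sum())
    plaque_area = float(sum(p.area_um2 for p in plaques))
    free_area = region.area_um2 - plaque_area
    if free_area <= 0:
        raise InputError(
            f"region area ({region.area_um2:.1f} um^2) does not exceed total plaque area ({plaque_area:.1f} um^2)"
        )
    per_plaque = (
        assoc.groupby("nearest_plaque_id").size().reindex([p.plaque_id for p in plaques], fill_value=0)
    )
    return {
        "n_in_region": int(len(in_region)),
        "n_plaque_associated": int(len(assoc)),
        "n_distal": n_distal,
        "per_plaque_counts": {int(k): int(v) for k, v in per_plaque.items()},
        "region_area_um2": region.area_um2,
        "total_plaque_area_um2": plaque_area,
        "distal_density_per_um2": n_distal / free_area,
        "density_dimension": "cells per um^2 (region area minus total plaque area)",
    }


# ---------------------------------------------------------------------------
# plaque table I/O (plaque_id, x1, y1, ..., x4, y4)
# ---------------------------------------------------------------------------

def plaques_to_frame(plaques: list[Plaque]) -> pd.DataFrame:
    rows = []
    for p in plaques:
        row = {"plaque_id": p.plaque_id}
        for i, (x, y) in enumerate(p.perimeter, start=1):
            row[f"x{i}"] = x
            row[f"y{i}"] = y
        rows.append(row)
    return pd.DataFrame(rows)


def plaques_from_frame(df: pd.DataFrame) -> list[Plaque]:
    cols = [c for pair in ((f"x{i}", f"y{i}") for i in range(1, 5)) for c in pair]
    missing = [c for c in ["plaque_id", *cols] if c not in df.columns]
    if missing:
        raise InputError(f"plaque table is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        pts = np.asarray([[row[f"x{i}"], row[f"y{i}"]] for i in range(1, 5)], dtype=float)
        out.append(Plaque.from_points(int(row["plaque_id"]), pts))
    return out
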