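"""Island attribute metrics for fragmented landscapes.

Computes the per-island predictors used to explain diversity shifts: area
(ha), perimeter (km), the dimensionless shape index SI = P / (2 * sqrt(pi * A))
(1 for a perfect circle, growing with shape complexity), and isolation, the
shortest edge-to-edge distance from an island to the mainland (km).

All geometry is done in a planar projected coordinate system in meters;
hectares and kilometers are converted to meters internally so SI is truly
dimensionless regardless of the mixed units it is conventionally quoted in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InvalidArgumentError, InvalidGeometryError, SchemaError

__all__ = [
    "IslandAttributes",
    "Polygon",
    "shape_index",
    "polygon_area_perimeter",
    "isolation",
    "attributes_from_polygons",
    "read_attributes",
    "write_attributes",
]

#: numerical slack on the isoperimetric bound SI >= 1
SI_EPSILON = 1e-9

_M2_PER_HA = 1e4
_M_PER_KM = 1e3

ATTRIBUTE_COLUMNS = [
    "island_id",
    "area_ha",
    "perimeter_km",
    "shape_index",
    "isolation_km",
    "sampling_area_ha",
    "is_reference",
]


@dataclass(frozen=True)
class Polygon:
    """A simple planar polygon given as an ordered vertex ring in meters.

    The first vertex need not be repeated at the end; closure is implicit.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = [(float(x), float(y)) for x, y in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]  # drop explicit closure
        if len(verts) < 3:
            raise InvalidGeometryError(
                f"polygon needs >= 3 distinct vertices, got {len(verts)}"
            )
        object.__setattr__(self, "vertices", tuple(verts))

    def to_shapely(self) -> _ShapelyPolygon:
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise InvalidGeometryError(
                f"invalid polygon: {shapely.is_valid_reason(poly)}"
            )
        if poly.area <= 0:
            raise InvalidGeometryError("polygon has zero area")
        return poly


class IslandAttributes:
    """Per-island attribute table: area, perimeter, shape index, isolation.

    Thin wrapper over a :class:`pandas.DataFrame` with one row per island and
    the columns of :data:`ATTRIBUTE_COLUMNS`.  ``is_reference`` flags the
    mainland control site, which shift tables include but regression trees
    exclude by default.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [
            c
            for c in ("island_id", "area_ha", "perimeter_km", "isolation_km")
            if c not in table.columns
        ]
        if missing:
            raise SchemaError(f"attribute table missing columns: {missing}")
        table = table.copy()
        if table["island_id"].duplicated().any():
            dupes = table.loc[table["island_id"].duplicated(), "island_id"].tolist()
            raise SchemaError(f"duplicate island_id values: {dupes}")
        if "shape_index" not in table.columns or table["shape_index"].isna().any():
            table["shape_index"] = [
                shape_index(a, p)
                for a, p in zip(table["area_ha"], table["perimeter_km"])
            ]
        if "sampling_area_ha" not in table.columns:
            table["sampling_area_ha"] = np.nan
        if "is_reference" not in table.columns:
            table["is_reference"] = False
        table["is_reference"] = table["is_reference"].astype(bool)
        if (table["area_ha"] <= 0).any() or (table["perimeter_km"] <= 0).any():
            raise SchemaError("area_ha and perimeter_km must be positive")
        if (table["isolation_km"] < 0).any():
            raise SchemaError("isolation_km must be non-negative")
        if (table["shape_index"] < 1.0 - SI_EPSILON).any():
            bad = table.loc[table["shape_index"] < 1.0 - SI_EPSILON, "island_id"]
            raise SchemaError(
                f"shape index below isoperimetric bound 1 for: {bad.tolist()}"
            )
        self.table = table[ATTRIBUTE_COLUMNS].reset_index(drop=True)

    @property
    def island_ids(self) -> list[str]:
        return [str(i) for i in self.table["island_id"]]

    def __len__(self) -> int:
        return len(self.table)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IslandAttributes({len(self)} islands)"


def shape_index(area: float, perimeter: float) -> float:
    """Shape index SI = P / (2 * sqrt(pi * A)).

    Parameters
    ----------
    area : island area in hectares.
    perimeter : island perimeter in kilometers.

    Both are converted to meters before the ratio is taken, so the result is
    dimensionless.  SI equals 1 exactly for a circle and exceeds 1 for every
    other shape (isoperimetric inequality).
    """
    if not (area > 0) or not (perimeter > 0):
        raise InvalidArgumentError(
            f"area and perimeter must be positive, got area={area}, perimeter={perimeter}"
        )
    area_m2 = float(area) * _M2_PER_HA
    perimeter_m = float(perimeter) * _M_PER_KM
    return perimeter_m / (2.0 * math.sqrt(math.pi * area_m2))


def polygon_area_perimeter(poly: Polygon) -> tuple[float, float]:
    """Area (ha) and perimeter (km) of a polygon with vertices in meters.

    Orientation of the vertex ring is irrelevant (|shoelace| is used).
    """
    sp = poly.to_shapely()
    return sp.area / _M2_PER_HA, sp.length / _M_PER_KM


def isolation(island: Polygon, mainland: Polygon) -> float:
    """Shortest edge-to-edge distance between two polygons, in kilometers.

    Returns 0 when the boundaries touch.  Overlapping interiors are rejected:
    an island strictly inside the mainland has no meaningful isolation.
    """
    a = island.to_shapely()
    b = mainland.to_shapely()
    inter = a.intersection(b)
    if inter.area > 0:
        raise InvalidGeometryError("polygons have overlapping interiors")
    return a.distance(b) / _M_PER_KM


def attributes_from_polygons(
    islands: dict[str, Polygon],
    mainland: Polygon,
    sampling_area: dict[str, float] | None = None,
) -> IslandAttributes:
    """Build an attribute table from island polygons and a mainland polygon."""
    rows = []
    for island_id, poly in islands.items():
        a, p = polygon_area_perimeter(poly)
        rows.append(
            {
                "island_id": island_id,
                "area_ha": a,
                "perimeter_km": p,
                "shape_index": shape_index(a, p),
                "isolation_km": isolation(poly, mainland),
                "sampling_area_ha": (sampling_area or {}).get(island_id, np.nan),
                "is_reference": False,
            }
        )
    return IslandAttributes(pd.DataFrame(rows))


def read_polygons(path) -> dict[str, Polygon]:
    """Read polygons from a CSV of island_id,x,y vertex rows (meters)."""
    df = pd.read_csv(path)
    missing = [c for c in ("island_id", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"polygon CSV missing columns: {missing}")
    return {
        str(island_id): Polygon(tuple(zip(grp["x"], grp["y"])))
        for island_id, grp in df.groupby("island_id", sort=False)
    }


def read_attributes(path) -> IslandAttributes:
    """Read an island attribute CSV (shape_index recomputed if absent)."""
    return IslandAttributes(pd.read_csv(path))


def write_attributes(attrs: IslandAttributes, path) -> None:
    attrs.table.to_csv(path, index=False)
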