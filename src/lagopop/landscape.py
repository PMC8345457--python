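"""Fields, feeding areas and diet fractions.

The landscape is a set of planar polygons (fields) carrying a crop schedule
and two adjustable bands: an *inner band* just inside the field boundary and
an *outer band* (field margin) just outside it.  Each nest feeds within a
circular area around its location; the overlap of that disc with the
landscape zones, combined with food-availability weights, yields the
fraction of the diet obtained from each zone.

Coordinates are planar Cartesian in arbitrary but consistent units; no
geographic projection handling is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, Point, box, shape

from .errors import ConfigurationError, GeometryError

__all__ = [
    "CropInterval",
    "Field",
    "Landscape",
    "FeedingArea",
    "DietEntry",
    "DietFractionTable",
    "zone_partition",
    "feeding_zone_overlap",
    "diet_fractions",
    "landscape_from_geojson",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class CropInterval:
    crop: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ConfigurationError("crop interval end before start")


@dataclass
class Field:
    """A field polygon with crop schedule and band widths."""

    field_id: str
    polygon: Polygon
    crop_schedule: tuple[CropInterval, ...] = ()
    inner_band_width: float = 0.0
    outer_band_width: float = 0.0

    def __post_init__(self):
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise GeometryError(f"field {self.field_id}: invalid or empty polygon")
        if self.inner_band_width < 0 or self.outer_band_width < 0:
            raise ConfigurationError(f"field {self.field_id}: negative band width")
        self.crop_schedule = tuple(self.crop_schedule)
        intervals = sorted(self.crop_schedule, key=lambda c: c.start_day)
        for a, b in zip(intervals, intervals[1:]):
            if b.start_day <= a.end_day:
                raise ConfigurationError(
                    f"field {self.field_id}: overlapping crop intervals")

    def crop_on(self, day: int) -> str | None:
        for c in self.crop_schedule:
            if c.start_day <= day <= c.end_day:
                return c.crop
        return None


@dataclass
class Landscape:
    fields: tuple[Field, ...] = ()
    extent: tuple[float, float, float, float] | None = None  # minx,miny,maxx,maxy

    def __post_init__(self):
        self.fields = tuple(self.fields)
        ids = [f.field_id for f in self.fields]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate field ids in landscape")
        if self.extent is not None and self.fields:
            ext = box(*self.extent)
            for f in self.fields:
                if not ext.covers(f.polygon):
                    raise ConfigurationError(
                        f"field {f.field_id} extends outside the landscape extent")

    def field(self, field_id: str) -> Field:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise ConfigurationError(f"unknown field id {field_id!r}")


@dataclass(frozen=True)
class FeedingArea:
    """Circular feeding area of one nest."""

    nest_id: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("feeding radius must be > 0")


@dataclass(frozen=True)
class DietEntry:
    zone_id: str      # "<field_id>/core" etc., or "background"
    food_item: str
    fraction: float


@dataclass
class DietFractionTable:
    """Diet fractions per (zone, food item); fractions sum to 1."""

    entries: tuple[DietEntry, ...]

    def __post_init__(self):
        self.entries = tuple(self.entries)
        total = sum(e.fraction for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"diet fractions sum to {total}, expected 1")
        if any(e.fraction < 0 for e in self.entries):
            raise ConfigurationError("negative diet fraction")


def zone_id(field_id: str, kind: str) -> str:
    return f"{field_id}/{kind}"


def split_zone_id(zid: str) -> tuple[str | None, str]:
    """Return (field_id, zone_kind); background has no field."""
    if zid == BACKGROUND:
        return None, BACKGROUND
    fid, _, kind = zid.rpartition("/")
    if not fid:
        raise ConfigurationError(f"malformed zone id {zid!r}")
    return fid, kind


def zone_partition(fld: Field) -> dict[str, Polygon]:
    """Split a field into core, inner band and outer band polygons.

    The inner band is the ring of ``inner_band_width`` inside the boundary
    (core = the remainder); the outer band is the ring of ``outer_band_width``
    outside the boundary.  Core and inner band partition the field exactly.
    """
    poly = fld.polygon
    if fld.inner_band_width > 0:
        core = poly.buffer(-fld.inner_band_width, join_style="mitre")
        if core.is_empty or core.area <= 0:
            raise GeometryError(
                f"field {fld.field_id}: inner band width {fld.inner_band_width} "
                "swallows the whole field (no core left)")
        inner = poly.difference(core)
    else:
        core, inner = poly, Polygon()
    # mitred joins keep rectangular fields rectangular in the outer ring
    outer = (poly.buffer(fld.outer_band_width, join_style="mitre")
             .difference(poly)
             if fld.outer_band_width > 0 else Polygon())
    return {"core": core, "inner_band": inner, "outer_band": outer}


def feeding_zone_overlap(area: FeedingArea, landscape: Landscape,
                         resolution: float | None = None) -> dict[str, float]:
    """Fraction of the feeding disc falling in each landscape zone.

    The disc is rasterized at ``resolution`` (default radius/100) and each
    cell center is classified; ties between overlapping fields go to the
    first field in declaration order.  Fractions over all zones, including
    the background, sum to 1; the approximation error of any single fraction
    is O(resolution/radius).
    """
    r = area.radius
    if resolution is None:
        resolution = r / 100.0
    if resolution >= r:
        raise ConfigurationError("raster resolution must be smaller than radius")
    cx, cy = area.center
    n = int(np.ceil(2 * r / resolution))
    offsets = (np.arange(n) + 0.5) * resolution - r
    xs, ys = np.meshgrid(cx + offsets, cy + offsets)
    xs, ys = xs.ravel(), ys.ravel()
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    xs, ys = xs[inside], ys[inside]
    total = xs.size

    assigned = np.zeros(total, dtype=bool)
    fractions: dict[str, float] = {}
    for fld in landscape.fields:
        zones = zone_partition(fld)
        # core/inner claim points inside the field; outer claims a ring outside
        for kind in ("core", "inner_band", "outer_band"):
            poly = zones[kind]
            if poly.is_empty:
                continue
            free = ~assigned
            if not free.any():
                break
            hit = np.zeros(total, dtype=bool)
            hit[free] = shapely.contains_xy(poly, xs[free], ys[free])
            if hit.any():
                fractions[zone_id(fld.field_id, kind)] = (
                    fractions.get(zone_id(fld.field_id, kind), 0.0)
                    + hit.sum() / total)
                assigned |= hit
    bg = float((~assigned).sum()) / total
    if bg > 0:
        fractions[BACKGROUND] = bg
    return fractions


def diet_fractions(area_fractions: Mapping[str, float],
                   food_weights: Mapping[tuple[str, str], float]
                   ) -> DietFractionTable:
    """Diet fraction proportional to zone area x food-availability weight.

    ``food_weights`` is keyed by (zone_id, food_item); weights in zones with
    zero area contribute nothing.  Uniform rescaling of all weights leaves
    the result unchanged.
    """
    raw: list[tuple[str, str, float]] = []
    for (zid, item), w in food_weights.items():
        if w < 0:
            raise ConfigurationError("food weights must be >= 0")
        a = area_fractions.get(zid, 0.0)
        if a > 0 and w > 0:
            raw.append((zid, item, a * w))
    total = sum(v for _, _, v in raw)
    if total <= 0:
        raise ConfigurationError(
            "no food source: all weights are zero in the occupied zones")
    return DietFractionTable(tuple(
        DietEntry(zid, item, v / total) for zid, item, v in raw))


def landscape_from_geojson(source) -> Landscape:
    """Build a landscape from a GeoJSON FeatureCollection.

    Each feature must be a Polygon; per-feature ``properties`` may carry
    ``field_id``, ``inner_band_width``, ``outer_band_width`` and a
    ``crop_schedule`` list of {crop, start_day, end_day}.
    """
    if isinstance(source, (str, bytes)):
        data = json.loads(source)
    elif hasattr(source, "read"):
        data = json.load(source)
    else:
        data = source
    if data.get("type") != "FeatureCollection":
        raise ConfigurationError("expected a GeoJSON FeatureCollection")
    fields = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ConfigurationError("only Polygon features are supported")
        schedule = tuple(CropInterval(c["crop"], int(c["start_day"]),
                                      int(c["end_day"]))
                         for c in props.get("crop_schedule", []))
        fields.append(Field(
            field_id=str(props.get("field_id", f"field_{i}")),
            polygon=geom,
            crop_schedule=schedule,
            inner_band_width=float(props.get("inner_band_width", 0.0)),
            outer_band_width=float(props.get("outer_band_width", 0.0)),
        ))
    return Landscape(fields=tuple(fields))
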