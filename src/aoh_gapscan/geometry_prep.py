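"""Validate, repair, and dissolve site polygons; align layers to one frame.

Site networks assembled from many national inventories routinely contain
overlapping polygons, self-intersecting rings, and records with no digital
boundary at all.  Before any overlap is measured the sites are (1) repaired
where a deterministic node-and-rebuild fixes them, (2) dropped to a ledger
where it does not, and (3) dissolved into a single union geometry so that
overlapping sites are not double counted in coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .frames import WORLD, Frame, FrameError, transform_geometry

RECORD_COLUMNS = ["site_id", "name", "country", "region", "iba_flag", "geometry", "extent_km2"]
LEDGER_COLUMNS = ["site_id", "reason"]

#: Drop reasons used in the ledger.
REASON_INVALID = "invalid-geometry"
REASON_EMPTY = "empty"
REASON_NO_BOUNDARY = "no-boundary"


@dataclass
class SiteSet:
    """Repaired site records, their dissolved union, and a dropped-site ledger.

    Every raw input site appears exactly once: either as a retained record or
    as a ledger row (site_id, reason).
    """

    records: pd.DataFrame
    ledger: pd.DataFrame
    union: BaseGeometry | None = None
    frame: Frame = field(default_factory=lambda: WORLD)

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_dropped(self) -> int:
        return len(self.ledger)

    def dissolve(self) -> BaseGeometry:
        """Compute (and cache) the dissolved union of retained sites."""
        if self.union is None:
            self.union = dissolve_sites(self.records)
        return self.union


def _polygonal_part(geom: BaseGeometry) -> BaseGeometry | None:
    """Extract the polygonal component of a repaired geometry, if any."""
    if geom.is_empty:
        return None
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom if geom.area > 0 else None
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            return None
        merged = shapely.union_all(polys)
        return merged if merged.area > 0 else None
    return None


def repair_geometries(raw_sites) -> SiteSet:
    """Repair raw site polygons; drop what cannot be repaired, with reasons.

    Policy: one deterministic node-and-rebuild repair attempt
    (``shapely.validation.make_valid``, which splits self-intersecting rings
    at their crossing points and preserves enclosed area).  A site is dropped
    to the ledger when it has no boundary geometry at all (``no-boundary``),
    an empty geometry (``empty``), or when repair yields no polygonal area
    (``invalid-geometry``).  Empty input -> empty SiteSet, no error.

    ``raw_sites`` is an iterable of objects/mappings with fields
    site_id, name, country, region, iba_flag, geometry (shapely or None).
    """
    records, ledger = [], []
    for site in raw_sites:
        get = site.get if isinstance(site, dict) else lambda k, s=site: getattr(s, k, None)
        sid = get("site_id")
        geom = get("geometry")
        if geom is None:
            ledger.append((sid, REASON_NO_BOUNDARY))
            continue
        if geom.is_empty:
            ledger.append((sid, REASON_EMPTY))
            continue
        if not geom.is_valid:
            geom = make_valid(geom)
        poly = _polygonal_part(geom)
        if poly is None or not poly.is_valid:
            ledger.append((sid, REASON_INVALID))
            continue
        records.append((
            sid, get("name"), get("country"), get("region"),
            bool(get("iba_flag")), poly, poly.area,
        ))
    return SiteSet(
        records=pd.DataFrame(records, columns=RECORD_COLUMNS),
        ledger=pd.DataFrame(ledger, columns=LEDGER_COLUMNS),
    )


def dissolve_sites(records: pd.DataFrame) -> BaseGeometry:
    """Union all retained site polygons into one dissolved geometry.

    The union area is <= the sum of per-site areas, with equality exactly
    when sites are pairwise disjoint; this is what makes per-map coverage
    percents well defined (bounded by 100).
    """
    geoms = list(records["geometry"]) if len(records) else []
    if not geoms:
        return shapely.Polygon()
    return shapely.union_all(geoms)


def align_projection(layer, source: Frame, target: Frame):
    """Re-express a geometry, or an iterable of geometries, in ``target`` frame.

    Both frames are planar affine maps to the shared world, so the transform
    is exact: round-tripping returns vertices to floating-point precision and
    equal-area frames preserve area to ~1e-9 relative.
    Missing frame metadata is a format error.
    """
    if source is None or target is None:
        raise FrameError("layer frame metadata is missing")
    if isinstance(layer, BaseGeometry):
        return transform_geometry(layer, source, target)
    return [transform_geometry(g, source, target) for g in layer]
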