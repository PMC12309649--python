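"""Species-map x site overlap matrix: the computational core of the gap analysis.

Each species-season is represented by a binary equal-area habitat raster
(an Area of Habitat map).  Overlap of a map with a site polygon is measured
by the cell-center rule: a suitable cell contributes its full area
``cell_km**2`` iff its center falls inside (or on the boundary of) the
polygon.  This is the standard zonal-statistics default and an unbiased
area estimator for equal-area grids.

The full matrix over all (map, site) pairs is stored sparsely — only
nonzero overlaps are materialized — while the cross-product combination
count remains available in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .frames import WORLD, Frame, FrameError, cell_centers

SEASONS = ("resident", "breeding", "nonbreeding")


class InputError(ValueError):
    """Malformed analysis input (duplicate ids, bad season codes, ...)."""


@dataclass
class SpeciesMap:
    """One binary suitable-habitat raster for one species-season.

    Suitable cells are stored sparsely as parallel ``(rows, cols)`` index
    arrays into a grid of ``shape`` cells of ``cell_km`` km on a side.
    ``frame`` maps (col, row) grid coordinates to world km (y up).
    """

    map_id: str
    species_id: str
    season: str
    rows: np.ndarray
    cols: np.ndarray
    shape: tuple[int, int]
    cell_km: float
    frame: Frame

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise InputError(f"unknown season {self.season!r}")
        self.rows = np.asarray(self.rows, dtype=np.int32)
        self.cols = np.asarray(self.cols, dtype=np.int32)
        if self.rows.shape != self.cols.shape:
            raise InputError("rows and cols must be parallel arrays")

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    @property
    def cell_area_km2(self) -> float:
        return float(self.cell_km) ** 2

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of suitable-cell centers."""
        return cell_centers(self.rows, self.cols, self.frame)

    def to_raster(self) -> np.ndarray:
        grid = np.zeros(self.shape, dtype=np.uint8)
        grid[self.rows, self.cols] = 1
        return grid

    @classmethod
    def from_raster(cls, map_id: str, species_id: str, season: str,
                    grid: np.ndarray, cell_km: float, frame: Frame) -> "SpeciesMap":
        rows, cols = np.nonzero(np.asarray(grid))
        return cls(map_id, species_id, season, rows, cols, tuple(grid.shape), cell_km, frame)


def mask_area(smap: SpeciesMap, polygon: BaseGeometry,
              polygon_frame: Frame | None = WORLD) -> float:
    """Suitable area (km^2) of ``smap`` inside ``polygon``, by the cell-center rule.

    ``polygon_frame`` is the frame the polygon's coordinates are expressed in;
    it must be the shared world frame of the raster.  ``None`` (missing frame
    metadata) is an error.
    """
    if polygon_frame is None:
        raise FrameError("polygon carries no frame metadata")
    if polygon_frame != WORLD:
        raise FrameError(
            f"polygon frame {polygon_frame.name!r} does not match the analysis "
            "world frame; align layers first (geometry_prep.align_projection)"
        )
    if smap.n_cells == 0 or polygon.is_empty:
        return 0.0
    x, y = smap.centers()
    minx, miny, maxx, maxy = polygon.bounds
    near = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
    if not near.any():
        return 0.0
    # intersects == covers for points: centers on the boundary count as inside
    inside = shapely.intersects_xy(polygon, x[near], y[near])
    return float(inside.sum()) * smap.cell_area_km2


MATRIX_COLUMNS = [
    "map_id", "site_id", "area_km2", "pct_of_map",
    "site_extent_km2", "country", "region", "iba_flag",
]


@dataclass
class OverlapMatrix:
    """Sparse cross-product of species maps x retained sites.

    ``records`` holds one row per (map, site) pair with nonzero overlap;
    zero-overlap pairs are implicit but counted by :attr:`combination_count`.
    """

    records: pd.DataFrame
    n_maps: int
    n_sites: int
    map_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def combination_count(self) -> int:
        return combination_count(self.n_maps, self.n_sites, 0)

    def percent(self, map_id: str, site_id: str) -> float:
        """Percent of one map's habitat in one site (0.0 for implicit zeros)."""
        sel = self.records[(self.records.map_id == map_id) & (self.records.site_id == site_id)]
        if sel.empty:
            return 0.0
        return float(sel.pct_of_map.iloc[0])


def combination_count(n_maps: int, n_raw_sites: int, n_dropped: int = 0) -> int:
    """Closed-form size of the full (map, retained-site) cross-product.

    Retained sites are the raw sites minus those dropped during geometry
    repair; the count is exact and never requires materializing records.
    """
    if n_dropped > n_raw_sites:
        raise InputError("more dropped sites than raw sites")
    return int(n_maps) * (int(n_raw_sites) - int(n_dropped))


def build_matrix(maps, siteset) -> OverlapMatrix:
    """Compute overlap records for every (map, retained site) pair.

    ``siteset`` is a :class:`~aoh_gapscan.geometry_prep.SiteSet` (repaired
    records).  Zero overlaps are not stored; the cross-product dimensions are
    recorded so the combination count stays exact.
    """
    map_ids = [m.map_id for m in maps]
    if len(set(map_ids)) != len(map_ids):
        raise InputError("duplicate map ids in input")
    rows = []
    totals = {}
    site_records = siteset.records
    geoms = list(site_records["geometry"])
    bounds = np.array([g.bounds for g in geoms]) if geoms else np.empty((0, 4))
    for smap in maps:
        totals[smap.map_id] = smap.total_area_km2
        if smap.n_cells == 0:
            continue
        x, y = smap.centers()
        mminx, mmaxx = x.min() - smap.cell_km, x.max() + smap.cell_km
        mminy, mmaxy = y.min() - smap.cell_km, y.max() + smap.cell_km
        for i, rec in enumerate(site_records.itertuples()):
            bminx, bminy, bmaxx, bmaxy = bounds[i]
            if bminx > mmaxx or bmaxx < mminx or bminy > mmaxy or bmaxy < mminy:
                continue
            area = mask_area(smap, geoms[i])
            if area > 0:
                rows.append((
                    smap.map_id, rec.site_id, area,
                    100.0 * area / smap.total_area_km2,
                    rec.extent_km2, rec.country, rec.region, rec.iba_flag,
                ))
    records = pd.DataFrame(rows, columns=MATRIX_COLUMNS)
    return OverlapMatrix(
        records=records,
        n_maps=len(maps),
        n_sites=len(site_records),
        map_totals=pd.Series(totals, name="total_area_km2"),
    )


def summarize_map(smap: SpeciesMap, union_geom: BaseGeometry) -> dict:
    """Per-map representation core fields against the dissolved site union.

    Because the union is dissolved, overlapping sites are never double
    counted and the percent is guaranteed to lie in [0, 100].  Zero-area
    maps are flagged unusable (they cannot yield a meaningful percent).
    """
    unusable = smap.n_cells == 0
    if unusable:
        area_in = float("nan")
        pct = float("nan")
    else:
        area_in = mask_area(smap, union_geom)
        pct = 100.0 * area_in / smap.total_area_km2
    return {
        "map_id": smap.map_id,
        "species_id": smap.species_id,
        "season": smap.season,
        "total_area_km2": smap.total_area_km2,
        "area_in_union_km2": area_in,
        "pct_in_union": pct,
        "unusable": unusable,
    }


def summarize_maps(maps, union_geom: BaseGeometry, *, warn_unusable: bool = True) -> pd.DataFrame:
    """Apply :func:`summarize_map` over a collection; one row per map."""
    out = pd.DataFrame([summarize_map(m, union_geom) for m in maps])
    n_bad = int(out["unusable"].sum()) if len(out) else 0
    if n_bad and warn_unusable:
        warnings.warn(f"{n_bad} zero-area maps flagged unusable and excluded from percents")
    return out
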