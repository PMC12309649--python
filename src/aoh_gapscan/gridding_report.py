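"""Equal-area gridded gap maps, centroid point layers, and the overlap histogram.

Species footprints are aggregated onto a coarse equal-area grid (100-km
cells by default): per-cell species richness, the count and proportion of
species flagged as underrepresented, and the count of trigger species.
Migratory species contribute the union of their seasonal maps, counted
once per cell; flags come from the species-level rollup ("underrepresented
in at least one seasonal range").  A centroid point layer locates the maps
with no site overlap and the threatened maps below the lower threshold,
and a fixed-width histogram summarises the full percent-overlap
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import WORLD, Frame, FrameError
from .overlap_engine import SpeciesMap


@dataclass(frozen=True)
class GridSpec:
    """Coarse analysis grid in the world frame (km, y up, origin bottom-left)."""

    cell_km: float
    rows: int
    cols: int
    x0: float = 0.0
    y0: float = 0.0
    frame: Frame = WORLD

    @classmethod
    def for_extent(cls, width_km: float, height_km: float, cell_km: float = 100.0) -> "GridSpec":
        return cls(cell_km=cell_km,
                   rows=int(np.ceil(height_km / cell_km)),
                   cols=int(np.ceil(width_km / cell_km)))

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid (row, col) of world points; row 0 is the TOP row of the grid."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_km).astype(int)
        row = self.rows - 1 - np.floor((np.asarray(y) - self.y0) / self.cell_km).astype(int)
        return row, col


@dataclass
class GridSummary:
    """Per-cell gap metrics on one grid."""

    grid: GridSpec
    richness: np.ndarray
    under_count: np.ndarray
    proportion_under: np.ndarray   # NaN where richness == 0
    trigger_count: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.richness >= 0)
        return pd.DataFrame({
            "row": rows, "col": cols,
            "richness": self.richness[rows, cols],
            "under_count": self.under_count[rows, cols],
            "proportion_under": self.proportion_under[rows, cols],
            "trigger_count": self.trigger_count[rows, cols],
        })


def species_footprints(maps: list[SpeciesMap]) -> dict[str, list[SpeciesMap]]:
    """Group maps by species; the footprint is the union of seasonal maps."""
    out: dict[str, list[SpeciesMap]] = {}
    for m in maps:
        out.setdefault(m.species_id, []).append(m)
    return out


def _presence_cells(maps_of_species: list[SpeciesMap], grid: GridSpec) -> set[tuple[int, int]]:
    cells: set[tuple[int, int]] = set()
    for m in maps_of_species:
        if m.n_cells == 0:
            continue
        x, y = m.centers()
        if m.frame is None:
            raise FrameError(f"map {m.map_id} carries no frame")
        r, c = grid.cell_of(x, y)
        ok = (r >= 0) & (r < grid.rows) & (c >= 0) & (c < grid.cols)
        cells.update(zip(r[ok].tolist(), c[ok].tolist()))
    return cells


def stack_to_grid(footprints: dict[str, list[SpeciesMap]], grid: GridSpec) -> np.ndarray:
    """Species richness per grid cell: each species counted once per cell."""
    richness = np.zeros((grid.rows, grid.cols), dtype=np.int32)
    for _, maps in sorted(footprints.items()):
        for r, c in _presence_cells(maps, grid):
            richness[r, c] += 1
    return richness


def gap_grids(footprints: dict[str, list[SpeciesMap]], grid: GridSpec,
              under_flags: dict[str, bool],
              trigger_flags: dict[str, bool] | None = None,
              warn_missing: bool = True) -> GridSummary:
    """Richness, underrepresented-count/proportion, and trigger-count grids.

    ``under_flags``/``trigger_flags`` map species_id -> bool (typically the
    species rollup's "under in at least one seasonal range" and the trigger
    attribute).  Species missing from ``under_flags`` are excluded entirely,
    with a warning.
    """
    import warnings

    trigger_flags = trigger_flags or {}
    missing = [s for s in footprints if s not in under_flags]
    if missing and warn_missing:
        warnings.warn(f"{len(missing)} species missing from flag table; excluded")
    kept = {s: m for s, m in footprints.items() if s in under_flags}

    richness = np.zeros((grid.rows, grid.cols), dtype=np.int32)
    under = np.zeros_like(richness)
    trig = np.zeros_like(richness)
    for sid, maps in sorted(kept.items()):
        cells = _presence_cells(maps, grid)
        for r, c in cells:
            richness[r, c] += 1
            if under_flags[sid]:
                under[r, c] += 1
            if trigger_flags.get(sid, False):
                trig[r, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(richness > 0, under / np.maximum(richness, 1), np.nan)
    return GridSummary(grid=grid, richness=richness, under_count=under,
                       proportion_under=prop, trigger_count=trig)


def centroid_points(maps: list[SpeciesMap], summaries: pd.DataFrame,
                    lower_threshold: float = 5.0,
                    redlist_subset: tuple[str, ...] = ("EN", "CR")) -> pd.DataFrame:
    """Area-weighted centroids of the most exposed maps, as a point table.

    Qualifying maps: percent-in-union exactly 0 (no overlap), plus maps of
    species in ``redlist_subset`` strictly below ``lower_threshold``.  The
    centroid of a binary equal-area raster is the mean of its suitable-cell
    centers.  Empty maps are skipped with a warning.
    """
    import warnings

    by_id = {m.map_id: m for m in maps}
    sel = summaries[~summaries["pct_in_union"].isna()]
    qualifying = sel[(sel["pct_in_union"] == 0.0) |
                     (sel["redlist"].isin(redlist_subset) &
                      (sel["pct_in_union"] < lower_threshold))]
    rows = []
    for rec in qualifying.itertuples():
        m = by_id.get(rec.map_id)
        if m is None:
            continue
        if m.n_cells == 0:
            warnings.warn(f"map {rec.map_id} is empty; no centroid")
            continue
        x, y = m.centers()
        rows.append({
            "map_id": rec.map_id, "species_id": rec.species_id,
            "season": rec.season, "x_km": float(x.mean()), "y_km": float(y.mean()),
            "class": None,   # filled from the summary table below
            "redlist": rec.redlist,
        })
    out = pd.DataFrame(rows, columns=["map_id", "species_id", "season",
                                      "x_km", "y_km", "class", "redlist"])
    if len(out):
        cls = summaries.set_index("map_id")["class"]
        out["class"] = out["map_id"].map(cls)
    return out


def overlap_histogram(percents, bin_width: float = 5.0) -> pd.DataFrame:
    """Fixed-width histogram of percent overlaps on [0, 100].

    Bins are left-closed right-open except the final bin, which is closed at
    100; counts sum to the number of input maps.
    """
    p = np.asarray(list(percents), dtype=float)
    if p.size and ((p < 0) | (p > 100)).any():
        raise ValueError("percents outside [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(p, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })


# ----------------------------------------------------------------------
# Minimal matplotlib renderers (no cartographic styling by design)
# ----------------------------------------------------------------------

def plot_overlap_histogram(hist: pd.DataFrame, ax=None,
                           thresholds: tuple[float, float] = (5.0, 8.0)):
    """Bar plot of the overlap histogram with the two threshold lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(hist["bin_left"], hist["count"],
           width=hist["bin_right"] - hist["bin_left"], align="edge",
           edgecolor="white")
    for t in thresholds:
        ax.axvline(t, linestyle="--", linewidth=1)
    ax.set_xlabel("% of habitat map inside site union")
    ax.set_ylabel("number of maps")
    return ax


def plot_grid(arr: np.ndarray, grid: GridSpec, ax=None, label: str = ""):
    """Image plot of one gridded metric in world km coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (grid.x0, grid.x0 + grid.cols * grid.cell_km,
              grid.y0, grid.y0 + grid.rows * grid.cell_km)
    im = ax.imshow(arr, origin="upper", extent=extent)
    ax.figure.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    return ax
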