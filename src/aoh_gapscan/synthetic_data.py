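"""Synthetic landscapes, species habitat maps, site polygons, and attributes.

This module fabricates a miniature world with the statistical structure the
gap analysis assumes, so every downstream stage (geometry repair, overlap
matrix, representation thresholds, null models, gridding) is testable
without the proprietary global datasets:

* an equal-area grid landscape with a terrestrial mask, small disconnected
  island components, and spatially autocorrelated habitat classes;
* per-species binary habitat maps grown by seeded random accretion, with a
  right-skewed (log-normal) range-size distribution and a configurable
  fraction of island-confined species; migratory species get separate
  breeding and nonbreeding maps;
* site polygons whose dissolved union covers a configurable fraction of
  terrestrial cells, with pairwise overlaps, optional injected invalid
  (collapsed self-intersecting) geometries, and a "targeted" placement mode
  that concentrates sites on threatened species' habitat;
* an attribute table (order, family, Red List category, habitat codes with
  importance, trigger status, year of taxonomic recognition).

The range-size distribution defaults are placeholders chosen for shape
(right-skewed, with island-like tiny ranges), not fits to any real dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .frames import Frame, raster_frame
from .overlap_engine import SpeciesMap


class ParameterError(ValueError):
    """Scenario configuration is inconsistent or out of range."""


# --------------------------------------------------------------------------
# Habitat taxonomy fixture: two-level code table (level-1 class, level-2
# subclass), mirroring the structure of the IUCN habitat classification.
# --------------------------------------------------------------------------
HABITAT_TAXONOMY = pd.DataFrame(
    [
        ("1", "Forest", None),
        ("1.1", "Forest - Boreal", "1"),
        ("1.2", "Forest - Temperate", "1"),
        ("1.5", "Forest - Subtropical/Tropical Dry", "1"),
        ("1.6", "Forest - Subtropical/Tropical Moist Lowland", "1"),
        ("1.9", "Forest - Subtropical/Tropical Moist Montane", "1"),
        ("3", "Shrubland", None),
        ("3.4", "Shrubland - Temperate", "3"),
        ("3.8", "Shrubland - Mediterranean", "3"),
        ("4", "Grassland", None),
        ("4.4", "Grassland - Temperate", "4"),
        ("4.6", "Grassland - Subtropical/Tropical Seasonally Wet", "4"),
        ("5", "Wetlands (inland)", None),
        ("5.1", "Wetlands - Permanent Rivers", "5"),
        ("5.4", "Wetlands - Bogs and Marshes", "5"),
        ("8", "Desert", None),
        ("8.2", "Desert - Temperate", "8"),
    ],
    columns=["code", "name", "parent"],
)

LEVEL2_CODES = tuple(HABITAT_TAXONOMY.loc[HABITAT_TAXONOMY.parent.notna(), "code"])

REDLIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD")
THREATENED = frozenset({"VU", "EN", "CR"})
#: Severity order used when coupling threat status to range size.
_SEVERITY = {"CR": 5, "EN": 4, "VU": 3, "NT": 2, "DD": 1, "LC": 0}

#: Level-2 codes typical of extensive high-latitude habitats; the generator
#: preferentially assigns them to widespread least-concern species.
WIDESPREAD_HABITATS = ("1.1", "1.2", "4.4")
#: Level-2 codes typical of species-rich tropical habitats; preferentially
#: assigned to small-ranged threatened species.
RESTRICTED_HABITATS = ("1.6", "1.9")

_COUNTRIES = [
    ("Aldera", "North"), ("Borreal", "North"), ("Cispina", "Equatorial"),
    ("Dorsia", "Equatorial"), ("Elmira", "South"), ("Feronia", "South"),
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic world; identical config + seed => identical world."""

    # landscape
    rows: int = 200
    cols: int = 200
    cell_km: float = 10.0
    terrestrial_fraction: float = 0.55
    n_islands: int = 10
    island_size_cells: tuple[int, int] = (2, 10)
    habitat_smoothing_cells: float = 6.0
    # species
    n_species: int = 300
    migratory_fraction: float = 0.12
    range_meanlog: float = math.log(60.0)   # log of cell count; placeholder
    range_sdlog: float = 1.1                # placeholder scale
    max_range_cells: int = 4000
    island_fraction: float = 0.12
    threat_smallrange_assoc: float = 0.6    # 0 = none, 1 = rank-perfect
    habitat_threat_bias: float = 3.0        # multiplicative habitat reweighting
    single_major_fraction: float = 0.6
    recent_split_fraction: float = 0.12
    redlist_probs: tuple = (("LC", 0.70), ("NT", 0.09), ("VU", 0.09),
                            ("EN", 0.06), ("CR", 0.04), ("DD", 0.02))
    habitat_probs: tuple = (("1.1", 0.10), ("1.2", 0.10), ("1.5", 0.08),
                            ("1.6", 0.16), ("1.9", 0.10), ("3.4", 0.08),
                            ("3.8", 0.05), ("4.4", 0.10), ("4.6", 0.07),
                            ("5.1", 0.06), ("5.4", 0.04), ("8.2", 0.06))
    # sites
    n_sites: int = 80
    site_coverage: float = 0.0801
    coverage_tolerance: float = 0.005       # +/- 0.5 percentage points
    site_mode: str = "random"               # or "targeted"
    n_invalid_sites: int = 0
    n_missing_boundary: int = 0
    site_size_sdlog: float = 0.35
    max_site_extent_km2: float | None = None
    iba_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 10 or self.cols < 10:
            raise ParameterError("grid must be at least 10x10")
        if self.cell_km <= 0:
            raise ParameterError("cell size must be positive")
        if not (0 < self.site_coverage < 1):
            raise ParameterError("site coverage fraction must lie in (0, 1)")
        if not (0 < self.terrestrial_fraction <= 1):
            raise ParameterError("terrestrial fraction must lie in (0, 1]")
        if self.site_mode not in ("random", "targeted"):
            raise ParameterError(f"unknown site mode {self.site_mode!r}")
        for name, probs in (("redlist_probs", self.redlist_probs),
                            ("habitat_probs", self.habitat_probs)):
            total = sum(p for _, p in probs)
            if abs(total - 1.0) > 1e-8:
                raise ParameterError(f"{name} must sum to 1 (got {total})")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generation stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class Landscape:
    """Equal-area grid world: terrestrial mask + habitat classes + islands."""

    rows: int
    cols: int
    cell_km: float
    terrestrial: np.ndarray            # bool (rows, cols)
    habitat: np.ndarray                # object codes, "" on non-land
    component: np.ndarray              # int labels of terrestrial components, 0 = sea
    island_labels: tuple[int, ...]     # component labels that are islands
    frame: Frame
    seed: int

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km ** 2

    @property
    def n_terrestrial(self) -> int:
        return int(self.terrestrial.sum())

    @property
    def extent_km(self) -> tuple[float, float]:
        return self.cols * self.cell_km, self.rows * self.cell_km


def _grow_blob(allowed: np.ndarray, taken: np.ndarray, start, target: int,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Eden-style random accretion of a connected blob inside ``allowed``.

    ``start`` is one (row, col) seed or a list of frontier cells to continue
    from.  Returns (rows, cols) of the grown cells; stops early if the
    reachable region is exhausted.  ``taken`` is updated in place.
    """
    nrows, ncols = allowed.shape
    frontier = [start] if isinstance(start, tuple) else list(start)
    grown_r, grown_c = [], []
    while frontier and len(grown_r) < target:
        i = rng.integers(len(frontier))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        r, c = frontier.pop()
        if taken[r, c]:
            continue
        taken[r, c] = True
        grown_r.append(r)
        grown_c.append(c)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and allowed[rr, cc] and not taken[rr, cc]:
                frontier.append((rr, cc))
    return np.array(grown_r, dtype=np.int32), np.array(grown_c, dtype=np.int32)


def generate_landscape(config: ScenarioConfig) -> Landscape:
    """Build the terrestrial mask, island components, and habitat patches."""
    rng = config.rng(1)
    rows, cols = config.rows, config.cols
    n_cells = rows * cols
    n_land = int(round(config.terrestrial_fraction * n_cells))

    terrestrial = np.zeros((rows, cols), dtype=bool)
    if config.terrestrial_fraction >= 0.999:
        terrestrial[:] = True
    else:
        # Islands first (small blobs kept 8-disconnected from each other),
        # then one connected mainland sized so the total land count is exact.
        island_sizes = []
        if config.n_islands > 0:
            lo, hi = config.island_size_cells
            island_sizes = list(rng.integers(lo, hi + 1, size=config.n_islands))
        grown_island = 0
        for size in island_sizes:
            forbidden = ndimage.binary_dilation(terrestrial, structure=np.ones((3, 3)))
            candidates = np.flatnonzero(~forbidden)
            if candidates.size == 0:
                warnings.warn("no room left for an island; skipping")
                continue
            start_flat = int(rng.choice(candidates))
            start_rc = (start_flat // cols, start_flat % cols)
            taken_isl = np.zeros_like(terrestrial)
            ir, ic = _grow_blob(~forbidden, taken_isl, start_rc, int(size), rng)
            terrestrial[ir, ic] = True
            grown_island += ir.size
        n_main = max(1, n_land - grown_island)
        forbidden = ndimage.binary_dilation(terrestrial, structure=np.ones((3, 3)))
        allowed = ~forbidden
        start = (rows // 2, cols // 2)
        if not allowed[start]:
            start_flat = int(rng.choice(np.flatnonzero(allowed)))
            start = (start_flat // cols, start_flat % cols)
        taken = np.zeros_like(terrestrial)
        mr, mc = _grow_blob(allowed, taken, start, n_main, rng)
        if mr.size < n_main:
            warnings.warn("mainland growth exhausted free space before target size")
        terrestrial[mr, mc] = True

    component, _ = ndimage.label(terrestrial)
    sizes = np.bincount(component.reshape(-1))
    sizes[0] = 0
    mainland_label = int(sizes.argmax()) if sizes.size > 1 else 0
    island_labels = tuple(int(l) for l in np.nonzero(sizes)[0] if l != mainland_label)

    # Spatially autocorrelated habitat classes: quantile-bin a smoothed field.
    codes = [c for c, _ in config.habitat_probs]
    probs = np.array([p for _, p in config.habitat_probs])
    noise = ndimage.gaussian_filter(rng.normal(size=(rows, cols)),
                                    sigma=config.habitat_smoothing_cells)
    habitat = np.full((rows, cols), "", dtype=object)
    land_idx = np.nonzero(terrestrial)
    vals = noise[land_idx]
    ranks = vals.argsort().argsort() / max(1, vals.size - 1)
    edges = np.cumsum(probs)
    bins = np.minimum(np.searchsorted(edges, ranks, side="left"), len(codes) - 1)
    habitat[land_idx] = np.array(codes, dtype=object)[bins]

    return Landscape(
        rows=rows, cols=cols, cell_km=config.cell_km,
        terrestrial=terrestrial, habitat=habitat, component=component,
        island_labels=island_labels,
        frame=raster_frame(rows, config.cell_km, name="landscape"),
        seed=config.seed,
    )


# --------------------------------------------------------------------------
# Species maps + attribute table
# --------------------------------------------------------------------------

def _couple_to_rank(values: np.ndarray, order_key: np.ndarray, assoc: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Reassign ``values`` across items so higher values go to higher noisy rank.

    Preserves the marginal distribution of ``values`` exactly (it is a
    permutation); ``assoc`` in [0, 1] scales the coupling strength.
    """
    n = len(values)
    if n == 0 or assoc <= 0:
        return values
    noisy = (1 - assoc) * rng.normal(size=n) + assoc * (
        (order_key.argsort().argsort() / max(1, n - 1)) - 0.5) * 3.46  # ~unit sd
    out = np.empty(n, dtype=values.dtype)
    out[noisy.argsort()] = np.sort(values)
    return out


def generate_species_maps(landscape: Landscape, config: ScenarioConfig
                          ) -> tuple[list[SpeciesMap], pd.DataFrame, pd.DataFrame]:
    """Generate per-species binary habitat maps and the species attribute table.

    Returns ``(maps, attributes, habitat_rows)``:

    * ``maps`` — one :class:`SpeciesMap` per resident species and two
      (breeding + nonbreeding) per migratory species;
    * ``attributes`` — one row per species: order, family, Red List category,
      recognition year, migratory/island flags, range size, the
      single-important-habitat code (or NA), and a trigger placeholder;
    * ``habitat_rows`` — long table (species_id, habitat_code, level1,
      importance) listing every habitat each species is associated with.
    """
    rng = config.rng(2)
    n = config.n_species
    if n <= 0:
        raise ParameterError("n_species must be positive")

    comp = landscape.component
    mainland_sizes = np.bincount(comp.reshape(-1))
    mainland_sizes[0] = 0
    for lbl in landscape.island_labels:
        mainland_sizes[lbl] = 0
    mainland_label = int(mainland_sizes.argmax())
    mainland_cells = int(mainland_sizes[mainland_label])

    n_island_sp = int(round(config.island_fraction * n))
    if n_island_sp and not landscape.island_labels:
        warnings.warn("landscape has no islands; island species placed on mainland")
        n_island_sp = 0
    is_island = np.zeros(n, dtype=bool)
    if n_island_sp:
        is_island[rng.choice(n, size=n_island_sp, replace=False)] = True

    n_migr = int(round(config.migratory_fraction * n))
    is_migr = np.zeros(n, dtype=bool)
    # island endemics are resident; choose migrants among mainland species
    mainland_idx = np.flatnonzero(~is_island)
    if n_migr > 0:
        n_migr = min(n_migr, mainland_idx.size)
        is_migr[rng.choice(mainland_idx, size=n_migr, replace=False)] = True

    sizes = np.maximum(1, np.round(rng.lognormal(
        config.range_meanlog, config.range_sdlog, size=n))).astype(int)
    sizes = np.minimum(sizes, config.max_range_cells)

    # Red List categories: iid draw, then rank-coupled so severe categories
    # preferentially attach to small-ranged species (marginal preserved).
    cats = [c for c, _ in config.redlist_probs]
    p = np.array([q for _, q in config.redlist_probs])
    draw = rng.choice(len(cats), size=n, p=p)
    severity = np.array([_SEVERITY[cats[i]] for i in draw])
    severity = _couple_to_rank(severity, -sizes.astype(float), config.threat_smallrange_assoc, rng)
    # map severities back to category names (ties broken by the draw's counts)
    cat_by_sev = sorted((cats[i] for i in draw), key=lambda c: _SEVERITY[c])
    order = severity.argsort(kind="stable")
    redlist = np.empty(n, dtype=object)
    redlist[order] = cat_by_sev

    orders = ("Passeriformes", "Anseriformes", "Charadriiformes", "Psittaciformes",
              "Trogoniformes", "Accipitriformes", "Columbiformes", "Apodiformes")
    order_p = np.array([0.45, 0.08, 0.09, 0.08, 0.05, 0.08, 0.10, 0.07])
    families = {
        "Passeriformes": ["Thamnophilidae", "Emberizidae", "Parulidae", "Tyrannidae"],
        "Anseriformes": ["Anatidae"],
        "Charadriiformes": ["Scolopacidae", "Laridae"],
        "Psittaciformes": ["Psittacidae"],
        "Trogoniformes": ["Trogonidae"],
        "Accipitriformes": ["Accipitridae"],
        "Columbiformes": ["Columbidae"],
        "Apodiformes": ["Apodidae", "Trochilidae"],
    }
    sp_order = rng.choice(orders, size=n, p=order_p)
    sp_family = np.array([rng.choice(families[o]) for o in sp_order], dtype=object)

    # Habitat assignment: reweight level-2 probabilities by ecology —
    # widespread LC species toward boreal/temperate codes, threatened
    # small-ranged species toward tropical codes.
    hab_codes = [c for c, _ in config.habitat_probs]
    hab_p = np.array([q for _, q in config.habitat_probs])
    q75 = np.quantile(sizes, 0.75)
    level1 = dict(zip(HABITAT_TAXONOMY.code, HABITAT_TAXONOMY.parent))
    bias = config.habitat_threat_bias
    primary = np.empty(n, dtype=object)
    for i in range(n):
        w = hab_p.copy()
        if redlist[i] == "LC" and sizes[i] >= q75:
            for j, c in enumerate(hab_codes):
                if c in WIDESPREAD_HABITATS:
                    w[j] *= bias
        elif redlist[i] in THREATENED:
            # threatened specialists of extensive high-latitude habitats are
            # essentially absent in real assemblages; exclude the combination
            for j, c in enumerate(hab_codes):
                if c in RESTRICTED_HABITATS:
                    w[j] *= bias
                elif c in WIDESPREAD_HABITATS:
                    w[j] = 0.0
        primary[i] = rng.choice(hab_codes, p=w / w.sum())

    single_major = rng.random(n) < config.single_major_fraction
    hab_rows = []
    single_major_code = np.full(n, pd.NA, dtype=object)
    n_major = np.zeros(n, dtype=int)
    for i in range(n):
        sid = f"sp{i:04d}"
        extras = [c for c in rng.choice(hab_codes, size=int(rng.integers(0, 3)), replace=False)
                  if c != primary[i]]
        if single_major[i]:
            importance = {primary[i]: "major", **{c: "suitable" for c in extras}}
            single_major_code[i] = primary[i]
        else:
            # zero or two majors, so the species is excluded from habitat-bias tests
            if rng.random() < 0.5 and extras:
                importance = {primary[i]: "major", extras[0]: "major",
                              **{c: "suitable" for c in extras[1:]}}
            else:
                importance = {primary[i]: "suitable", **{c: "suitable" for c in extras}}
        for code, imp in importance.items():
            hab_rows.append((sid, code, level1.get(code), imp))
            n_major[i] += imp == "major"

    year = np.where(rng.random(n) < config.recent_split_fraction,
                    rng.integers(1998, 2025, size=n),
                    rng.integers(1900, 1998, size=n))

    # Grow the habitat patches.
    maps: list[SpeciesMap] = []
    island_cycle = list(landscape.island_labels)
    for i in range(n):
        sid = f"sp{i:04d}"
        if is_island[i] and island_cycle:
            lbl = island_cycle[int(rng.integers(len(island_cycle)))]
            domain = comp == lbl
        else:
            domain = comp == mainland_label
        domain_cells = int(domain.sum())
        if is_island[i]:
            # island endemics are structurally confined; cap silently
            sizes[i] = min(sizes[i], domain_cells)
        # ranges grow preferentially within the species' primary habitat:
        # an AOH map is by construction habitat-restricted, which also keeps
        # habitat groups spatially segregated on the landscape
        hab_pref = domain & (landscape.habitat == primary[i])
        seasons = ("breeding", "nonbreeding") if is_migr[i] else ("resident",)
        for season in seasons:
            target = int(sizes[i])
            if target > domain_cells:
                warnings.warn(
                    f"{sid}/{season}: requested range {target} cells exceeds available "
                    f"{domain_cells}; clipping")
                target = domain_cells
            starts = np.flatnonzero(hab_pref) if hab_pref.any() else np.flatnonzero(domain)
            start_flat = int(rng.choice(starts))
            start_rc = (start_flat // landscape.cols, start_flat % landscape.cols)
            taken = np.zeros_like(domain)
            rr, cc = _grow_blob(hab_pref if hab_pref.any() else domain,
                                taken, start_rc, target, rng)
            if rr.size < target:
                # habitat patch exhausted: spill into the rest of the component
                blob = np.zeros_like(domain)
                blob[rr, cc] = True
                edge = ndimage.binary_dilation(blob) & domain & ~taken
                rr2, cc2 = _grow_blob(domain, taken,
                                      list(zip(*np.nonzero(edge))), target - rr.size, rng)
                rr = np.concatenate([rr, rr2])
                cc = np.concatenate([cc, cc2])
            maps.append(SpeciesMap(
                map_id=f"{sid}_{season}", species_id=sid, season=season,
                rows=rr, cols=cc, shape=(landscape.rows, landscape.cols),
                cell_km=landscape.cell_km, frame=landscape.frame,
            ))

    attributes = pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(n)],
        "order": sp_order,
        "family": sp_family,
        "redlist": redlist,
        "threatened": [c in THREATENED for c in redlist],
        "migratory": is_migr,
        "island": is_island,
        "range_cells": sizes,
        "n_major_habitats": n_major,
        "single_major_habitat": single_major_code,
        "recognition_year": year,
        "trigger": False,      # filled by assign_trigger_status after sites exist
    })
    habitat_rows = pd.DataFrame(
        hab_rows, columns=["species_id", "habitat_code", "habitat_level1", "importance"])
    return maps, attributes, habitat_rows


# --------------------------------------------------------------------------
# Site polygons
# --------------------------------------------------------------------------

@dataclass
class RawSite:
    """One raw site record as read from an inventory: geometry may be missing."""
    site_id: str
    name: str
    country: str
    region: str
    iba_flag: bool
    geometry: shapely.Geometry | None


def _collapsed_bowtie(x: float, y: float, size: float) -> shapely.Polygon:
    """A self-intersecting zero-area ring: invalid and unrepairable to a polygon."""
    return shapely.Polygon([(x, y), (x + size, y), (x + 2 * size, y), (x + size, y)])


def _paint_coverage(centers_rc: np.ndarray, half_w: np.ndarray,
                    half_h: np.ndarray, landscape: Landscape) -> float:
    """Fraction of terrestrial cell centers covered by the union of rectangles."""
    covered = np.zeros_like(landscape.terrestrial)
    cell = landscape.cell_km
    for (r, c), hw, hh in zip(centers_rc, half_w, half_h):
        # rectangle centered on the center of cell (r, c)
        r0 = max(0, int(math.ceil(r + 0.5 - hh / cell - 0.5)))
        r1 = min(landscape.rows - 1, int(math.floor(r + 0.5 + hh / cell - 0.5)))
        c0 = max(0, int(math.ceil(c + 0.5 - hw / cell - 0.5)))
        c1 = min(landscape.cols - 1, int(math.floor(c + 0.5 + hw / cell - 0.5)))
        if r1 >= r0 and c1 >= c0:
            covered[r0:r1 + 1, c0:c1 + 1] = True
    inter = covered & landscape.terrestrial
    return inter.sum() / max(1, landscape.n_terrestrial)


def generate_sites(landscape: Landscape, config: ScenarioConfig,
                   species: list[SpeciesMap] | None = None,
                   attributes: pd.DataFrame | None = None) -> list[RawSite]:
    """Generate raw site polygons whose valid union hits the target coverage.

    Sites are axis-aligned rectangles (in world km) with log-normal size
    variation; a global size scale is calibrated by bisection so the union of
    *valid* sites covers ``site_coverage`` of terrestrial cell centers within
    ``coverage_tolerance``.  In targeted mode, site centers are sampled from
    terrestrial cells with probability proportional to local threatened-species
    richness (plus a small floor), emulating a network assembled around
    threatened species.  ``n_invalid_sites`` collapsed bowtie geometries and
    ``n_missing_boundary`` no-geometry records are appended after the valid
    sites.
    """
    rng = config.rng(3)
    n_valid = config.n_sites - config.n_invalid_sites - config.n_missing_boundary
    if n_valid < 1:
        raise ParameterError("n_sites must exceed injected invalid/missing records")
    if config.site_mode == "targeted" and (species is None or attributes is None):
        raise ParameterError("targeted placement requires species maps and attributes")

    land_flat = np.flatnonzero(landscape.terrestrial)
    if config.site_mode == "targeted":
        richness = np.zeros(landscape.rows * landscape.cols)
        threatened_ids = set(attributes.loc[attributes.threatened, "species_id"])
        for m in species:
            if m.species_id in threatened_ids:
                richness[m.rows.astype(np.int64) * landscape.cols + m.cols] += 1
        w = richness[land_flat] + 0.05
    else:
        w = np.ones(land_flat.size)
    w = w / w.sum()
    centers_flat = rng.choice(land_flat, size=n_valid, replace=True, p=w)
    centers_rc = np.column_stack([centers_flat // landscape.cols,
                                  centers_flat % landscape.cols])
    if n_valid >= 2:
        # force at least one pairwise overlap: site 1 hugs site 0
        centers_rc[1] = np.clip(centers_rc[0] + 1,
                                0, [landscape.rows - 1, landscape.cols - 1])

    # base size from an even split of the target area, inflated for overlap
    target_area = config.site_coverage * landscape.n_terrestrial * landscape.cell_area_km2
    base_half = math.sqrt(target_area / n_valid) / 2.0
    size_mult = rng.lognormal(0.0, config.site_size_sdlog, size=n_valid)
    aspect = rng.lognormal(0.0, 0.2, size=n_valid)

    ext_x, ext_y = landscape.extent_km
    if config.max_site_extent_km2 is not None:
        cap_half = math.sqrt(config.max_site_extent_km2) / 2.0
        s_hi = cap_half / (base_half * size_mult.max())
    else:
        s_hi = max(ext_x, ext_y) / base_half
    lo, hi = 1e-6, s_hi
    tol = min(config.coverage_tolerance / 2, 0.002)
    cov_hi = _paint_coverage(centers_rc,
                             base_half * size_mult * aspect * hi,
                             base_half * size_mult / aspect * hi, landscape)
    if cov_hi < config.site_coverage - config.coverage_tolerance:
        raise ParameterError(
            f"coverage {config.site_coverage:.3f} unreachable with {n_valid} sites "
            f"(max attainable ~{cov_hi:.3f})")
    scale = hi
    for _ in range(60):
        mid = (lo + hi) / 2
        cov = _paint_coverage(centers_rc,
                              base_half * size_mult * aspect * mid,
                              base_half * size_mult / aspect * mid, landscape)
        if abs(cov - config.site_coverage) <= tol:
            scale = mid
            break
        if cov < config.site_coverage:
            lo = mid
        else:
            hi = mid
        scale = mid

    half_w = base_half * size_mult * aspect * scale
    half_h = base_half * size_mult / aspect * scale
    frame = landscape.frame
    sites: list[RawSite] = []
    for i in range(n_valid):
        r, c = centers_rc[i]
        cx, cy = frame.to_world(c + 0.5, r + 0.5)
        geom = shapely.box(cx - half_w[i], cy - half_h[i], cx + half_w[i], cy + half_h[i])
        country, region = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]
        sites.append(RawSite(
            site_id=f"S{i:04d}", name=f"Site {i}", country=country, region=region,
            iba_flag=bool(rng.random() < config.iba_prob), geometry=geom,
        ))
    k = n_valid
    for _ in range(config.n_invalid_sites):
        flat = int(rng.choice(land_flat))
        r, c = flat // landscape.cols, flat % landscape.cols
        cx, cy = frame.to_world(c + 0.5, r + 0.5)
        country, region = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]
        sites.append(RawSite(
            site_id=f"S{k:04d}", name=f"Site {k} (invalid)", country=country,
            region=region, iba_flag=False,
            geometry=_collapsed_bowtie(cx, cy, landscape.cell_km),
        ))
        k += 1
    for _ in range(config.n_missing_boundary):
        country, region = _COUNTRIES[int(rng.integers(len(_COUNTRIES)))]
        sites.append(RawSite(
            site_id=f"S{k:04d}", name=f"Site {k} (no boundary)", country=country,
            region=region, iba_flag=False, geometry=None,
        ))
        k += 1
    return sites


def assign_trigger_status(maps: list[SpeciesMap], sites: list[RawSite],
                          attributes: pd.DataFrame) -> pd.DataFrame:
    """Flag species for which at least one site has been identified.

    A species is a trigger species when the center of at least one valid site
    polygon falls on a suitable cell of one of its maps (the site was, in
    effect, identified for that species).  Returns a copy of ``attributes``
    with the ``trigger`` column filled.
    """
    pts = []
    for s in sites:
        if s.geometry is not None and s.geometry.is_valid and s.geometry.area > 0:
            c = s.geometry.centroid
            pts.append((c.x, c.y))
    out = attributes.copy()
    if not pts:
        out["trigger"] = False
        return out
    px = np.array([p[0] for p in pts])
    py = np.array([p[1] for p in pts])
    triggered = set()
    for m in maps:
        if m.species_id in triggered or m.n_cells == 0:
            continue
        u, v = m.frame.from_world(px, py)
        cc, rr = np.floor(u).astype(int), np.floor(v).astype(int)
        ok = (rr >= 0) & (rr < m.shape[0]) & (cc >= 0) & (cc < m.shape[1])
        if not ok.any():
            continue
        cell_set = set(zip(m.rows.tolist(), m.cols.tolist()))
        if any((int(r), int(c)) in cell_set for r, c in zip(rr[ok], cc[ok])):
            triggered.add(m.species_id)
    out["trigger"] = out["species_id"].isin(triggered)
    return out


@dataclass
class Scenario:
    """A fully generated synthetic study: world, species, sites, attributes."""
    config: ScenarioConfig
    landscape: Landscape
    maps: list[SpeciesMap]
    attributes: pd.DataFrame
    habitat_rows: pd.DataFrame
    sites: list[RawSite]


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Run all three generators in order and wire trigger status."""
    landscape = generate_landscape(config)
    maps, attributes, habitat_rows = generate_species_maps(landscape, config)
    sites = generate_sites(landscape, config, species=maps, attributes=attributes)
    attributes = assign_trigger_status(maps, sites, attributes)
    return Scenario(config, landscape, maps, attributes, habitat_rows, sites)
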