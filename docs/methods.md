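# Methods

## The measurement

The unit of analysis is one species-season habitat map: a binary raster on
an equal-area grid (cell side `cell_km`, every cell of identical area) in
which 1 marks suitable habitat.  Residents contribute one map; migrants
contribute separate breeding and nonbreeding maps, analysed separately
because site coverage of each seasonal range matters independently.

Site polygons are prepared in three steps before any overlap is measured:

1. **Repair.**  Invalid geometries get one deterministic node-and-rebuild
   repair (`shapely.validation.make_valid`), which splits self-intersecting
   rings at their crossing points and preserves enclosed area.  A site is
   dropped to a ledger — with reason `no-boundary`, `empty`, or
   `invalid-geometry` — when it has no geometry, an empty geometry, or when
   repair yields no polygonal area.  Every input site ends up in exactly one
   of: retained records, ledger.
2. **Dissolve.**  Retained polygons are unioned.  Sites overlap each other
   heavily in real inventories; only the dissolved union makes "percent of a
   species' habitat inside the network" well defined (bounded by 100%).
3. **Frame alignment.**  All layers live in one planar equal-area frame
   (km, y increasing upward); rasters carry an affine col/row→world
   transform with row 0 at the top.  `align_projection` is exact for the
   affine frames used here (round-trip < 1e-6 km, area error < 1e-9
   relative).

**Overlap** uses the cell-center rule: a suitable cell contributes its full
area iff its center falls inside (or on the boundary of) the polygon.  This
is the standard zonal-statistics default and an unbiased area estimator on
an equal-area grid; there is no sub-cell apportionment.  The full
map × site matrix is stored sparsely (only nonzero overlaps materialized)
while the cross-product count `n_maps × (n_raw_sites − n_dropped)` stays
available in closed form.  Per-map percents are kept at full precision
internally; reports round to 0.1.

**Classification** uses strict `<` semantics: a map is *underrepresented*
below 8%, *very underrepresented* below 5%, and additionally flagged
*no-overlap* at exactly 0.  The classes nest (a 0% map counts in both
threshold tallies).  The 8% default anchors to the Key Biodiversity Area
network's share of Earth's land (8.01%): under random placement of species
and sites, any map's expected coverage equals the network's land share, so
falling well below it marks a genuine gap.  5% probes sensitivity.  Both
thresholds are configurable.  A zero-area map cannot yield a percent and is
flagged unusable.

Counts are reported at two granularities, maps and species, with an
explicit unit column, because one migratory species contributes two maps.
The species-level rollup flags a species when *any* seasonal map is below
threshold and partitions flagged species into resident / both-seasons /
breeding-only / nonbreeding-only patterns.

**Protected-area cross-check.**  Coverage by a second polygon layer
(protected areas) reuses the identical masking machinery.  The gap table
reports, within the subset of maps with zero site overlap plus threatened
maps below the lower threshold, those with zero protected-area coverage.

## Null models for group bias

With `m` of `N` usable maps below a threshold, the question "is group g
over- or under-represented among them?" is answered by resampling: draw
`S = 1000` random samples of `m` maps, uniformly without replacement, from
the full map set, and count group-g members `c_s` in each.  Reported per
group:

* signed percent difference `D_g = 100 (mean_s c_s − O_g) / N_g`; negative
  means the group contributes more below-threshold maps than chance (worse
  represented), positive fewer (better represented);
* an exact binomial tail probability with `p = m / N`, two-sided by default
  (`min(1, 2·min(P[X ≤ O_g], P[X ≥ O_g]))`, exact tail sums, no normal
  approximation).  Because sampling is without replacement the binomial is
  an approximation to the hypergeometric; the hypergeometric test is
  available as an option, and the two agree closely at small sampling
  fractions;
* a significance flag: true when the central 95% interval (2.5th–97.5th
  percentiles, not the full range) of the per-sample differences
  `100 (c_s − O_g)/N_g` excludes 0.  The percentile reading was chosen
  because the full range of 1000 samples is noise-dominated and the
  accompanying binomial test implies a conventional α = 0.05.

Each grouping × threshold analysis uses an independent seeded RNG stream,
logged in the output.  Groups below a configurable floor (default 10 maps)
are reported but flagged small-sample.  No multiple-testing correction is
applied across groups.  When groups partition the map set, per-sample
counts sum to `m` exactly — a built-in conservation check.

Calibration: when labels are assigned independently of representation
class, the flag fires at the nominal rate and `D_g` averages zero.  The
measured false-positive rate sits slightly *below* 5% (typically 3.5–5%)
because counts are integers: ties between the observed count and the
empirical 2.5/97.5 percentiles land on "not significant".  The test and
reproduction script accept 5% ± 2 percentage points.

## Gridded reporting

Species footprints (the union of a species' seasonal maps) are aggregated
onto a coarse equal-area grid, 100-km cells by default: per-cell richness,
the count and proportion of species flagged by the seasonal rollup, and
trigger-species counts.  Presence uses the same center rule as the overlap
engine; each species counts once per cell.  The centroid layer locates
no-overlap maps and EN/CR maps below the lower threshold at the mean of
their suitable-cell centers.  The overlap histogram uses fixed-width bins,
left-closed right-open with the final bin closed at 100, so counts conserve
the number of maps.

## The synthetic world

The generator fabricates the statistical structure the analysis assumes —
not real biogeography.  What it emulates, and how:

* **Landscape** — an equal-area grid (default 200 × 200 cells of 10 km;
  the abstraction of an equal-area cylindrical projection).  Small islands
  (default 10, of 2–10 cells) are grown first, kept 8-disconnected from
  other land; one connected mainland is then grown by random accretion so
  the terrestrial count exactly matches the configured fraction (default
  0.55).  Habitat classes come from quantile-binning a Gaussian-smoothed
  noise field (smoothing σ = 6 cells), giving contiguous patches with the
  configured marginal frequencies, coded against a fixed two-level habitat
  taxonomy.
* **Species** — range sizes in cells are log-normal (default
  `meanlog = ln 60`, `sdlog = 1.1`, capped at 4000).  *These defaults are
  placeholders chosen only to be right-skewed with island-like tiny
  ranges; they are not fits to any published range-size distribution.*
  Ranges grow by Eden-style random accretion, preferentially inside the
  species' primary habitat patch and spilling into the rest of the
  landmass only when the patch is exhausted — a deliberate caricature of
  habitat-restricted ranges that also keeps habitat groups spatially
  segregated.  A configurable fraction (default 0.12) are island endemics
  confined to island components (their sizes capped by the island,
  silently — the cap is structural).  Red List categories are drawn i.i.d.
  from configured marginals ({LC .70, NT .09, VU .09, EN .06, CR .04,
  DD .02}) and then rank-coupled to range size by a
  marginal-preserving permutation (association 0.6), so severe categories
  attach to small ranges, as in real assemblages.  Threatened species are
  never assigned a widespread high-latitude habitat (boreal/temperate
  forest, temperate grassland) as primary — mirroring the near-absence of
  threatened specialists of such extensive habitats — while widespread
  least-concern species are biased toward them and threatened species
  toward tropical forest codes.  60% of species get exactly one "major"
  habitat (the unit of the habitat-bias analysis); the rest get zero or
  two, excluding them from it.
* **Sites** — axis-aligned rectangles with log-normal size variation; a
  global size scale is calibrated by bisection so the union of valid sites
  covers the target fraction of terrestrial cell centers (default 0.0801)
  within ±0.5 percentage points.  Centers are uniform over land in
  `random` mode; in `targeted` mode they are sampled proportionally to
  per-cell threatened-species richness (plus a small floor), emulating a
  network assembled around threatened species.  At least one pair of
  sites is forced to overlap.  Injected invalid geometries are collapsed
  (zero-area, collinear) self-intersecting rings — invalid *and*
  unrepairable to a polygon, so they deterministically land in the drop
  ledger; records without geometry emulate sites lacking digital
  boundaries.  A species is a *trigger* species when the center of at
  least one valid site falls on its suitable habitat.

Identical config + seed reproduces every layer bit-for-bit; the three
generators draw from independent streams spawned from the scenario seed.

What the synthetic world does **not** contain: latitudinal or realm
structure, real taxonomies, range-map vs AOH distinctions, partial-cell
geometry, non-equal-area projections.  Passing tests therefore demonstrate
the correctness and calibration of the *machinery* — masking, dissolving,
thresholding, resampling, gridding — not any empirical claim about real
site networks.

## Validation experiments and problem sizes

Two simulation experiments back the package's substantive claims; both are
also recomputed by `scripts/acceptance.py`.

* **Random placement.**  With species and sites both placed at random and
  the union covering 8.01% of land, the mean percent-in-union must equal
  the coverage fraction.  The experiment uses 6 replicate worlds of
  400 × 400 fully terrestrial cells, 350 sites, and 600 maps each
  (log-normal sizes, `meanlog = ln 25`, capped at 400 cells) — footprints
  deliberately small relative to the grid, because on a finite grid both
  layers are otherwise slightly interior-weighted and the shared geometry
  couples them.  Maps within one world share one site layer and are
  therefore correlated, so the Monte-Carlo error is assessed across
  replicate worlds (per-replicate differences scatter by ~0.7 pp; the
  acceptance band of 1 pp on the replicate mean is a ≈3.5 σ allowance).
* **Targeted placement.**  In the threat-targeted scenario (400 species,
  90 sites), trigger species must out-cover non-trigger species, threatened
  categories must show positive `D`, and the widespread-habitat group
  negative `D`.  These directions are stable across seeds; their
  magnitudes are properties of the synthetic world, not estimates of any
  real network.

Null-model calibration runs 60 independent random labelings of 10 groups
over 2000 maps (600 groups total, 500 samples each).  Test-suite and
script problem sizes are chosen to keep a full run in tens of seconds on
one CPU while leaving every statistical check adequately powered.

## Numerical and design notes

* Cell centers exactly on a polygon boundary count as inside (point
  `intersects`, i.e. `covers` semantics).  With fractional-coordinate cell
  centers and typical site coordinates, exact hits are rare; the tie-break
  is documented rather than consequential.
* `buffer(0)` was rejected as the repair primitive: on a bowtie it keeps
  only one lobe (halving the area), whereas the noded rebuild retains both.
* Degenerate inputs: empty site list → empty SiteSet; zero-area maps →
  flagged unusable and excluded from percents; empty groups are skipped
  with a note; an all-or-none below-threshold split admits no bias test
  and raises.
* The per-map percent uses the dissolved union, never the sum of per-site
  overlaps — the union bound `pct_union ≤ Σ pct_site` is strict whenever
  sites overlap on a map's cells, and summing would exceed 100%.
* Unweighted means of per-map percents are used for group comparisons
  (each map one observation, regardless of area).
* The trigger-definition (site center on suitable habitat) is the
  generator's operationalization of "a site has been identified for this
  species"; real inventories record this attribution explicitly, and the
  analysis consumes it as a plain boolean column either way.

## Known limitations

* Rectangular sites only in the generator (arbitrary polygons are accepted
  everywhere downstream).
* The binomial test ignores the without-replacement dependence; at large
  sampling fractions (`m/N` here is ~0.2–0.5) it is mildly conservative
  relative to the hypergeometric option.
* Species counts derived from map counts depend on a de-duplication rule
  (any-season-below-threshold); alternative rules would give different
  species-level tallies, which is why every table carries a unit column.
* GeoTIFF geotags and GeoPackage containers are not written; rasters go to
  plain TIFF with a JSON sidecar carrying the affine frame, vectors to
  GeoJSON.
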