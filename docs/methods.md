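# Methods

This note documents the models, decision rules, numerical choices and
synthetic-data design behind `gapcover`, in the spirit of a package
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometry and units

All computation happens in one planar equal-area coordinate system with
metre units; areas are planimetric and reported in km² (m²/10⁶). The
package never reprojects: layers must arrive in the study CRS, and a
declared mismatch is an error rather than a silent assumption. Real
national data would use an Albers-style equal-area projection
(EPSG:5070); synthetic worlds declare a trivial local Cartesian plane.
Invalid input polygons are repaired with `make_valid` (which preserves
both lobes of a bow-tie, unlike a zero-width buffer on some
orientations); features whose repaired geometry is empty or
non-polygonal are dropped with a warning. The sliver tolerance is
10⁻⁶ km² (1 m²) everywhere overlay debris is discarded.

## Protected-area selection rules

Highly protected means GAP status 1 or 2. Units strictly smaller than
5 km² are removed — a unit of exactly 5 km² is retained — so that
slivers of protection do not count large-bodied species as covered. The
area filter applies to whole database features *before* ecoregion
splitting, so post-split pieces may fall below 5 km²; adjacent features
are not dissolved first (each database feature is one unit). Both
choices follow the plainest reading of the selection rules; the
alternative orderings change survivor sets only for fragmented units.
After filtering, units are split along ecoregion boundaries; each piece
carries its parent id and its ecoregion, and piece areas sum to the
parent's area inside the study boundary to 10⁻⁶ relative.

## The placement null model

Per ecoregion, the observed statistic is the number of unique species
whose range intersects the union of that ecoregion's protected pieces by
more than the sliver tolerance (shared edges do not count; a species
overlapping several pieces counts once). Each null draw independently
re-places every piece by a rigid motion: rotation angle uniform on
[0, 2π) about the piece centroid, then translation of the centroid to a
point drawn uniformly from the ecoregion (rejection from the bounding
box). Placed pieces may overlap each other — randomness of placement is
the point of the null, and forbidding overlap would make the comparison
anti-conservative — and each ecoregion is simulated independently.

*Containment.* A candidate is accepted when the fraction of its area
inside the ecoregion reaches the `containment` parameter (default 1.0,
i.e. full containment). After `max_tries` (default 100) rejections the
fallback fires: the best candidate seen is clipped to the ecoregion and
the event is counted in `fallback_placements`. Clipping mirrors the
observed layout, whose pieces are themselves ecoregion-clipped, and
guarantees termination for pieces large relative to their ecoregion.

*Decision rule.* The comparison point is the **mean** of the null
counts. The ±1-species buffer is inclusive: a difference of exactly
+1.0 is "better", exactly −1.0 is "worse". This is a fixed decision
rule, not a significance test; no permutation p-values are attached.

*Reproducibility.* One master seed; each ecoregion draws from a
substream derived from (seed, CRC-32 of the ecoregion id), so results
are bitwise reproducible and independent of iteration order. The full
analysis uses 1,000 draws; validation experiments use 250 (the null
mean's Monte-Carlo error is then ≈ sd/√250 ≈ 0.2 species, small against
the ±1 buffer).

## The tier cascade

Canonical order: `PROTECTED_GAP12 → EASEMENT → USFS_BLM → OTHER_FEDERAL
→ STATE → PRIVATE_UNDEVELOPED → PRIVATE_OTHER`, reflecting the
narrative of converting progressively less-available land. Overlaps
between source layers are resolved by precedence: a location belongs to
the first tier whose source covers it (a USFS parcel already GAP-2 is
protected; an easement on public land is public). Public-land features
route by their `agency` attribute: USFS/BLM → `USFS_BLM`, `STATE*` →
`STATE`, anything else federal → `OTHER_FEDERAL`.

Coverage percentages use exact polygon overlay for vector tiers. The
undeveloped-private tier is a raster cell set: private land (study
boundary minus everything public or protected) masks the landcover
grid, and a cell belongs to the tier when its **centre** lies in the
private mask and its code is neither a developed class nor cultivated
crops (NLCD codes 21–24 and 82 under the default legend; a 3-code toy
legend in synthetic worlds). The cell-centre rule is unbiased for area
in expectation and makes results bit-reproducible; its error in any
range-overlay percentage is bounded by the boundary length times the
cell diagonal over the range area, and shrinks linearly with cell size.
The final `PRIVATE_OTHER` tier is the residual of the partition, which
keeps every species' percentages summing to exactly 100 despite the
mixed vector/raster representation.

A species is adequately protected at threshold 30% of its range
(inclusive: exactly 30.0% counts, configurable to strict), the standard
rule-of-thumb standing in for species-specific viability analysis. The
denominator is always the range clipped to the study boundary.

## The synthetic-world generator

The generator emulates the statistical structure the analysis assumes,
with exact bookkeeping so pipeline outputs can be checked against known
truth. Design choices, with rationale:

* **Ecoregions** — bounded Voronoi cells around random sites (closed by
  reflecting sites across the extent edges), relaxed by two Lloyd
  iterations so region areas are comparable in scale, as real level-II
  ecoregions are. Un-relaxed partitions produce occasional tiny regions
  that a single species cluster saturates, which no placement analysis
  can say anything about.
* **Species ranges** — simple blobs (disc radius modulated by bounded
  harmonics k = 2..5, rescaled to the sampled log-normal area, so the
  polygon is always valid without repair). Centres cluster: 80% of
  species scatter (Gaussian, sd 4 km) around one hotspot per ecoregion,
  the rest are uniform. Clustering is essential, not cosmetic: real
  endangered-species richness is hotspot-structured, and without
  richness peaks a placement bias has nothing to seek or avoid.
* **Protected areas** — areas log-normal (median 10 km², so units are
  small relative to ranges, as real reserves are relative to
  endangered-species ranges); at least five units per ecoregion
  (remainder allocated by area), since a placement comparison is
  uninformative in an ecoregion whose null mean is below one species.
  Placement runs through the null model's own rigid-placement sampler;
  the bias parameter β reweights only the centroid law, density ∝
  exp(−β·R(x)) with R(x) the number of ranges covering x, by rejection
  referenced to the most favourable richness on a probe sample. At
  β = 0 the code path is *identical* to the null model's, so the
  default world's layout is one genuine null draw — the calibration
  experiments are exact by construction. A few GAP 3/4 decoy units
  exercise the selection filter.
* **Tiers and landcover** — non-protected land is tessellated into ~250
  small Voronoi cells, shuffled and greedily labelled
  easement/USFS–BLM/other-federal/state until each tier reaches its
  target share of non-protected land (within about one cell, ≈ 0.4
  percentage points); the rest is private. Default shares (2/22/8/9/59%)
  echo the relative magnitudes of the real tiers — easements about a
  quarter of the highly protected estate, public land about a third of
  the country. Landcover cells are i.i.d. developed (10%) / crops
  (20%) / natural on a 100 m grid.
* **Ground truth** — per species, exact overlay areas for vector tiers,
  and for the raster tier the exact area of the range ∩ private ∩
  natural-cell squares (cells wholly inside/outside decided by buffered
  point tests, the boundary band by exact box intersection). Truth
  percentages sum to exactly 100.

The default world: 100 × 100 km, 8 ecoregions, 140 species, 40
protected areas. Scale was chosen so every validation experiment runs
in seconds to ~1 minute on one CPU.

What the generator does **not** emulate: habitat-driven range shapes,
phylogenetic or class structure in where species live, realistic
parcel geometry or ownership fragmentation, spatially autocorrelated
landcover, migration corridors and seasonal ranges. Passing tests
therefore show that the machinery is correct and calibrated under the
stated statistical structure, not that any particular real landscape
satisfies that structure.

## Validation experiments and their design

* **Calibration** (`run_calibration`): 200 ecoregions from β = 0 worlds,
  250 draws each. Because the observed layout is a null draw, the mean
  of (observed − null mean) must be zero up to Monte-Carlo error (the
  check uses ±3 standard errors) and "worse" vs "better" labels must be
  binomially symmetric (two-sided test, required p > 0.01). One caveat
  discovered during design and worth recording: with few pieces per
  ecoregion the per-draw count distribution is strongly right-skewed,
  and a single draw then falls ≥1 below the *mean* more often than ≥1
  above it — the ±1-about-the-mean rule is asymmetric under skew even
  for a perfectly calibrated model. The default world's piece count
  (≥5 per ecoregion) keeps the count distribution close enough to
  symmetric for the binomial check to hold.
* **Bias recovery** (`run_bias_recovery`): worlds with β = +2 must
  classify ≥80% of ecoregions "worse", β = −2 ≥80% "better". This is
  the parameter-recovery property that justifies reading the real
  map's "worse" ecoregions as evidence of placement away from species.
* **Rigid-motion conservation**: 10⁴ placements of a 100 m disc in a
  40 km square; accepted placements must conserve area to 10⁻⁹
  relative, and centroid counts on a 4 × 4 grid must pass a chi-square
  uniformity test at p > 0.001 (the disc is small enough that full
  containment leaves the centroid law essentially uniform).
* **Overlay oracle**: for 100 random range × tier-map pairs, exact
  overlay percentages are compared with a 10⁵-point Monte-Carlo
  point-classification estimate. Across the ~300 simultaneous
  comparisons, each exceeds 3 binomial standard errors with ≈0.3%
  probability under exact agreement, so the check bounds the
  *exceedance rate* (≤2%) and the absolute deviation (<0.5 pp) rather
  than the single worst z-score; a genuine overlay defect produces
  z-scores orders of magnitude above 3.
* **Ground-truth recovery**: on the default world, pipeline coverage
  must match generator truth within 0.1 pp for vector tiers and within
  the perimeter × cell-size bound for the raster tier, and the adequacy
  counts at every cumulative tier must match truth-derived counts
  exactly.
* **Determinism**: identical config and seed must reproduce the
  null-model and coverage CSVs bitwise.

## Known limitations

* GeoJSON/ASCII-grid I/O only; no Shapefile/GeoPackage/GeoTIFF drivers
  and no reprojection — real national data must be converted and
  projected upstream.
* The null model treats ecoregions independently; pieces near a shared
  boundary never interact with neighbouring ecoregions' species pools
  beyond the ranges that physically cross the boundary.
* Whether the original containment convention was full containment,
  overhang, or clipping is not knowable from the analysis description;
  it is exposed as the `containment` parameter (default full
  containment with clip fallback) rather than resolved.
* The ±1-species rule is scale-dependent: in species-poor ecoregions
  (null mean < 1) "worse" is unreachable and the classifier defaults to
  "equal"; interpretation of class percentages should keep the
  ecoregion richness profile in mind.
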