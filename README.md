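# gapcover

Protected-area gap analysis for endangered species: a spatial null model
for reserve placement, and a tiered land-designation coverage analysis
with the 30% adequate-protection rule.

## The scientific problem

Highly protected areas (IUCN-style reserves recorded in PAD-US as GAP
status 1 or 2 — "managed for biodiversity with no extractive uses") are
the main instrument for conserving endangered species, yet they were
often sited for scenery or low agricultural value rather than for
biodiversity. Two questions follow, and this package implements the
analysis machinery for both:

1. **Are reserves better placed than chance?** For each ecoregion, count
   the unique endangered species whose ranges overlap its highly
   protected areas. Build a null distribution by rigidly re-placing every
   protected-area polygon — random rotation about its centroid, centroid
   translated to a uniform random point of the ecoregion — 1,000 times,
   recounting species each time. With observed count `S_obs` and null
   mean `S̄_null`, the ecoregion is

   * **better** than random if `S_obs − S̄_null ≥ +1` species,
   * **worse** if `S_obs − S̄_null ≤ −1`,
   * **equal** otherwise.

2. **Where could adequate protection come from?** Partition land into an
   ordered cascade of designation tiers — highly protected (GAP 1–2) →
   conservation easements → USFS/BLM → other federal → state →
   undeveloped private → developed/cropland private — and accumulate, for
   each species, the percent of its range `p_t` in each tier t. A species
   is *adequately protected* once its cumulative coverage reaches the 30%
   rule-of-thumb threshold; the earliest tier where `Σ p_t ≥ 30%` says
   what kind of land conversion could protect it. "Undeveloped private"
   means private land whose landcover is not any developed class and not
   cultivated crops.

Because the real inputs are versioned national geodatabases, the package
ships a **synthetic-world generator** that emulates their statistical
structure — ecoregion partitions, hotspot-clustered blob ranges,
protected areas with a controllable placement bias `β` (centroid density
∝ exp(−β·richness); β = 0 is exactly the null model's own placement
law), tier tessellations with known proportions, and a categorical
landcover grid — with exact per-species ground truth, so every stage is
testable end to end without downloads.

## Worked example

```bash
python analysis/01_generate_world.py   # three worlds: β = 0, +2, −2
python analysis/02_null_model.py       # 1,000-draw null model on each
python analysis/03_coverage_tiers.py   # tier cascade on the unbiased world
python analysis/04_calibration.py      # calibration + power of the classifier
```

`02_null_model.py` prints, for the three worlds (seed 0):

```
unbiased:  50% worse, 12% equal, 38% better than random (8 ecoregions)
repelled:  100% worse, 0% equal, 0% better than random (8 ecoregions)
attracted: 0% worse, 12% equal, 88% better than random (8 ecoregions)
```

The unbiased world splits roughly symmetrically (a single draw from the
null per ecoregion); when reserve placement avoids species-rich land
(β = +2) every ecoregion is flagged worse than random, and when it seeks
rich land (β = −2) almost every ecoregion is flagged better.

`03_coverage_tiers.py` prints the adequacy cascade for the 140 species
of the unbiased world:

```
through PROTECTED_GAP12           4 (3%)
through EASEMENT                  4 (3%)
through USFS_BLM                 50 (36%)
through OTHER_FEDERAL            72 (51%)
through STATE                    93 (66%)
through PRIVATE_UNDEVELOPED     140 (100%)
```

Reading: only 4 species reach 30% of range inside existing reserves;
easements add none (they cover far less land than reserves); converting
USFS/BLM land could protect 50; other federal and state land bring the
count to 93; every species could reach the threshold only once
undeveloped private land joins the cascade. `results/class_coverage.png`
is the mean-coverage-by-tetrapod-class bar chart with the 30% line.

`04_calibration.py` prints (seed 0):

```
mean(observed - null mean) = +0.032 (SE 0.314);
better/equal/worse = 85/33/82; two-sided binomial p = 0.877
```

The CLI mirrors the scripts: `gapcover generate`, `gapcover nullmodel`,
`gapcover coverage`, `gapcover pipeline run|validate` (see `--help`).

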