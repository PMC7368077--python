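"""Reusable validation experiments over synthetic worlds.

These are the package's own checks of its scientific machinery: null
model calibration on unbiased worlds, parameter recovery under placement
bias, rigid-motion conservation and centroid uniformity, Monte-Carlo
verification of overlay percentages, and recovery of generator ground
truth by the coverage pipeline.  The analysis drivers, the test suite
and the acceptance script all call these functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import box

from .coverage import (
    TIER_ORDER,
    TierMap,
    build_tier_map,
    count_adequate,
    coverage_for_species,
)
from .geo_io import M2_PER_KM2, VectorLayer
from .null_model import (
    PlacementConfig,
    random_rigid_placement,
    run_null_model,
    summarize,
)
from .preprocess import (
    ProtectedArea,
    SpeciesRange,
    filter_min_area,
    split_by_ecoregion,
)
from .private_lands import UndevelopedRule, private_mask, undeveloped_private_geometry
from .synthetic import (
    TOY_EXCLUDED_CODES,
    WorldConfig,
    blob_polygon,
    generate_world,
)

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationResult",
    "run_calibration",
    "run_bias_recovery",
    "placement_conservation",
    "monte_carlo_overlay_check",
    "coverage_truth_recovery",
    "world_tier_map_via_pipeline",
]


def _pieces_by_ecoregion(world) -> dict[str, list[ProtectedArea]]:
    qualifying = filter_min_area(
        [pa for pa in world.protected if pa.gap_status in (1, 2)]
    )
    pieces = split_by_ecoregion(qualifying, world.ecoregions)
    by_eco: dict[str, list[ProtectedArea]] = {}
    for p in pieces:
        by_eco.setdefault(p.ecoregion_id, []).append(p)
    return by_eco


@dataclass
class CalibrationResult:
    diffs: np.ndarray
    n_better: int
    n_equal: int
    n_worse: int
    mean_diff: float
    se_mean: float
    binomial_p: float

    @property
    def n_ecoregions(self) -> int:
        return self.diffs.size


def run_calibration(
    n_ecoregions: int = 200,
    iterations: int = 250,
    seed: int = 0,
    base_config: WorldConfig | None = None,
) -> CalibrationResult:
    """Null-model calibration over unbiased synthetic worlds.

    Generates worlds whose protected areas are themselves single draws
    from the placement null (bias 0) and runs the null model on each,
    accumulating per-ecoregion observed-minus-null differences until
    ``n_ecoregions`` ecoregions with protected areas have been analysed.
    On a calibrated model the mean difference is zero up to Monte-Carlo
    error and "worse" and "better" classifications are equally likely.
    """
    cfg0 = base_config if base_config is not None else WorldConfig()
    diffs: list[float] = []
    classes: list[str] = []
    world_seed_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA11]))
    while len(diffs) < n_ecoregions:
        wseed = int(world_seed_rng.integers(0, 2**31 - 1))
        cfg = replace(cfg0, seed=wseed, bias_beta=0.0)
        world = generate_world(cfg, include_tiers=False)
        by_eco = _pieces_by_ecoregion(world)
        results = run_null_model(
            by_eco,
            world.ranges,
            world.ecoregions,
            PlacementConfig(n_iterations=iterations, seed=wseed + 1),
        )
        for r in results:
            diffs.append(r.difference)
            classes.append(r.classification)
    diffs_arr = np.array(diffs[:n_ecoregions])
    classes = classes[:n_ecoregions]
    n_better = classes.count("better")
    n_worse = classes.count("worse")
    n_equal = classes.count("equal")
    se = float(diffs_arr.std(ddof=1) / math.sqrt(diffs_arr.size))
    if n_better + n_worse > 0:
        p = stats.binomtest(n_worse, n_worse + n_better, 0.5).pvalue
    else:  # pragma: no cover - degenerate worlds
        p = 1.0
    return CalibrationResult(
        diffs=diffs_arr,
        n_better=n_better,
        n_equal=n_equal,
        n_worse=n_worse,
        mean_diff=float(diffs_arr.mean()),
        se_mean=se,
        binomial_p=float(p),
    )


def run_bias_recovery(
    bias_beta: float,
    n_worlds: int = 6,
    iterations: int = 250,
    seed: int = 0,
    base_config: WorldConfig | None = None,
) -> dict[str, float]:
    """Classification rates over worlds with biased protected-area placement.

    With strong repulsion from species-rich land (positive bias) most
    ecoregions should classify "worse" than random; with strong
    attraction, "better".  Returns the pooled percentages.
    """
    cfg0 = base_config if base_config is not None else WorldConfig()
    counts = {"better": 0, "equal": 0, "worse": 0}
    world_seed_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1A5]))
    n_total = 0
    for _ in range(n_worlds):
        wseed = int(world_seed_rng.integers(0, 2**31 - 1))
        cfg = replace(cfg0, seed=wseed, bias_beta=bias_beta)
        world = generate_world(cfg, include_tiers=False)
        by_eco = _pieces_by_ecoregion(world)
        results = run_null_model(
            by_eco,
            world.ranges,
            world.ecoregions,
            PlacementConfig(n_iterations=iterations, seed=wseed + 1),
        )
        for r in results:
            counts[r.classification] += 1
            n_total += 1
    return {
        "pct_better": 100.0 * counts["better"] / n_total,
        "pct_equal": 100.0 * counts["equal"] / n_total,
        "pct_worse": 100.0 * counts["worse"] / n_total,
        "n_ecoregions": float(n_total),
    }


def placement_conservation(
    n_placements: int = 10_000,
    seed: int = 0,
    disc_radius_m: float = 100.0,
    rect_km: tuple[float, float] = (40.0, 40.0),
) -> dict[str, float]:
    """Area conservation and centroid uniformity of the rigid placement.

    Places a small disc in a rectangle ``n_placements`` times; reports
    the maximum relative area change over accepted placements and the
    chi-square p-value of centroid counts in a 4x4 grid of equal-area
    cells.  The disc is small relative to the rectangle so the full
    containment constraint leaves the centroid law essentially uniform.
    """
    rng = np.random.default_rng(seed)
    w, h = rect_km[0] * 1000.0, rect_km[1] * 1000.0
    rect = box(0.0, 0.0, w, h)
    disc = shapely.Point(w / 2, h / 2).buffer(disc_radius_m, quad_segs=64)
    a0 = disc.area
    cfg = PlacementConfig(n_iterations=1, seed=seed)
    max_rel_err = 0.0
    cx = np.empty(n_placements)
    cy = np.empty(n_placements)
    n_fallback = 0
    for i in range(n_placements):
        g, fb = random_rigid_placement(disc, rect, rng, cfg)
        n_fallback += fb
        if not fb:
            max_rel_err = max(max_rel_err, abs(g.area - a0) / a0)
        c = g.centroid
        cx[i], cy[i] = c.x, c.y
    counts, _, _ = np.histogram2d(cx, cy, bins=4, range=[[0, w], [0, h]])
    chi2, p = stats.chisquare(counts.ravel())
    return {
        "max_rel_area_error": max_rel_err,
        "chi2": float(chi2),
        "chi2_p": float(p),
        "n_fallback": float(n_fallback),
    }


def monte_carlo_overlay_check(
    n_pairs: int = 100,
    n_points: int = 100_000,
    seed: int = 0,
) -> dict[str, float]:
    """Overlay percentages vs a point-classification Monte-Carlo oracle.

    For random (range, vector tier map) pairs, the exact overlay percent
    of the range in each tier is compared with the fraction of uniform
    random points in the range classified into that tier; reported are
    the worst z-score (absolute deviation over binomial standard error),
    the worst absolute deviation, and the share of comparisons exceeding
    3 standard errors.  Under exact agreement each comparison exceeds
    3 SE with probability ~0.3%, so across hundreds of simultaneous
    comparisons a small exceedance rate is expected by chance, whereas a
    genuine overlay defect drives z-scores into the tens or hundreds.
    """
    rng = np.random.default_rng(seed)
    side = 50_000.0
    frame = box(0.0, 0.0, side, side)
    max_z = 0.0
    max_abs_dev_pp = 0.0
    n_comparisons = 0
    n_over_3se = 0
    for _ in range(n_pairs):
        # a random 3-tier vector partition from two random blobs
        b1 = blob_polygon(
            (rng.uniform(0, side), rng.uniform(0, side)),
            rng.uniform(0.05, 0.3) * side**2,
            0.4,
            rng,
        )
        b2 = blob_polygon(
            (rng.uniform(0, side), rng.uniform(0, side)),
            rng.uniform(0.05, 0.3) * side**2,
            0.4,
            rng,
        )
        pa = ProtectedArea("pa0", b1.intersection(frame), gap_status=1)
        tier_map = build_tier_map(
            [pa],
            None,
            VectorLayer([(b2.intersection(frame), {"agency": "USFS"})]),
            None,
            frame,
        )
        blob = blob_polygon(
            (rng.uniform(0, side), rng.uniform(0, side)),
            rng.uniform(0.02, 0.2) * side**2,
            0.4,
            rng,
        )
        geom = blob.intersection(frame)
        sp = SpeciesRange("s", "bird", geom)
        rec = coverage_for_species(sp, tier_map)

        # uniform points in the range by rejection from its bounding box
        bxmin, bymin, bxmax, bymax = geom.bounds
        pts_x = np.empty(0)
        pts_y = np.empty(0)
        shapely.prepare(geom)
        while pts_x.size < n_points:
            m = int((n_points - pts_x.size) * 2.5) + 1000
            xs = rng.uniform(bxmin, bxmax, m)
            ys = rng.uniform(bymin, bymax, m)
            keep = shapely.contains_xy(geom, xs, ys)
            pts_x = np.concatenate([pts_x, xs[keep]])
            pts_y = np.concatenate([pts_y, ys[keep]])
        pts_x, pts_y = pts_x[:n_points], pts_y[:n_points]
        for tier in ("PROTECTED_GAP12", "USFS_BLM", "PRIVATE_OTHER"):
            src = tier_map.tiers[tier]
            if src is None or src.is_empty:
                p_hat = 0.0
            else:
                shapely.prepare(src)
                p_hat = float(shapely.contains_xy(src, pts_x, pts_y).mean())
            p_exact = rec.pct_by_tier[tier] / 100.0
            se = math.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n_points)
            dev = abs(p_hat - p_exact)
            max_abs_dev_pp = max(max_abs_dev_pp, 100.0 * dev)
            n_comparisons += 1
            if se > 0:
                z = dev / se
                max_z = max(max_z, z)
                n_over_3se += z > 3.0
    return {
        "max_z": max_z,
        "max_abs_dev_pp": max_abs_dev_pp,
        "frac_over_3se": n_over_3se / n_comparisons,
        "n_comparisons": float(n_comparisons),
        "n_points": float(n_points),
    }


def world_tier_map_via_pipeline(world) -> TierMap:
    """Rebuild a world's tier map through the analysis-side code path.

    Applies the protected-area selection rules, derives the private-land
    mask, classifies undeveloped private cells from the landcover grid,
    and resolves tier precedence — everything the pipeline does, without
    touching the generator's own tier map.
    """
    qualifying = filter_min_area(
        [pa for pa in world.protected if pa.gap_status in (1, 2)]
    )
    others = [pa.geometry for pa in qualifying]
    others += world.easements.geometries()
    others += world.public.geometries()
    mask = private_mask(world.study_boundary, others)
    rule = UndevelopedRule(TOY_EXCLUDED_CODES)
    cells = undeveloped_private_geometry(mask, world.landcover, rule)
    return build_tier_map(qualifying, world.easements, world.public, cells, world.study_boundary)


def coverage_truth_recovery(world=None, seed: int = 0) -> dict[str, float]:
    """Coverage pipeline vs generator ground truth on one synthetic world.

    Returns the worst vector-tier error (percentage points), the worst
    raster-tier error together with its perimeter-based quantisation
    bound, and whether the adequacy counts at every cumulative tier
    match the counts derived from ground truth exactly.
    """
    if world is None:
        world = generate_world(WorldConfig(seed=seed))
    tier_map = world_tier_map_via_pipeline(world)
    records = {r.species_id: coverage_for_species(r, tier_map) for r in world.ranges}
    truth = world.truth.set_index("species_id")
    cs = world.config.cell_size_m

    vec_tiers = ("PROTECTED_GAP12", "EASEMENT", "USFS_BLM", "OTHER_FEDERAL", "STATE")
    max_vec_err = 0.0
    max_rast_err = 0.0
    max_rast_ratio = 0.0  # raster error / perimeter-based bound
    for r in world.ranges:
        rec = records[r.species_id]
        for t in vec_tiers:
            err = abs(rec.pct_by_tier[t] - truth.loc[r.species_id, f"pct_{t}"])
            max_vec_err = max(max_vec_err, err)
        err = abs(
            rec.pct_by_tier["PRIVATE_UNDEVELOPED"]
            - truth.loc[r.species_id, f"pct_PRIVATE_UNDEVELOPED"]
        )
        max_rast_err = max(max_rast_err, err)
        # every misclassified cell sits within one cell diagonal of either
        # the range boundary or the private-mask boundary inside the range
        perim = r.geometry.length
        bound_pp = (
            100.0
            * 2.0
            * math.sqrt(2.0)
            * perim
            * cs
            / (r.total_range_km2 * M2_PER_KM2)
        )
        if bound_pp > 0:
            max_rast_ratio = max(max_rast_ratio, err / bound_pp)

    # adequacy counts from ground truth vs from pipeline records
    counts_match = True
    rec_list = list(records.values())
    for tier in TIER_ORDER:
        upto = TIER_ORDER[: TIER_ORDER.index(tier) + 1]
        cum_truth = sum(truth[f"pct_{t}"] for t in upto)
        n_truth = int((cum_truth >= 30.0).sum())
        n_pipe = count_adequate(rec_list, tier)
        if n_truth != n_pipe:
            counts_match = False
    return {
        "max_vector_err_pp": max_vec_err,
        "max_raster_err_pp": max_rast_err,
        "max_raster_err_over_bound": max_rast_ratio,
        "adequacy_counts_match": float(counts_match),
        "n_species": float(len(world.ranges)),
    }
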