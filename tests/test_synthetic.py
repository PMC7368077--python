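"""World generator: partitions, blobs, bias, tier proportions, determinism."""

import numpy as np
import pytest
import shapely

from gapcover.null_model import _uniform_point_in
from gapcover.synthetic import (
    WorldConfig,
    blob_polygon,
    ecoregions_from_sites,
    generate_ecoregions,
    generate_species_ranges,
    generate_world,
    place_protected_biased,
)


class TestEcoregions:
    def test_single_region_is_the_extent(self, rng):
        cfg = WorldConfig(n_ecoregions=1)
        (eco,) = generate_ecoregions(cfg, rng)
        assert eco.geometry.equals(cfg.extent_box())

    def test_partition_covers_extent_exactly(self, rng):
        cfg = WorldConfig(n_ecoregions=11)
        ecos = generate_ecoregions(cfg, rng)
        total = sum(e.area_km2 for e in ecos)
        assert total == pytest.approx(1e4, rel=1e-6)
        union = shapely.union_all([e.geometry for e in ecos])
        assert union.symmetric_difference(cfg.extent_box()).area / 1e6 < 1e-6
        # pairwise overlaps below sliver tolerance
        for i in range(len(ecos)):
            for j in range(i + 1, len(ecos)):
                assert ecos[i].geometry.intersection(ecos[j].geometry).area / 1e6 < 1e-6

    def test_symmetric_sites_give_equal_quadrants(self):
        sites = np.array([[25e3, 25e3], [75e3, 25e3], [25e3, 75e3], [75e3, 75e3]])
        ecos = ecoregions_from_sites(sites, (100e3, 100e3))
        for e in ecos:
            assert e.area_km2 == pytest.approx(2500.0, rel=1e-9)


class TestBlobs:
    def test_zero_irregularity_is_a_disc_of_exact_area(self, rng):
        target = 5e6
        blob = blob_polygon((1000.0, 2000.0), target, 0.0, rng)
        assert blob.area == pytest.approx(target, rel=1e-9)
        # all vertices equidistant from the centre
        cx, cy = blob.centroid.x, blob.centroid.y
        d = [np.hypot(x - cx, y - cy) for x, y in blob.exterior.coords]
        assert np.ptp(d) / np.mean(d) < 1e-6

    def test_irregular_blob_simple_and_exact_area(self, rng):
        for _ in range(20):
            blob = blob_polygon((0.0, 0.0), 2e6, 1.0, rng)
            assert blob.is_valid and blob.is_simple
            assert blob.area == pytest.approx(2e6, rel=1e-9)

    def test_median_area_recovered(self):
        cfg = WorldConfig(n_species=1000, range_shape=0.0)
        rng = np.random.default_rng(5)
        ecos = generate_ecoregions(cfg, np.random.default_rng(1))
        # measure pre-clip areas through a wide extent so clipping is rare
        wide = WorldConfig(extent_km=(400.0, 400.0), n_species=1000)
        ranges = generate_species_ranges(wide, ecos, rng)
        med = np.median([r.total_range_km2 for r in ranges])
        assert med == pytest.approx(wide.range_median_km2, rel=0.10)

    def test_determinism(self):
        cfg = WorldConfig(n_species=10)
        ecos = generate_ecoregions(cfg, np.random.default_rng(1))
        a = generate_species_ranges(cfg, ecos, np.random.default_rng(9))
        b = generate_species_ranges(cfg, ecos, np.random.default_rng(9))
        for ra, rb in zip(a, b):
            assert ra.geometry.equals_exact(rb.geometry, 0)


class TestPlacementBias:
    def test_strong_positive_bias_avoids_a_half_extent_range(self):
        # one species covering the left half: with strong repulsion every
        # qualifying centroid must land in the empty right half
        cfg = WorldConfig(
            n_species=1, n_protected=8, n_multiuse=0, min_pa_per_ecoregion=0,
            n_ecoregions=1, bias_beta=50.0, p_hotspot=0.0,
        )
        rng = np.random.default_rng(3)
        ecos = generate_ecoregions(cfg, rng)
        from gapcover.preprocess import SpeciesRange
        from shapely.geometry import box

        half = SpeciesRange("s", "bird", box(0, 0, 50e3, 100e3))
        pas = place_protected_biased(cfg, ecos, [half], rng)
        for pa in pas:
            assert pa.geometry.centroid.x > 50e3

    def test_negative_bias_raises_centroid_richness(self):
        cfg_null = WorldConfig(seed=21, bias_beta=0.0)
        cfg_att = WorldConfig(seed=21, bias_beta=-2.0)
        w0 = generate_world(cfg_null, include_tiers=False)
        w1 = generate_world(cfg_att, include_tiers=False)

        def mean_richness(world):
            geoms = [r.geometry for r in world.ranges]
            for g in geoms:
                shapely.prepare(g)
            tree = shapely.STRtree(geoms)
            vals = []
            for pa in world.protected:
                if pa.gap_status not in (1, 2):
                    continue
                c = pa.geometry.centroid
                vals.append(
                    sum(1 for i in tree.query(c) if shapely.contains_xy(geoms[i], c.x, c.y))
                )
            return np.mean(vals)

        assert mean_richness(w1) > mean_richness(w0) + 0.5


class TestTiersAndTruth:
    def test_truth_fractions_sum_to_100(self, default_world):
        pct_cols = [c for c in default_world.truth.columns if c.startswith("pct_")]
        sums = default_world.truth[pct_cols].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_tier_proportions_hit_within_two_points(self, default_world):
        cfg = default_world.config
        tm = default_world.tier_map
        pa_area = tm.tiers["PROTECTED_GAP12"].area
        non_pa = default_world.study_boundary.area - pa_area
        for tier in ("EASEMENT", "USFS_BLM", "OTHER_FEDERAL", "STATE"):
            frac = tm.tiers[tier].area / non_pa
            assert abs(frac - cfg.tier_proportions[tier]) < 0.02

    def test_all_developed_private_leaves_no_undeveloped_truth(self):
        cfg = WorldConfig(
            landcover_p_developed=1.0, landcover_p_crops=0.0,
            n_species=10, n_protected=8, cell_size_m=500.0, tier_cells=60, seed=4,
        )
        world = generate_world(cfg)
        assert (world.truth["pct_PRIVATE_UNDEVELOPED"] < 1e-9).all()

    def test_single_tier_proportion_takes_all_non_pa_land(self):
        cfg = WorldConfig(
            tier_proportions={"STATE": 1.0},
            n_species=10, n_protected=8, cell_size_m=500.0, tier_cells=60, seed=4,
        )
        world = generate_world(cfg)
        for tier in ("EASEMENT", "USFS_BLM", "OTHER_FEDERAL"):
            assert world.tier_map.tiers[tier].area / 1e6 < 1e-6
            assert (world.truth[f"pct_{tier}"] < 1e-9).all()

    def test_world_fully_determined_by_seed(self):
        cfg = WorldConfig(n_species=12, n_protected=8, cell_size_m=500.0, tier_cells=60, seed=11)
        a = generate_world(cfg)
        b = generate_world(cfg)
        assert a.truth.equals(b.truth)
        for pa_a, pa_b in zip(a.protected, b.protected):
            assert pa_a.geometry.equals_exact(pa_b.geometry, 0)
        assert np.array_equal(a.landcover.values, b.landcover.values)
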