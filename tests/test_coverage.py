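"""Tier cascade: precedence, coverage percentages, 30% threshold."""

import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from gapcover.coverage import (
    TIER_ORDER,
    agency_tier,
    build_tier_map,
    class_summary,
    count_adequate,
    coverage_for_species,
)
from gapcover.geo_io import VectorLayer
from gapcover.preprocess import ProtectedArea, SpeciesRange


STUDY = box(0, 0, 10000, 10000)  # 100 km^2 square


def _record(pcts, tclass="bird", sid="s", threshold=30.0):
    """CoverageRecord-like via the real constructor path: build a world
    of axis-aligned strips whose tier shares equal ``pcts``."""
    # build from an explicit tier map of vertical strips
    x = 0.0
    protected = []
    easements, public = [], []
    und = None
    strips = {}
    for tier, pct in pcts.items():
        wdt = 10000 * pct / 100.0
        strips[tier] = box(x, 0, x + wdt, 10000)
        x += wdt
    if "PROTECTED_GAP12" in strips:
        protected = [ProtectedArea("p", strips["PROTECTED_GAP12"], 1)]
    if "EASEMENT" in strips:
        easements.append((strips["EASEMENT"], {}))
    for tier, agency in (("USFS_BLM", "USFS"), ("OTHER_FEDERAL", "DOD"), ("STATE", "STATE")):
        if tier in strips:
            public.append((strips[tier], {"agency": agency}))
    if "PRIVATE_UNDEVELOPED" in strips:
        und = strips["PRIVATE_UNDEVELOPED"]
    tier_map = build_tier_map(
        protected,
        VectorLayer(easements) if easements else None,
        VectorLayer(public) if public else None,
        und,
        STUDY,
    )
    sp = SpeciesRange(sid, tclass, STUDY)
    return coverage_for_species(sp, tier_map, threshold=threshold)


class TestAgencyTier:
    @pytest.mark.parametrize(
        "agency,tier",
        [("USFS", "USFS_BLM"), ("blm", "USFS_BLM"), ("STATE_DNR", "STATE"),
         ("DOD", "OTHER_FEDERAL"), ("BOR", "OTHER_FEDERAL")],
    )
    def test_routing(self, agency, tier):
        assert agency_tier(agency) == tier


class TestBuildTierMap:
    def test_half_gap_half_usfs(self):
        left = box(0, 0, 5000, 10000)
        right = box(5000, 0, 10000, 10000)
        tm = build_tier_map(
            [ProtectedArea("p", left, 1)],
            None,
            VectorLayer([(right, {"agency": "USFS"})]),
            None,
            STUDY,
        )
        assert tm.tiers["PROTECTED_GAP12"].area == pytest.approx(STUDY.area / 2)
        assert tm.tiers["USFS_BLM"].area == pytest.approx(STUDY.area / 2)
        inter = tm.tiers["PROTECTED_GAP12"].intersection(tm.tiers["USFS_BLM"]).area
        assert inter / 1e6 < 1e-6

    def test_precedence_empties_lower_tier(self):
        big = box(0, 0, 6000, 6000)
        inside = box(1000, 1000, 2000, 2000)
        tm = build_tier_map(
            [ProtectedArea("p", big, 2)],
            None,
            VectorLayer([(inside, {"agency": "USFS"})]),
            None,
            STUDY,
        )
        assert tm.tiers["USFS_BLM"].is_empty or tm.tiers["USFS_BLM"].area / 1e6 < 1e-6

    def test_random_overlapping_layers_conserve_area(self, rng):
        pas, ease, pub = [], [], []
        for i in range(8):
            pas.append(ProtectedArea(f"p{i}", shapely.Point(rng.uniform(0, 1e4, 2)).buffer(rng.uniform(300, 2000)), 1))
            ease.append((shapely.Point(rng.uniform(0, 1e4, 2)).buffer(rng.uniform(300, 2000)), {}))
            pub.append((shapely.Point(rng.uniform(0, 1e4, 2)).buffer(rng.uniform(300, 2000)),
                        {"agency": ["USFS", "DOD", "STATE"][i % 3]}))
        tm = build_tier_map(pas, VectorLayer(ease), VectorLayer(pub), None, STUDY)
        total = sum(g.area for g in tm.vector_tiers().values())
        assert total == pytest.approx(STUDY.area, rel=1e-4)  # 0.01%


class TestCoverageForSpecies:
    def test_fully_protected_species(self):
        rec = _record({"PROTECTED_GAP12": 100.0})
        assert rec.pct_by_tier["PROTECTED_GAP12"] == pytest.approx(100.0)
        assert rec.earliest_adequate_tier == "PROTECTED_GAP12"

    def test_adequate_protection_achievable_on_public_land(self):
        # ground-squirrel-style profile: 1.9% protected now, 51.4% on other
        # federal land, so the cascade crosses 30% at OTHER_FEDERAL
        rec = _record({"PROTECTED_GAP12": 1.9, "OTHER_FEDERAL": 51.4})
        assert rec.cumulative_pct["EASEMENT"] < 30.0
        assert rec.cumulative_pct["OTHER_FEDERAL"] == pytest.approx(53.3, abs=0.01)
        assert rec.earliest_adequate_tier == "OTHER_FEDERAL"

    def test_threshold_boundary_inclusive(self):
        rec = _record({"PROTECTED_GAP12": 30.0})
        assert rec.earliest_adequate_tier == "PROTECTED_GAP12"
        rec_excl = _record({"PROTECTED_GAP12": 30.0})
        assert count_adequate([rec_excl], "PROTECTED_GAP12", inclusive=False) == 0

    def test_percentages_sum_to_100(self):
        rec = _record({"PROTECTED_GAP12": 10.0, "USFS_BLM": 25.0, "STATE": 5.0})
        assert sum(rec.pct_by_tier.values()) == pytest.approx(100.0, abs=0.01)
        cums = [rec.cumulative_pct[t] for t in TIER_ORDER]
        assert cums == sorted(cums)
        assert cums[-1] == pytest.approx(100.0, abs=0.01)

    def test_zero_area_range_is_error(self):
        tm = build_tier_map([], None, None, None, STUDY)
        sp = SpeciesRange.__new__(SpeciesRange)
        sp.species_id, sp.tetrapod_class = "z", "bird"
        sp.geometry, sp.total_range_km2 = shapely.Polygon(), 0.0
        with pytest.raises(ValueError):
            coverage_for_species(sp, tm)


class TestCountAdequate:
    def test_monotone_along_cascade(self):
        recs = [
            _record({"PROTECTED_GAP12": 40.0}, sid="a"),
            _record({"USFS_BLM": 35.0}, sid="b"),
            _record({"STATE": 50.0}, sid="c"),
            _record({}, sid="d"),  # everything private-other
        ]
        counts = [count_adequate(recs, t) for t in TIER_ORDER]
        assert counts == sorted(counts)
        assert counts[0] == 1 and counts[2] == 2 and counts[4] == 3
        # tier-less species still reaches 30% once private land enters
        assert counts[-1] == 4

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            count_adequate([], "NOT_A_TIER")


class TestClassSummary:
    def test_mean_of_two_species(self):
        recs = [
            _record({"PROTECTED_GAP12": 100.0}, tclass="bird", sid="a"),
            _record({}, tclass="bird", sid="b"),
        ]
        df = class_summary(recs)
        got = df[(df.tetrapod_class == "bird") & (df.tier_id == "PROTECTED_GAP12")]
        assert got.mean_pct.iloc[0] == pytest.approx(50.0)

    def test_matches_groupby_oracle(self, default_world):
        from gapcover.experiments import world_tier_map_via_pipeline

        tm = world_tier_map_via_pipeline(default_world)
        recs = [coverage_for_species(r, tm) for r in default_world.ranges[:40]]
        df = class_summary(recs)
        raw = pd.DataFrame(
            [
                {"tetrapod_class": r.tetrapod_class, "tier_id": t, "pct": r.pct_by_tier[t]}
                for r in recs
                for t in TIER_ORDER
            ]
        )
        oracle = raw.groupby(["tetrapod_class", "tier_id"])["pct"].mean()
        for _, row in df.iterrows():
            assert row.mean_pct == pytest.approx(oracle.loc[(row.tetrapod_class, row.tier_id)])
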