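"""Tiered land-designation coverage of endangered-species ranges.

Land is partitioned into an ordered cascade of designation tiers —
highly protected (GAP 1-2), conservation easements, USFS/BLM, other
federal, state, undeveloped private, and remaining (developed/cropland)
private land.  For each species the percent of its range in each tier is
accumulated along that order; a species is *adequately protected* once
its cumulative coverage reaches the 30% rule-of-thumb threshold, and the
earliest tier at which that happens says what kind of land conversion
could deliver adequate protection.

Overlaps between source layers are resolved by precedence: a location
belongs to the first tier in the canonical order whose source covers it
(e.g. a USFS parcel already managed as GAP 2 counts as protected, and an
easement on state land counts as state land).  The undeveloped-private
tier may be a raster cell set (see ``private_lands``); the final
private-other tier is then the residual, which keeps per-species
percentages summing to exactly 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geo_io import M2_PER_KM2, VectorLayer, polygonal
from .preprocess import ProtectedArea, SpeciesRange, SLIVER_KM2
from .private_lands import CellSet, range_pct_on_undeveloped_private

log = logging.getLogger(__name__)

__all__ = [
    "TIER_ORDER",
    "DEFAULT_THRESHOLD_PCT",
    "TierMap",
    "CoverageRecord",
    "build_tier_map",
    "coverage_for_species",
    "count_adequate",
    "class_summary",
    "agency_tier",
]

TIER_ORDER = (
    "PROTECTED_GAP12",
    "EASEMENT",
    "USFS_BLM",
    "OTHER_FEDERAL",
    "STATE",
    "PRIVATE_UNDEVELOPED",
    "PRIVATE_OTHER",
)

#: Rule-of-thumb fraction of a species' range that must be protected for
#: persistence, standing in for species-specific viability analysis.
DEFAULT_THRESHOLD_PCT = 30.0


def agency_tier(agency: str) -> str:
    """Map a public-land agency attribute to its designation tier."""
    a = agency.strip().upper()
    if a in ("USFS", "BLM"):
        return "USFS_BLM"
    if a.startswith("STATE"):
        return "STATE"
    return "OTHER_FEDERAL"


@dataclass
class TierMap:
    """Mutually exclusive, ordered partition of the study area.

    ``tiers`` maps tier_id -> geometry, or -> CellSet for the rasterised
    undeveloped-private tier, or -> None for a residual tier (whatever the
    study boundary is not otherwise assigned to).
    """

    tiers: dict[str, BaseGeometry | CellSet | None]
    study_boundary: BaseGeometry
    order: tuple[str, ...] = TIER_ORDER

    def vector_tiers(self) -> dict[str, BaseGeometry]:
        return {
            t: g for t, g in self.tiers.items() if isinstance(g, BaseGeometry)
        }


@dataclass
class CoverageRecord:
    species_id: str
    tetrapod_class: str
    pct_by_tier: dict[str, float]
    cumulative_pct: dict[str, float]
    earliest_adequate_tier: str | None
    threshold: float = DEFAULT_THRESHOLD_PCT


def build_tier_map(
    protected: Sequence[ProtectedArea],
    easements: VectorLayer | None,
    public: VectorLayer | None,
    undeveloped_private: BaseGeometry | CellSet | None,
    study_boundary: BaseGeometry,
) -> TierMap:
    """Resolve source layers into the exclusive tier partition.

    Each location goes to the first tier in canonical order whose source
    layer covers it; later tiers are differenced against everything above
    them.  Geometry extending outside the study boundary is clipped with a
    warning.  ``public`` features are routed by their ``agency`` attribute
    (USFS/BLM, STATE*, else other-federal).
    """
    raw: dict[str, list[BaseGeometry]] = {t: [] for t in TIER_ORDER}
    raw["PROTECTED_GAP12"] = [pa.geometry for pa in protected]
    if easements is not None:
        raw["EASEMENT"] = easements.geometries()
    if public is not None:
        for geom, attrs in public.features:
            raw[agency_tier(str(attrs.get("agency", "")))].append(geom)

    tiers: dict[str, BaseGeometry | CellSet | None] = {}
    higher = shapely.Polygon()  # union of all higher-precedence tiers
    for tier in ("PROTECTED_GAP12", "EASEMENT", "USFS_BLM", "OTHER_FEDERAL", "STATE"):
        geoms = raw[tier]
        union = shapely.union_all(geoms) if geoms else shapely.Polygon()
        outside = union.difference(study_boundary).area / M2_PER_KM2
        if outside > SLIVER_KM2:
            log.warning("tier %s extends %.3f km^2 outside the study boundary; clipped",
                        tier, outside)
        union = polygonal(union.intersection(study_boundary))
        tiers[tier] = polygonal(union.difference(higher))
        higher = shapely.union_all([higher, union])

    if isinstance(undeveloped_private, CellSet):
        tiers["PRIVATE_UNDEVELOPED"] = undeveloped_private.drop_inside(higher)
        tiers["PRIVATE_OTHER"] = None  # residual of the partition
    elif isinstance(undeveloped_private, BaseGeometry):
        und = polygonal(
            undeveloped_private.intersection(study_boundary).difference(higher)
        )
        tiers["PRIVATE_UNDEVELOPED"] = und
        higher = shapely.union_all([higher, und])
        tiers["PRIVATE_OTHER"] = polygonal(study_boundary.difference(higher))
    else:
        tiers["PRIVATE_UNDEVELOPED"] = shapely.Polygon()
        tiers["PRIVATE_OTHER"] = polygonal(study_boundary.difference(higher))
    return TierMap(tiers, study_boundary)


def coverage_for_species(
    rng: SpeciesRange,
    tier_map: TierMap,
    threshold: float = DEFAULT_THRESHOLD_PCT,
    inclusive: bool = True,
) -> CoverageRecord:
    """Percent of one species' range in each tier, with the 30% cascade.

    Vector tiers are measured by exact polygon overlay; a CellSet tier by
    the cell-centre rule; a residual tier receives 100 minus the rest, so
    the percentages always total 100.
    """
    if rng.total_range_km2 <= 0:
        raise ValueError(f"species {rng.species_id}: zero-area range")
    pct: dict[str, float] = {}
    residual_tier: str | None = None
    for tier in tier_map.order:
        src = tier_map.tiers.get(tier)
        if src is None:
            residual_tier = tier
            continue
        if isinstance(src, CellSet):
            pct[tier] = range_pct_on_undeveloped_private(rng, src)
        else:
            inter = rng.geometry.intersection(src).area / M2_PER_KM2
            pct[tier] = 100.0 * inter / rng.total_range_km2
    if residual_tier is not None:
        pct[residual_tier] = max(0.0, 100.0 - sum(pct.values()))

    cumulative: dict[str, float] = {}
    running = 0.0
    earliest: str | None = None
    for tier in tier_map.order:
        running += pct.get(tier, 0.0)
        cumulative[tier] = running
        if earliest is None and _adequate(running, threshold, inclusive):
            earliest = tier
    return CoverageRecord(
        species_id=rng.species_id,
        tetrapod_class=rng.tetrapod_class,
        pct_by_tier={t: pct.get(t, 0.0) for t in tier_map.order},
        cumulative_pct=cumulative,
        earliest_adequate_tier=earliest,
        threshold=threshold,
    )


def _adequate(cum_pct: float, threshold: float, inclusive: bool) -> bool:
    return cum_pct >= threshold if inclusive else cum_pct > threshold


def count_adequate(
    records: Sequence[CoverageRecord],
    through_tier: str,
    inclusive: bool = True,
) -> int:
    """Species whose cumulative coverage through ``through_tier`` is adequate."""
    if through_tier not in TIER_ORDER:
        raise ValueError(f"unknown tier {through_tier!r}")
    return sum(
        _adequate(r.cumulative_pct[through_tier], r.threshold, inclusive)
        for r in records
    )


def class_summary(records: Sequence[CoverageRecord]) -> pd.DataFrame:
    """Mean percent of range per tier, by tetrapod class (long format)."""
    rows = [
        {"tetrapod_class": r.tetrapod_class, "tier_id": t, "pct": r.pct_by_tier[t]}
        for r in records
        for t in r.pct_by_tier
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["tetrapod_class", "tier_id"], sort=False)["pct"]
        .mean()
        .reset_index()
        .rename(columns={"pct": "mean_pct"})
    )
    return out
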