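"""Protected-area selection rules and species-range normalisation.

The analysis considers only *highly protected* areas: GAP status 1 or 2
(managed for biodiversity with no extractive uses).  Units smaller than
5 km^2 are removed so that a sliver of protection does not count a large
species as covered; the cut is applied to whole protected-area features
*before* they are split along ecoregion boundaries, so post-split pieces
may be smaller than 5 km^2.  Species ranges are dissolved to one
multipolygon per listed population and clipped to the study boundary,
which defines the denominator for every coverage percentage downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import shapely
from shapely import STRtree
from shapely.geometry.base import BaseGeometry

from .geo_io import M2_PER_KM2, SchemaError, VectorLayer, polygonal

log = logging.getLogger(__name__)

__all__ = [
    "Ecoregion",
    "ProtectedArea",
    "SpeciesRange",
    "DEFAULT_MIN_AREA_KM2",
    "SLIVER_KM2",
    "TETRAPOD_CLASSES",
    "select_protected",
    "filter_min_area",
    "split_by_ecoregion",
    "normalize_ranges",
]

#: Minimum protected-area size retained (strictly smaller units removed).
DEFAULT_MIN_AREA_KM2 = 5.0

#: Overlay noise floor: pieces/overlaps below 1 m^2 are discarded everywhere.
SLIVER_KM2 = 1.0e-6

TETRAPOD_CLASSES = ("amphibian", "bird", "mammal", "reptile")


@dataclass
class Ecoregion:
    ecoregion_id: str
    geometry: BaseGeometry
    area_km2: float = 0.0

    def __post_init__(self) -> None:
        if self.area_km2 == 0.0:
            self.area_km2 = self.geometry.area / M2_PER_KM2


@dataclass
class ProtectedArea:
    """One protected-area feature (or, after splitting, one piece of one)."""

    pa_id: str
    geometry: BaseGeometry
    gap_status: int
    area_km2: float = 0.0
    ecoregion_id: str | None = None

    def __post_init__(self) -> None:
        if self.area_km2 == 0.0:
            self.area_km2 = self.geometry.area / M2_PER_KM2


@dataclass
class SpeciesRange:
    """A listed population's dissolved range, clipped to the study boundary."""

    species_id: str
    tetrapod_class: str
    geometry: BaseGeometry
    total_range_km2: float = 0.0

    def __post_init__(self) -> None:
        if self.total_range_km2 == 0.0:
            self.total_range_km2 = self.geometry.area / M2_PER_KM2


def select_protected(
    pas: VectorLayer, allowed_gap: frozenset[int] | set[int] = frozenset({1, 2})
) -> list[ProtectedArea]:
    """Keep protected areas whose ``gap_status`` is in ``allowed_gap``.

    Every feature must carry an integer gap_status in 1..4; anything else
    is a schema error rather than a silent drop.
    """
    out: list[ProtectedArea] = []
    for i, (geom, attrs) in enumerate(pas.features):
        if "gap_status" not in attrs:
            raise SchemaError(f"feature {i} missing required attribute 'gap_status'")
        status = attrs["gap_status"]
        if not isinstance(status, (int,)) or isinstance(status, bool):
            try:
                status = int(status)
            except (TypeError, ValueError):
                raise SchemaError(f"feature {i}: gap_status {status!r} is not an integer")
        if status not in (1, 2, 3, 4):
            raise SchemaError(f"feature {i}: gap_status {status} outside 1-4")
        if status in allowed_gap:
            out.append(
                ProtectedArea(
                    pa_id=str(attrs.get("pa_id", f"pa{i}")),
                    geometry=geom,
                    gap_status=status,
                )
            )
    return out


def filter_min_area(
    pas: list[ProtectedArea], min_km2: float = DEFAULT_MIN_AREA_KM2
) -> list[ProtectedArea]:
    """Remove protected areas strictly smaller than ``min_km2``.

    A unit of exactly ``min_km2`` is retained ("less than" removed).
    """
    if min_km2 < 0:
        raise ValueError("min_km2 must be non-negative")
    kept = [pa for pa in pas if pa.area_km2 >= min_km2]
    if len(kept) < len(pas):
        log.info("area filter: removed %d of %d protected areas (< %g km^2)",
                 len(pas) - len(kept), len(pas), min_km2)
    return kept


def split_by_ecoregion(
    pas: list[ProtectedArea],
    ecoregions: list[Ecoregion],
    sliver_km2: float = SLIVER_KM2,
) -> list[ProtectedArea]:
    """Split each protected area along ecoregion boundaries.

    Each output piece is the intersection of one input unit with one
    ecoregion and carries the parent ``pa_id`` plus the ``ecoregion_id``.
    Pieces below the sliver tolerance are dropped; a unit outside every
    ecoregion is dropped with a warning.
    """
    tree = STRtree([e.geometry for e in ecoregions])
    pieces: list[ProtectedArea] = []
    n_outside = 0
    for pa in pas:
        got_any = False
        for idx in tree.query(pa.geometry):
            eco = ecoregions[idx]
            inter = polygonal(pa.geometry.intersection(eco.geometry))
            area_km2 = inter.area / M2_PER_KM2
            if area_km2 < sliver_km2:
                continue
            pieces.append(
                ProtectedArea(
                    pa_id=pa.pa_id,
                    geometry=inter,
                    gap_status=pa.gap_status,
                    area_km2=area_km2,
                    ecoregion_id=eco.ecoregion_id,
                )
            )
            got_any = True
        if not got_any:
            n_outside += 1
    if n_outside:
        log.warning("split_by_ecoregion: %d protected areas outside all ecoregions dropped",
                    n_outside)
    return pieces


def normalize_ranges(
    ranges: VectorLayer, study_boundary: BaseGeometry
) -> list[SpeciesRange]:
    """Dissolve range features per species, clip to the study boundary.

    Requires ``species_id`` and ``tetrapod_class`` attributes; a species id
    appearing with two different classes is a schema error.  Species whose
    clipped range is empty are dropped with a warning.
    """
    by_species: dict[str, list[BaseGeometry]] = {}
    classes: dict[str, str] = {}
    for i, (geom, attrs) in enumerate(ranges.features):
        for attr in ("species_id", "tetrapod_class"):
            if attr not in attrs:
                raise SchemaError(f"feature {i} missing required attribute {attr!r}")
        sid = str(attrs["species_id"])
        tclass = str(attrs["tetrapod_class"])
        if sid in classes and classes[sid] != tclass:
            raise SchemaError(
                f"species {sid!r} appears with conflicting tetrapod_class "
                f"({classes[sid]!r} vs {tclass!r})"
            )
        classes[sid] = tclass
        by_species.setdefault(sid, []).append(geom)

    out: list[SpeciesRange] = []
    n_dropped = 0
    for sid in by_species:
        dissolved = shapely.union_all(by_species[sid])
        clipped = polygonal(dissolved.intersection(study_boundary))
        area_km2 = clipped.area / M2_PER_KM2
        if clipped.is_empty or area_km2 <= 0.0:
            n_dropped += 1
            continue
        out.append(SpeciesRange(sid, classes[sid], clipped, area_km2))
    if n_dropped:
        log.warning("normalize_ranges: dropped %d species with no range inside the study boundary",
                    n_dropped)
    return out
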