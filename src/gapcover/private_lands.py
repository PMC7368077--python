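"""Private-lands mask and undeveloped-private classification.

Private land is everything inside the study boundary that is neither
highly protected nor otherwise public.  The landcover raster is masked to
that private geometry and *undeveloped* private land is the part whose
landcover is not any "developed" class and not "cultivated crops".  The
result is kept as a raster cell set (cell membership decided by the
cell-centre rule), mirroring the vector-public / raster-private hybrid of
the original workflow; the quantisation error of any range-overlay
percentage shrinks linearly with cell size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .geo_io import LandcoverGrid, M2_PER_KM2
from .preprocess import SpeciesRange

log = logging.getLogger(__name__)

__all__ = [
    "UndevelopedRule",
    "NLCD_EXCLUDED_CODES",
    "CellSet",
    "private_mask",
    "undeveloped_private_geometry",
    "range_pct_on_undeveloped_private",
]

#: NLCD developed (21-24) and cultivated-crops (82) classes.
NLCD_EXCLUDED_CODES = frozenset({21, 22, 23, 24, 82})


@dataclass(frozen=True)
class UndevelopedRule:
    """Landcover codes that disqualify private land as "undeveloped"."""

    excluded_codes: frozenset[int] = NLCD_EXCLUDED_CODES

    def __post_init__(self) -> None:
        if not self.excluded_codes:
            raise ValueError("excluded_codes must be non-empty")

    def validate_against(self, legend: dict[int, str]) -> None:
        extra = set(self.excluded_codes) - set(legend)
        if extra:
            raise ValueError(f"excluded codes {sorted(extra)} not in the legend")


@dataclass
class CellSet:
    """An area-weighted set of retained square grid cells.

    ``mask`` is boolean with row 0 at the top; ``origin`` is the (x, y) of
    the grid's top-left corner.  The set stands in for a polygon whose
    area is ``n_cells * cell_size**2``.
    """

    origin: tuple[float, float]
    cell_size: float
    mask: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.cell_size**2 / M2_PER_KM2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates (x, y) of retained cell centres (1-D arrays)."""
        rows, cols = np.nonzero(self.mask)
        x0, ytop = self.origin
        return (
            x0 + (cols + 0.5) * self.cell_size,
            ytop - (rows + 0.5) * self.cell_size,
        )

    def drop_inside(self, geom: BaseGeometry) -> "CellSet":
        """New CellSet without the cells whose centre lies inside ``geom``."""
        if geom.is_empty:
            return CellSet(self.origin, self.cell_size, self.mask.copy())
        xs, ys = self.cell_centers()
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, xs, ys)
        rows, cols = np.nonzero(self.mask)
        mask = self.mask.copy()
        mask[rows[inside], cols[inside]] = False
        return CellSet(self.origin, self.cell_size, mask)


def private_mask(
    study_boundary: BaseGeometry, public_and_protected: list[BaseGeometry]
) -> BaseGeometry:
    """Study boundary minus the union of public and protected geometries."""
    if not public_and_protected:
        return study_boundary
    union = shapely.union_all(public_and_protected)
    return study_boundary.difference(union)


def undeveloped_private_geometry(
    mask: BaseGeometry, grid: LandcoverGrid, rule: UndevelopedRule
) -> CellSet:
    """Cells of private land whose landcover is neither developed nor crops.

    A cell is retained when its centre lies inside ``mask`` and its code is
    valid (not nodata) and not excluded.  The grid must cover the mask
    footprint; otherwise an error reports the uncovered fraction.
    """
    if grid.legend:
        rule.validate_against(grid.legend)
    gxmin, gymin, gxmax, gymax = grid.bounds
    footprint = shapely.box(gxmin, gymin, gxmax, gymax)
    uncovered = mask.difference(footprint).area
    if uncovered > 1e-6 * max(mask.area, 1.0):
        frac = uncovered / mask.area if mask.area else 0.0
        raise ValueError(
            f"landcover grid does not cover the private mask "
            f"(uncovered fraction {frac:.4%})"
        )
    X, Y = grid.cell_centers()
    shapely.prepare(mask)
    in_mask = shapely.contains_xy(mask, X.ravel(), Y.ravel()).reshape(X.shape)
    excluded = np.isin(grid.values, sorted(rule.excluded_codes))
    valid = grid.values != grid.nodata
    keep = in_mask & valid & ~excluded
    log.info(
        "undeveloped private: %d of %d cells retained (%.1f km^2)",
        int(keep.sum()),
        keep.size,
        keep.sum() * grid.cell_area_km2,
    )
    return CellSet(grid.origin, grid.cell_size, keep)


def range_pct_on_undeveloped_private(
    rng: SpeciesRange | BaseGeometry,
    cells: CellSet,
    total_range_km2: float | None = None,
) -> float:
    """Percent of a species' range lying on undeveloped private cells.

    Counts retained cells whose centre falls inside the range geometry;
    the percentage denominator is the species' total range in the study
    boundary.
    """
    if isinstance(rng, SpeciesRange):
        geom = rng.geometry
        total = rng.total_range_km2
    else:
        geom = rng
        if total_range_km2 is None:
            total_range_km2 = geom.area / M2_PER_KM2
        total = total_range_km2
    if total <= 0:
        raise ValueError("total range area must be positive")
    xs, ys = cells.cell_centers()
    if xs.size == 0:
        return 0.0
    # bbox prefilter keeps the point-in-polygon test proportional to range size
    bxmin, bymin, bxmax, bymax = geom.bounds
    sel = (xs >= bxmin) & (xs <= bxmax) & (ys >= bymin) & (ys <= bymax)
    if not sel.any():
        return 0.0
    shapely.prepare(geom)
    n_in = int(shapely.contains_xy(geom, xs[sel], ys[sel]).sum())
    area_km2 = n_in * cells.cell_size**2 / M2_PER_KM2
    return 100.0 * area_km2 / total
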