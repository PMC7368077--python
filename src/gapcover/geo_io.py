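"""Planar vector/raster/table I/O for the gap-analysis pipeline.

All geometry is handled in a single planar equal-area coordinate reference
system (the *study CRS*) whose linear unit is the metre, so that polygon
areas divided by 10^6 are the km^2 quantities the analysis reports.  The
package performs no reprojection: every file must already carry (or be
declared to be in) the study CRS, and a mismatch is an error rather than a
silent assumption.  Synthetic worlds use a trivial local Cartesian CRS.

Formats
-------
* Vector layers: GeoJSON ``FeatureCollection`` with a legacy-style top-level
  ``crs`` member naming the planar CRS.
* Rasters: ESRI ASCII grid (``.asc``) with a one-line ``<path>.crs`` sidecar
  (or an explicit ``crs=`` argument).
* Tables: UTF-8 CSV with a header row.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger(__name__)

__all__ = [
    "StudyCRS",
    "LOCAL_CRS",
    "ALBERS_CONUS_CRS",
    "VectorLayer",
    "LandcoverGrid",
    "SchemaError",
    "CRSError",
    "read_vector",
    "write_vector",
    "read_landcover",
    "write_landcover",
    "read_table",
    "write_table",
    "polygonal",
]

M2_PER_KM2 = 1.0e6


class SchemaError(ValueError):
    """An input layer is missing or violates a required attribute."""


class CRSError(ValueError):
    """A layer's coordinate reference system is absent or mismatched."""


@dataclass(frozen=True)
class StudyCRS:
    """A planar equal-area CRS identified by a text code; unit is metres.

    The package treats the identifier as a label to be matched between
    layers, not as something to transform between: all inputs of one run
    must share a single StudyCRS.
    """

    identifier: str = "EPSG:5070"
    linear_unit: str = "metre"


#: Albers equal-area conic over the conterminous USA — the conventional
#: choice for km^2 area accounting on real national data.
ALBERS_CONUS_CRS = StudyCRS("EPSG:5070")

#: Trivial local Cartesian plane in metres, used by synthetic worlds.
LOCAL_CRS = StudyCRS("LOCAL_CARTESIAN_M")


def polygonal(geom: BaseGeometry) -> BaseGeometry:
    """Extract the polygonal part of ``geom`` (drops points/lines).

    ``make_valid`` can return a GeometryCollection mixing polygons with
    lower-dimensional debris; only the areal part is meaningful here.
    """
    if geom.is_empty:
        return geom
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            return shapely.Polygon()
        return shapely.union_all(polys)
    return shapely.Polygon()


@dataclass
class VectorLayer:
    """An in-memory polygon layer: (geometry, attributes) pairs plus a CRS."""

    features: list[tuple[BaseGeometry, dict[str, Any]]]
    crs: StudyCRS = LOCAL_CRS

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]


@dataclass
class LandcoverGrid:
    """A categorical landcover raster on a square-cell grid.

    ``values`` is row-major with row 0 at the *top* of the grid; ``origin``
    is the (x, y) of the top-left corner.  Codes absent from ``legend`` are
    replaced by ``nodata`` on read.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: int = -9999
    crs: StudyCRS = LOCAL_CRS
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("landcover values must be an integer array")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("landcover values must be a 2-D array of size >= 1x1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-centre coordinates, shape = values.shape."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / M2_PER_KM2


# ---------------------------------------------------------------------------
# Vector I/O


def _read_geojson_crs(doc: Mapping[str, Any]) -> str | None:
    crs = doc.get("crs")
    if isinstance(crs, Mapping):
        name = crs.get("properties", {}).get("name")
        if isinstance(name, str):
            return name
    return None


def read_vector(
    path: str | os.PathLike,
    required_attrs: Sequence[str] = (),
    crs: StudyCRS = LOCAL_CRS,
) -> VectorLayer:
    """Read a GeoJSON polygon layer, repair invalid geometries, check schema.

    Parameters
    ----------
    path
        A GeoJSON FeatureCollection. Its ``crs`` member must name
        ``crs.identifier``; a file with no ``crs`` member is accepted only
        if it declares nothing contradictory (plain RFC-7946 files are
        assumed to be in the study CRS the caller declares).
    required_attrs
        Attribute names every feature must carry.
    crs
        The study CRS the layer is declared to be in.

    Invalid geometries are repaired with ``make_valid``; features whose
    repaired geometry is empty or non-polygonal are dropped with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    declared = _read_geojson_crs(doc)
    if declared is not None and declared != crs.identifier:
        raise CRSError(
            f"{path}: layer CRS {declared!r} != study CRS {crs.identifier!r} "
            "(no reprojection is performed)"
        )

    features: list[tuple[BaseGeometry, dict[str, Any]]] = []
    n_repaired = n_dropped = 0
    raw_features = doc.get("features", [])
    for i, feat in enumerate(raw_features):
        attrs = dict(feat.get("properties") or {})
        for attr in required_attrs:
            if attr not in attrs:
                raise SchemaError(
                    f"{path}: feature {i} missing required attribute {attr!r}"
                )
        geom_json = feat.get("geometry")
        if geom_json is None:
            n_dropped += 1
            continue
        geom = shape(geom_json)
        if not geom.is_valid:
            geom = polygonal(shapely.make_valid(geom))
            n_repaired += 1
        geom = polygonal(geom)
        if geom.is_empty:
            n_dropped += 1
            continue
        features.append((geom, attrs))
    if n_repaired:
        log.warning("%s: repaired %d invalid geometries", path, n_repaired)
    if n_dropped:
        log.warning("%s: dropped %d empty/unrepairable features", path, n_dropped)
    if raw_features and not features:
        raise ValueError(f"{path}: every feature was empty or unrepairable")
    return VectorLayer(features, crs)


def write_vector(layer: VectorLayer, path: str | os.PathLike) -> None:
    """Write a VectorLayer as GeoJSON with a legacy ``crs`` member."""
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": layer.crs.identifier}},
        "features": [
            {"type": "Feature", "properties": attrs, "geometry": mapping(geom)}
            for geom, attrs in layer.features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_landcover(
    path: str | os.PathLike,
    legend: Mapping[int, str],
    crs: StudyCRS | None = None,
) -> LandcoverGrid:
    """Read a categorical ESRI ASCII grid with a declared legend.

    The CRS comes from ``crs`` or from a one-line sidecar file
    ``<path>.crs``; with neither, reading fails (no silent assumption).
    Cells whose code is not in ``legend`` become nodata with a warning.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if crs is None:
        sidecar = path + ".crs"
        if not os.path.exists(sidecar):
            raise CRSError(f"{path}: no CRS given and no sidecar {sidecar}")
        with open(sidecar, "r", encoding="utf-8") as fh:
            crs = StudyCRS(fh.read().strip())

    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, ndmin=2)
    for key in _ASC_HEADER_KEYS:
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key!r}")
    if not np.allclose(body, np.round(body)):
        raise ValueError(f"{path}: landcover band is not integer-valued")
    values = np.round(body).astype(np.int32)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: body shape {values.shape} != header ({nrows}, {ncols})")
    nodata = int(header.get("nodata_value", -9999))
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)

    known = set(int(k) for k in legend) | {nodata}
    unknown = ~np.isin(values, sorted(known))
    if unknown.any():
        log.warning(
            "%s: %d cells carry codes outside the legend; treated as nodata",
            path,
            int(unknown.sum()),
        )
        values = np.where(unknown, nodata, values)
    return LandcoverGrid(values, origin, cell, nodata, crs, dict(legend))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_landcover(grid: LandcoverGrid, path: str | os.PathLike) -> None:
    """Write an ESRI ASCII grid plus its ``.crs`` sidecar."""
    path = os.fspath(path)
    nrows, ncols = grid.values.shape
    x0, ytop = grid.origin
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {ytop - nrows * grid.cell_size:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"nodata_value {grid.nodata}\n")
        np.savetxt(fh, grid.values, fmt="%d")
    with open(path + ".crs", "w", encoding="utf-8") as fh:
        fh.write(grid.crs.identifier + "\n")


# ---------------------------------------------------------------------------
# Tables


def write_table(
    rows: Iterable[Mapping[str, Any]],
    path: str | os.PathLike,
    schema: Sequence[str] | None = None,
) -> None:
    """Write records as a UTF-8 CSV with a header row.

    Numeric fields round-trip losslessly well beyond 6 significant digits.
    An empty record list needs an explicit ``schema`` for the header.
    """
    rows = list(rows)
    if not rows:
        if schema is None:
            raise ValueError("cannot write an empty table without a schema")
        df = pd.DataFrame(columns=list(schema))
    else:
        df = pd.DataFrame(rows, columns=list(schema) if schema else None)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
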