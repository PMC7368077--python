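"""Synthetic landscapes with known ground truth for every pipeline stage.

A synthetic world is a rectangular study extent partitioned into
contiguous ecoregions (bounded Voronoi cells around random sites),
populated with blob-shaped species ranges (log-normal areas, harmonic
radial perturbation of a disc), protected areas whose centroid law can
be biased toward or away from species-rich locations, an ordered tier
labelling of the remaining land with controlled proportions, and a
categorical landcover grid with developed/cropland cells.

Two properties make the generator a test oracle rather than a fixture:

* With ``bias_beta = 0`` protected-area placement runs through exactly
  the same rigid-placement sampler as the null model, so the observed
  layout *is* one draw from the null and the better/worse classifier
  must be symmetric by construction.
* Every species' exact fraction of range per tier is computed by
  polygon/cell overlay at generation time and kept as ground truth, so
  pipeline coverage percentages can be checked against known values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely import STRtree
from shapely.geometry import Polygon, box
from shapely.geometry.base import BaseGeometry

from .geo_io import LOCAL_CRS, LandcoverGrid, M2_PER_KM2, VectorLayer, polygonal
from .null_model import PlacementConfig, _uniform_point_in, random_rigid_placement
from .preprocess import (
    DEFAULT_MIN_AREA_KM2,
    Ecoregion,
    ProtectedArea,
    SpeciesRange,
    TETRAPOD_CLASSES,
)
from .private_lands import CellSet
from .coverage import TIER_ORDER, TierMap

log = logging.getLogger(__name__)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "TOY_LEGEND",
    "TOY_EXCLUDED_CODES",
    "generate_ecoregions",
    "ecoregions_from_sites",
    "generate_species_ranges",
    "place_protected_biased",
    "assign_tiers_and_landcover",
    "generate_world",
    "write_world",
    "blob_polygon",
]

#: Three-code toy landcover legend used by synthetic worlds.
TOY_LEGEND = {1: "natural", 2: "developed", 3: "cultivated crops"}
TOY_EXCLUDED_CODES = frozenset({2, 3})


@dataclass
class WorldConfig:
    """Study conditions of a synthetic world.

    Defaults describe a 100 x 100 km landscape of eight ecoregions of
    comparable size.  Species ranges are log-normal (median 100 km^2)
    and cluster around one richness hotspot per ecoregion, mirroring how
    real endangered species concentrate in hotspots; a typical ecoregion
    overlaps a dozen or more species.  Highly protected areas are small
    relative to ranges (median 10 km^2), number at least five per
    ecoregion, and cover a few percent of the land; public-land tiers
    take about a third of the remainder and easements a few tenths of
    the protected share, echoing the relative magnitudes reported for
    the USA.
    """

    extent_km: tuple[float, float] = (100.0, 100.0)
    n_ecoregions: int = 8
    n_species: int = 140
    range_median_km2: float = 100.0
    range_log_sd: float = 0.6
    range_shape: float = 0.3  # blob irregularity in [0, 1]
    n_hotspots: int | None = None  # None: one richness hotspot per ecoregion
    hotspot_sd_km: float = 4.0
    p_hotspot: float = 0.8  # share of species tied to a hotspot
    n_protected: int = 40
    pa_median_km2: float = 10.0
    pa_log_sd: float = 0.5
    min_pa_per_ecoregion: int = 5
    n_multiuse: int = 6  # GAP 3/4 decoys exercising the selection filter
    bias_beta: float = 0.0
    tier_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "EASEMENT": 0.02,
            "USFS_BLM": 0.22,
            "OTHER_FEDERAL": 0.08,
            "STATE": 0.09,
            "PRIVATE": 0.59,
        }
    )
    landcover_p_developed: float = 0.10
    landcover_p_crops: float = 0.20
    cell_size_m: float = 100.0
    tier_cells: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.tier_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"tier_proportions must sum to 1, got {total}")
        for name in ("n_ecoregions", "n_species", "n_protected"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def extent_m(self) -> tuple[float, float]:
        return (self.extent_km[0] * 1000.0, self.extent_km[1] * 1000.0)

    def extent_box(self) -> Polygon:
        w, h = self.extent_m
        return box(0.0, 0.0, w, h)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    study_boundary: BaseGeometry
    ecoregions: list[Ecoregion]
    ranges: list[SpeciesRange]
    protected: list[ProtectedArea]  # all GAP statuses, pre-filtering
    easements: VectorLayer | None = None
    public: VectorLayer | None = None
    tier_map: TierMap | None = None
    landcover: LandcoverGrid | None = None
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Ecoregions


def ecoregions_from_sites(
    sites: np.ndarray, extent_m: tuple[float, float]
) -> list[Ecoregion]:
    """Bounded Voronoi partition of the extent around the given sites.

    Each site's cell is bounded by reflecting the whole site set across
    the four extent edges, which closes every cell inside the rectangle;
    the cells tile the extent exactly.
    """
    w, h = extent_m
    sites = np.asarray(sites, dtype=float)
    frame = box(0.0, 0.0, w, h)
    if len(sites) == 1:
        return [Ecoregion("eco00", frame)]
    mirrored = np.vstack(
        [
            sites,
            sites * [-1, 1],                 # across x = 0
            sites * [1, -1],                 # across y = 0
            np.column_stack([2 * w - sites[:, 0], sites[:, 1]]),
            np.column_stack([sites[:, 0], 2 * h - sites[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    out: list[Ecoregion] = []
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[i]]
        assert -1 not in region, "reflected Voronoi cell should be finite"
        poly = Polygon(vor.vertices[region])
        poly = polygonal(poly.intersection(frame))
        out.append(Ecoregion(f"eco{i:02d}", poly))
    return out


def generate_ecoregions(cfg: WorldConfig, rng: np.random.Generator) -> list[Ecoregion]:
    """Seeded random contiguous partition of the extent into ecoregions.

    Random sites are relaxed towards a centroidal Voronoi layout (two
    Lloyd iterations) so region areas are comparable in scale, as real
    level-II ecoregions are; without relaxation the smallest Voronoi
    cells can be an order of magnitude below the mean.
    """
    w, h = cfg.extent_m
    # keep sites apart so no cell degenerates to a sliver
    min_gap = 0.15 * math.sqrt(w * h / cfg.n_ecoregions)
    for _ in range(100):
        sites = rng.uniform([0, 0], [w, h], size=(cfg.n_ecoregions, 2))
        if cfg.n_ecoregions == 1:
            break
        d = np.sqrt(((sites[:, None, :] - sites[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > min_gap:
            break
    for _ in range(2):  # Lloyd relaxation
        cells = ecoregions_from_sites(sites, cfg.extent_m)
        sites = np.array([[e.geometry.centroid.x, e.geometry.centroid.y] for e in cells])
    return ecoregions_from_sites(sites, cfg.extent_m)


# ---------------------------------------------------------------------------
# Species ranges


def blob_polygon(
    center: tuple[float, float],
    target_area_m2: float,
    irregularity: float,
    rng: np.random.Generator,
    n_vertices: int = 64,
) -> Polygon:
    """A simple blob: disc radius perturbed by low-order harmonics.

    The radial profile r(phi) = 1 + sum_k a_k cos(k phi + psi_k) over
    harmonics k = 2..5 stays positive because the amplitudes are capped,
    so the polygon is always simple; it is then rescaled to the exact
    target area.
    """
    phi = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = np.ones_like(phi)
    if irregularity > 0:
        amps = irregularity * rng.uniform(0.0, 1.0, 4) / np.arange(2, 6)
        total = amps.sum()
        if total > 0.7:
            amps *= 0.7 / total
        phases = rng.uniform(0.0, 2.0 * math.pi, 4)
        for k, (a, p) in enumerate(zip(amps, phases), start=2):
            r = r + a * np.cos(k * phi + p)
    xs = center[0] + r * np.cos(phi)
    ys = center[1] + r * np.sin(phi)
    poly = Polygon(np.column_stack([xs, ys]))
    scale = math.sqrt(target_area_m2 / poly.area)
    xs = center[0] + (xs - center[0]) * scale
    ys = center[1] + (ys - center[1]) * scale
    return Polygon(np.column_stack([xs, ys]))


def generate_species_ranges(
    cfg: WorldConfig, ecoregions: list[Ecoregion], rng: np.random.Generator
) -> list[SpeciesRange]:
    """Blob ranges with log-normal areas and clustered centres.

    A fraction ``p_hotspot`` of species centre near a richness hotspot
    (Gaussian scatter of sd ``hotspot_sd_km``); the rest are uniform over
    the extent.  By default one hotspot is drawn inside each ecoregion —
    ecoregions delimit distinct habitats with their own endemic clusters —
    while an integer ``n_hotspots`` scatters that many hotspots uniformly
    over the whole extent instead.  Clustering reproduces the hotspot
    structure of real endangered-species richness, which is what gives a
    placement bias something to attract to or avoid.
    """
    frame = cfg.extent_box()
    out: list[SpeciesRange] = []
    w, h = cfg.extent_m
    mu = math.log(cfg.range_median_km2 * M2_PER_KM2)
    if cfg.n_hotspots is None:
        hotspots = np.array(
            [_uniform_point_in(e.geometry, rng) for e in ecoregions]
        )
    else:
        hotspots = rng.uniform([0, 0], [w, h], size=(max(cfg.n_hotspots, 0), 2))
    for i in range(cfg.n_species):
        area = rng.lognormal(mu, cfg.range_log_sd)
        if len(hotspots) and rng.random() < cfg.p_hotspot:
            hx, hy = hotspots[rng.integers(len(hotspots))]
            center = (
                float(np.clip(rng.normal(hx, cfg.hotspot_sd_km * 1000.0), 0, w)),
                float(np.clip(rng.normal(hy, cfg.hotspot_sd_km * 1000.0), 0, h)),
            )
        else:
            center = (rng.uniform(0, w), rng.uniform(0, h))
        blob = blob_polygon(center, area, cfg.range_shape, rng)
        clipped = polygonal(blob.intersection(frame))
        out.append(
            SpeciesRange(
                species_id=f"sp{i:03d}",
                tetrapod_class=TETRAPOD_CLASSES[i % len(TETRAPOD_CLASSES)],
                geometry=clipped,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Protected areas with placement bias


def _richness_function(ranges: list[SpeciesRange]):
    geoms = [r.geometry for r in ranges]
    for g in geoms:
        shapely.prepare(g)
    tree = STRtree(geoms)

    def richness(x: float, y: float) -> int:
        pt = shapely.points(x, y)
        return sum(1 for i in tree.query(pt) if shapely.contains_xy(geoms[i], x, y))

    return richness


def _biased_sampler(eco_geom, beta, richness, rng_probe: np.random.Generator):
    """Centroid sampler with density proportional to exp(-beta * richness).

    Rejection from the uniform law inside the ecoregion, referenced to
    the most favourable richness seen on a probe sample so acceptance is
    well scaled; a draw cap guarantees termination in pathological cases.
    """
    probe = np.array(
        [richness(*_uniform_point_in(eco_geom, rng_probe)) for _ in range(128)]
    )
    ref = probe.min() if beta > 0 else probe.max()

    def sample(rng: np.random.Generator) -> tuple[float, float]:
        best, best_logp = None, -np.inf
        for _ in range(10000):
            x, y = _uniform_point_in(eco_geom, rng)
            logp = -beta * (richness(x, y) - ref)
            if logp >= 0 or rng.random() < math.exp(logp):
                return x, y
            if logp > best_logp:
                best, best_logp = (x, y), logp
        return best  # pragma: no cover - pathological richness surface

    return sample


def place_protected_biased(
    cfg: WorldConfig,
    ecoregions: list[Ecoregion],
    ranges: list[SpeciesRange],
    rng: np.random.Generator,
) -> list[ProtectedArea]:
    """Protected areas placed with a controllable richness bias.

    Each unit is assigned to an ecoregion with probability proportional
    to ecoregion area, then rigidly placed inside it through the null
    model's placement sampler.  ``bias_beta = 0`` uses that sampler's
    uniform centroid law unchanged (the observed layout is one null
    draw); ``bias_beta > 0`` repels centroids from species-rich
    locations, ``< 0`` attracts them.  GAP 1 and 2 alternate; a few GAP
    3/4 multiple-use decoys are appended for the selection filter to
    remove.
    """
    pcfg = PlacementConfig(n_iterations=1, seed=0, containment=1.0)
    mu = math.log(cfg.pa_median_km2 * M2_PER_KM2)
    areas = np.array([e.area_km2 for e in ecoregions])
    richness = _richness_function(ranges) if cfg.bias_beta != 0.0 else None
    samplers: dict[str, object] = {}

    # stratified allocation: a minimum number of units per ecoregion (every
    # real ecoregion contains several highly protected areas), remainder
    # proportional to ecoregion area
    n_eco = len(ecoregions)
    alloc = [i % n_eco for i in range(min(cfg.min_pa_per_ecoregion * n_eco, cfg.n_protected))]
    while len(alloc) < cfg.n_protected:
        alloc.append(int(rng.choice(n_eco, p=areas / areas.sum())))
    alloc += [int(rng.choice(n_eco, p=areas / areas.sum())) for _ in range(cfg.n_multiuse)]

    out: list[ProtectedArea] = []
    n_total = cfg.n_protected + cfg.n_multiuse
    for i in range(n_total):
        eco = ecoregions[alloc[i]]
        target = rng.lognormal(mu, cfg.pa_log_sd)
        # truncate so the unit fits comfortably inside its ecoregion
        cap = 0.25 * eco.area_km2 * M2_PER_KM2
        for _ in range(20):
            if target <= cap:
                break
            target = rng.lognormal(mu, cfg.pa_log_sd)
        target = min(target, cap)
        blob = blob_polygon((0.0, 0.0), target, cfg.range_shape, rng)
        decoy = i >= cfg.n_protected
        sampler = None
        if cfg.bias_beta != 0.0 and not decoy:
            if eco.ecoregion_id not in samplers:
                samplers[eco.ecoregion_id] = _biased_sampler(
                    eco.geometry, cfg.bias_beta, richness, rng
                )
            sampler = samplers[eco.ecoregion_id]
        geom, fb = random_rigid_placement(blob, eco, rng, pcfg, point_sampler=sampler)
        if fb:
            log.debug("world PA %d clipped to ecoregion %s", i, eco.ecoregion_id)
        gap = (1, 2)[i % 2] if not decoy else (3, 4)[i % 2]
        out.append(
            ProtectedArea(
                pa_id=f"pa{i:03d}",
                geometry=geom,
                gap_status=gap,
                ecoregion_id=eco.ecoregion_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tiers, landcover and ground truth


def _exact_cell_area_km2(
    geom: BaseGeometry, grid: LandcoverGrid, code_mask: np.ndarray
) -> float:
    """Exact area of ``geom`` intersected with the cells where code_mask.

    Cells wholly inside/outside the geometry are decided by buffered
    point-in-polygon tests; only the boundary band of cells pays for an
    exact box intersection.
    """
    if geom.is_empty:
        return 0.0
    nrows, ncols = grid.values.shape
    x0, ytop = grid.origin
    cs = grid.cell_size
    bxmin, bymin, bxmax, bymax = geom.bounds
    c0 = max(0, int((bxmin - x0) // cs))
    c1 = min(ncols - 1, int((bxmax - x0) // cs))
    r0 = max(0, int((ytop - bymax) // cs))
    r1 = min(nrows - 1, int((ytop - bymin) // cs))
    if c1 < c0 or r1 < r0:
        return 0.0
    sub = code_mask[r0 : r1 + 1, c0 : c1 + 1]
    xs = x0 + (np.arange(c0, c1 + 1) + 0.5) * cs
    ys = ytop - (np.arange(r0, r1 + 1) + 0.5) * cs
    X, Y = np.meshgrid(xs, ys)
    half_diag = cs * math.sqrt(2.0) / 2.0
    outer = geom.buffer(half_diag)
    inner = geom.buffer(-half_diag)
    shapely.prepare(outer)
    near = shapely.contains_xy(outer, X.ravel(), Y.ravel()).reshape(X.shape)
    if inner.is_empty:
        full = np.zeros_like(near)
    else:
        shapely.prepare(inner)
        full = shapely.contains_xy(inner, X.ravel(), Y.ravel()).reshape(X.shape)
    area = float((full & sub).sum()) * cs * cs
    band = near & ~full & sub
    if band.any():
        rows, cols = np.nonzero(band)
        bx = X[rows, cols]
        by = Y[rows, cols]
        boxes = shapely.box(bx - cs / 2, by - cs / 2, bx + cs / 2, by + cs / 2)
        area += float(shapely.area(shapely.intersection(boxes, geom)).sum())
    return area / M2_PER_KM2


def assign_tiers_and_landcover(
    cfg: WorldConfig,
    ecoregions: list[Ecoregion],
    pas: list[ProtectedArea],
    ranges: list[SpeciesRange],
    rng: np.random.Generator,
) -> tuple[TierMap, LandcoverGrid, VectorLayer, VectorLayer, pd.DataFrame]:
    """Label non-protected land with tiers, draw landcover, compute truth.

    Non-protected land is tessellated into small Voronoi cells that are
    greedily labelled EASEMENT / USFS_BLM / OTHER_FEDERAL / STATE until
    each tier's target share of non-protected land is met (within one
    cell); the rest is private.  Private land receives a landcover grid
    with developed/crops cells at the configured probabilities; the
    undeveloped-private tier is the cell set of natural-cover cells whose
    centre is private.  Ground truth per species is computed by exact
    overlay (cell-exact for the raster tier).

    Returns (tier_map, landcover, easements_layer, public_layer, truth).
    """
    frame = cfg.extent_box()
    w, h = cfg.extent_m
    qualifying = [
        pa
        for pa in pas
        if pa.gap_status in (1, 2) and pa.area_km2 >= DEFAULT_MIN_AREA_KM2
    ]
    pa_union = polygonal(
        shapely.intersection(
            shapely.union_all([pa.geometry for pa in qualifying]) if qualifying else Polygon(),
            frame,
        )
    )

    # -- tier tessellation ---------------------------------------------------
    sites = rng.uniform([0, 0], [w, h], size=(cfg.tier_cells, 2))
    cells = ecoregions_from_sites(sites, cfg.extent_m)
    pieces = []
    for c in cells:
        piece = polygonal(c.geometry.difference(pa_union))
        if piece.area > 1.0:  # > 1 m^2
            pieces.append(piece)
    order = rng.permutation(len(pieces))
    non_pa_area = sum(p.area for p in pieces)
    tier_geoms: dict[str, list[BaseGeometry]] = {
        "EASEMENT": [],
        "USFS_BLM": [],
        "OTHER_FEDERAL": [],
        "STATE": [],
        "PRIVATE": [],
    }
    idx = 0
    for tier in ("EASEMENT", "USFS_BLM", "OTHER_FEDERAL", "STATE"):
        target = cfg.tier_proportions.get(tier, 0.0) * non_pa_area
        acc = 0.0
        while acc < target and idx < len(order):
            piece = pieces[order[idx]]
            tier_geoms[tier].append(piece)
            acc += piece.area
            idx += 1
    while idx < len(order):
        tier_geoms["PRIVATE"].append(pieces[order[idx]])
        idx += 1

    easements = VectorLayer(
        [(g, {"easement_id": f"ease{i:03d}"}) for i, g in enumerate(tier_geoms["EASEMENT"])],
        LOCAL_CRS,
    )
    agencies = {"USFS_BLM": ("USFS", "BLM"), "OTHER_FEDERAL": ("DOD", "BOR"), "STATE": ("STATE",)}
    public_feats = []
    for tier, names in agencies.items():
        for i, g in enumerate(tier_geoms[tier]):
            public_feats.append((g, {"agency": names[i % len(names)]}))
    public = VectorLayer(public_feats, LOCAL_CRS)

    private_geom = polygonal(shapely.union_all(tier_geoms["PRIVATE"]))

    # -- landcover -----------------------------------------------------------
    cs = cfg.cell_size_m
    ncols = int(round(w / cs))
    nrows = int(round(h / cs))
    p_dev, p_crop = cfg.landcover_p_developed, cfg.landcover_p_crops
    u = rng.random((nrows, ncols))
    codes = np.where(u < p_dev, 2, np.where(u < p_dev + p_crop, 3, 1)).astype(np.int32)
    grid = LandcoverGrid(codes, (0.0, h), cs, nodata=-9999, crs=LOCAL_CRS, legend=dict(TOY_LEGEND))

    X, Y = grid.cell_centers()
    shapely.prepare(private_geom)
    center_private = shapely.contains_xy(private_geom, X.ravel(), Y.ravel()).reshape(X.shape)
    und_mask = center_private & (codes == 1)
    und_cells = CellSet((0.0, h), cs, und_mask)

    tier_map = TierMap(
        tiers={
            "PROTECTED_GAP12": pa_union,
            "EASEMENT": polygonal(shapely.union_all(tier_geoms["EASEMENT"]))
            if tier_geoms["EASEMENT"]
            else Polygon(),
            "USFS_BLM": polygonal(shapely.union_all(tier_geoms["USFS_BLM"]))
            if tier_geoms["USFS_BLM"]
            else Polygon(),
            "OTHER_FEDERAL": polygonal(shapely.union_all(tier_geoms["OTHER_FEDERAL"]))
            if tier_geoms["OTHER_FEDERAL"]
            else Polygon(),
            "STATE": polygonal(shapely.union_all(tier_geoms["STATE"]))
            if tier_geoms["STATE"]
            else Polygon(),
            "PRIVATE_UNDEVELOPED": und_cells,
            "PRIVATE_OTHER": None,
        },
        study_boundary=frame,
    )

    # -- ground truth --------------------------------------------------------
    natural = codes == 1
    rows = []
    for r in ranges:
        a = r.total_range_km2
        row: dict[str, object] = {
            "species_id": r.species_id,
            "tetrapod_class": r.tetrapod_class,
            "total_range_km2": a,
        }
        for tier in ("PROTECTED_GAP12", "EASEMENT", "USFS_BLM", "OTHER_FEDERAL", "STATE"):
            src = tier_map.tiers[tier]
            inter = r.geometry.intersection(src).area / M2_PER_KM2 if not src.is_empty else 0.0
            row[f"pct_{tier}"] = 100.0 * inter / a
        g_priv = polygonal(r.geometry.intersection(private_geom))
        priv_km2 = g_priv.area / M2_PER_KM2
        und_km2 = _exact_cell_area_km2(g_priv, grid, natural)
        row["pct_PRIVATE_UNDEVELOPED"] = 100.0 * und_km2 / a
        row["pct_PRIVATE_OTHER"] = 100.0 * max(priv_km2 - und_km2, 0.0) / a
        rows.append(row)
    truth = pd.DataFrame(rows)
    return tier_map, grid, easements, public, truth


# ---------------------------------------------------------------------------
# Orchestration


def generate_world(cfg: WorldConfig, include_tiers: bool = True) -> SyntheticWorld:
    """Generate a complete deterministic world from (config, seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_eco, rng_sp, rng_pa, rng_tier = (np.random.default_rng(s) for s in ss.spawn(4))
    ecoregions = generate_ecoregions(cfg, rng_eco)
    ranges = generate_species_ranges(cfg, ecoregions, rng_sp)
    pas = place_protected_biased(cfg, ecoregions, ranges, rng_pa)
    world = SyntheticWorld(
        config=cfg,
        study_boundary=cfg.extent_box(),
        ecoregions=ecoregions,
        ranges=ranges,
        protected=pas,
    )
    if include_tiers:
        tier_map, grid, easements, public, truth = assign_tiers_and_landcover(
            cfg, ecoregions, pas, ranges, rng_tier
        )
        world.tier_map = tier_map
        world.landcover = grid
        world.easements = easements
        world.public = public
        world.truth = truth
    return world


def write_world(world: SyntheticWorld, out_dir: str) -> dict[str, str]:
    """Write a world to disk in the formats the pipeline consumes.

    Returns a mapping of layer name to file path.
    """
    import os

    from . import geo_io

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _vec(name: str, layer: VectorLayer) -> None:
        path = os.path.join(out_dir, f"{name}.geojson")
        geo_io.write_vector(layer, path)
        paths[name] = path

    _vec(
        "ecoregions",
        VectorLayer(
            [(e.geometry, {"ecoregion_id": e.ecoregion_id}) for e in world.ecoregions],
            LOCAL_CRS,
        ),
    )
    _vec(
        "protected",
        VectorLayer(
            [
                (pa.geometry, {"pa_id": pa.pa_id, "gap_status": pa.gap_status})
                for pa in world.protected
            ],
            LOCAL_CRS,
        ),
    )
    _vec(
        "ranges",
        VectorLayer(
            [
                (
                    r.geometry,
                    {"species_id": r.species_id, "tetrapod_class": r.tetrapod_class},
                )
                for r in world.ranges
            ],
            LOCAL_CRS,
        ),
    )
    _vec("boundary", VectorLayer([(world.study_boundary, {})], LOCAL_CRS))
    if world.easements is not None:
        _vec("easements", world.easements)
    if world.public is not None:
        _vec("public", world.public)
    if world.landcover is not None:
        path = os.path.join(out_dir, "landcover.asc")
        geo_io.write_landcover(world.landcover, path)
        paths["landcover"] = path
    if world.truth is not None:
        path = os.path.join(out_dir, "truth.csv")
        world.truth.to_csv(path, index=False)
        paths["truth"] = path
    return paths
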