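"""One-config orchestration of the full gap-analysis pipeline.

Stages: read layers -> protected-area selection rules -> null model ->
tier map -> per-species coverage -> summaries.  All randomness flows
from the single config seed; re-running an identical (config, seed)
reproduces every CSV bit-identically.  A manifest records the config
hash, seed, library versions and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
import yaml

from . import geo_io
from .coverage import (
    DEFAULT_THRESHOLD_PCT,
    TIER_ORDER,
    build_tier_map,
    class_summary,
    count_adequate,
    coverage_for_species,
)
from .geo_io import LandcoverGrid, StudyCRS, VectorLayer
from .null_model import PlacementConfig, richness_grid, run_null_model, summarize
from .preprocess import (
    DEFAULT_MIN_AREA_KM2,
    Ecoregion,
    filter_min_area,
    normalize_ranges,
    select_protected,
    split_by_ecoregion,
)
from .private_lands import UndevelopedRule, private_mask, undeveloped_private_geometry

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "config_for_world"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    ecoregions: str = ""
    protected: str = ""
    ranges: str = ""
    boundary: str = ""
    easements: str | None = None
    public: str | None = None
    landcover: str | None = None
    crs: str = "LOCAL_CARTESIAN_M"
    iterations: int = 1000
    seed: int = 0
    max_tries: int = 100
    containment: float = 1.0
    min_area_km2: float = DEFAULT_MIN_AREA_KM2
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    inclusive_threshold: bool = True
    legend: dict[int, str] = field(default_factory=dict)
    excluded_codes: list[int] = field(default_factory=lambda: [21, 22, 23, 24, 82])
    richness_pixel_km2: float = 5.0
    out_dir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.legend = {int(k): str(v) for k, v in (cfg.legend or {}).items()}
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Problems preventing a run; empty list iff runnable."""
    problems: list[str] = []
    for name in ("ecoregions", "protected", "ranges", "boundary"):
        path = getattr(cfg, name)
        if not path:
            problems.append(f"{name}: no path configured")
        elif not os.path.exists(path):
            problems.append(f"{name}: file not found: {path}")
    for name in ("easements", "public", "landcover"):
        path = getattr(cfg, name)
        if path is not None and not os.path.exists(path):
            problems.append(f"{name}: file not found: {path}")
    if not (0.0 < cfg.threshold_pct <= 100.0):
        problems.append("threshold_pct: must be in (0, 100]")
    if cfg.iterations < 1:
        problems.append("iterations: must be >= 1")
    if not (0.0 < cfg.containment <= 1.0):
        problems.append("containment: must be in (0, 1]")
    if cfg.min_area_km2 < 0:
        problems.append("min_area_km2: must be non-negative")
    if cfg.landcover is not None and not cfg.excluded_codes:
        problems.append("excluded_codes: must be non-empty when landcover is used")
    if cfg.landcover is not None and not cfg.legend:
        problems.append("legend: required when landcover is used")
    return problems


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write all artifacts, return the manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    os.makedirs(cfg.out_dir, exist_ok=True)
    crs = StudyCRS(cfg.crs)
    manifest: dict = {
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "shapely": shapely.__version__,
        },
        "stages": {},
        "counts": {},
    }

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start (seed=%d)", name, cfg.seed)
                return self

            def __exit__(self, exc_type, exc, tb):
                ok = exc_type is None
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "complete": ok,
                }
                if not ok:
                    log.error("stage %s: FAILED", name)
                return False

        return _T()

    with stage("read"):
        eco_layer = geo_io.read_vector(cfg.ecoregions, ["ecoregion_id"], crs)
        pa_layer = geo_io.read_vector(cfg.protected, ["gap_status"], crs)
        range_layer = geo_io.read_vector(cfg.ranges, ["species_id", "tetrapod_class"], crs)
        boundary_layer = geo_io.read_vector(cfg.boundary, [], crs)
        boundary = shapely.union_all(boundary_layer.geometries())
        easements = (
            geo_io.read_vector(cfg.easements, [], crs) if cfg.easements else None
        )
        public = geo_io.read_vector(cfg.public, ["agency"], crs) if cfg.public else None
        grid: LandcoverGrid | None = (
            geo_io.read_landcover(cfg.landcover, cfg.legend, crs)
            if cfg.landcover
            else None
        )

    with stage("preprocess"):
        ecoregions = [
            Ecoregion(str(attrs["ecoregion_id"]), geom)
            for geom, attrs in eco_layer.features
        ]
        selected = select_protected(pa_layer)
        filtered = filter_min_area(selected, cfg.min_area_km2)
        pieces = split_by_ecoregion(filtered, ecoregions)
        by_eco: dict[str, list] = {}
        for p in pieces:
            by_eco.setdefault(p.ecoregion_id, []).append(p)
        ranges = normalize_ranges(range_layer, boundary)
        manifest["counts"].update(
            {
                "protected_in": len(pa_layer),
                "protected_gap12": len(selected),
                "protected_after_area_filter": len(filtered),
                "pieces_after_split": len(pieces),
                "species": len(ranges),
                "ecoregions": len(ecoregions),
                "ecoregions_with_pieces": len(by_eco),
            }
        )
        log.info(
            "filters: %d -> %d (GAP 1-2) -> %d (>= %g km^2) -> %d pieces",
            len(pa_layer), len(selected), len(filtered), cfg.min_area_km2, len(pieces),
        )

    with stage("null_model"):
        pcfg = PlacementConfig(
            n_iterations=cfg.iterations,
            seed=cfg.seed,
            max_tries=cfg.max_tries,
            containment=cfg.containment,
        )
        results = run_null_model(by_eco, ranges, ecoregions, pcfg)
        rows = [
            {
                "ecoregion_id": r.ecoregion_id,
                "observed": r.observed_count,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "difference": r.difference,
                "classification": r.classification,
                "fallback_placements": r.fallback_placements,
            }
            for r in results
        ]
        geo_io.write_table(
            rows,
            os.path.join(cfg.out_dir, "nullmodel_results.csv"),
            schema=[
                "ecoregion_id", "observed", "null_mean", "null_sd",
                "difference", "classification", "fallback_placements",
            ],
        )
        summ = summarize(results) if results else None
        geo_io.write_table(
            [
                {
                    "n_ecoregions": summ.n_ecoregions,
                    "pct_better": summ.pct_better,
                    "pct_equal": summ.pct_equal,
                    "pct_worse": summ.pct_worse,
                }
            ]
            if summ
            else [],
            os.path.join(cfg.out_dir, "nullmodel_summary.csv"),
            schema=["n_ecoregions", "pct_better", "pct_equal", "pct_worse"],
        )

    with stage("tier_map"):
        und_cells = None
        if grid is not None:
            rule = UndevelopedRule(frozenset(cfg.excluded_codes))
            others = [pa.geometry for pa in filtered]
            if easements is not None:
                others += easements.geometries()
            if public is not None:
                others += public.geometries()
            mask = private_mask(boundary, others)
            und_cells = undeveloped_private_geometry(mask, grid, rule)
        tier_map = build_tier_map(filtered, easements, public, und_cells, boundary)

    with stage("coverage"):
        records = [
            coverage_for_species(r, tier_map, cfg.threshold_pct, cfg.inclusive_threshold)
            for r in ranges
        ]
        cov_rows = []
        for rec in records:
            row: dict = {
                "species_id": rec.species_id,
                "tetrapod_class": rec.tetrapod_class,
            }
            for t in TIER_ORDER:
                row[f"pct_{t}"] = rec.pct_by_tier[t]
            for t in TIER_ORDER:
                row[f"cum_{t}"] = rec.cumulative_pct[t]
            row["earliest_adequate_tier"] = rec.earliest_adequate_tier or ""
            cov_rows.append(row)
        schema = (
            ["species_id", "tetrapod_class"]
            + [f"pct_{t}" for t in TIER_ORDER]
            + [f"cum_{t}" for t in TIER_ORDER]
            + ["earliest_adequate_tier"]
        )
        geo_io.write_table(cov_rows, os.path.join(cfg.out_dir, "coverage.csv"), schema)

        summary = class_summary(records) if records else pd.DataFrame(
            columns=["tetrapod_class", "tier_id", "mean_pct"]
        )
        summary.to_csv(
            os.path.join(cfg.out_dir, "class_summary.csv"),
            index=False,
            float_format="%.12g",
        )
        cascade = [
            {"through_tier": t, "n_adequate": count_adequate(records, t, cfg.inclusive_threshold)}
            for t in TIER_ORDER
        ] if records else []
        geo_io.write_table(
            cascade,
            os.path.join(cfg.out_dir, "adequacy_cascade.csv"),
            schema=["through_tier", "n_adequate"],
        )
        manifest["counts"]["species_adequate_by_tier"] = {
            c["through_tier"]: c["n_adequate"] for c in cascade
        }

    with stage("richness"):
        if ranges:
            counts, origin, side = richness_grid(
                ranges, cfg.richness_pixel_km2, extent=boundary.bounds
            )
            rich = LandcoverGrid(counts, origin, side, nodata=-1, crs=crs)
            geo_io.write_landcover(rich, os.path.join(cfg.out_dir, "richness.asc"))

    manifest["complete"] = all(s["complete"] for s in manifest["stages"].values())
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def config_for_world(world_dir: str, out_dir: str, **overrides) -> PipelineConfig:
    """A PipelineConfig wired to the layers ``write_world`` produced."""
    from .synthetic import TOY_EXCLUDED_CODES, TOY_LEGEND

    def _opt(name: str) -> str | None:
        path = os.path.join(world_dir, name)
        return path if os.path.exists(path) else None

    cfg = PipelineConfig(
        ecoregions=os.path.join(world_dir, "ecoregions.geojson"),
        protected=os.path.join(world_dir, "protected.geojson"),
        ranges=os.path.join(world_dir, "ranges.geojson"),
        boundary=os.path.join(world_dir, "boundary.geojson"),
        easements=_opt("easements.geojson"),
        public=_opt("public.geojson"),
        landcover=_opt("landcover.asc"),
        legend={k: v for k, v in TOY_LEGEND.items()},
        excluded_codes=sorted(TOY_EXCLUDED_CODES),
        out_dir=out_dir,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg
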