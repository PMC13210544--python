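"""End-to-end orchestration: simulate → fuse → FPAR → NPP → evaluate.

One :class:`PipelineConfig` drives all stages from a single global seed;
per-stage seeds are derived by hashing the stage name against it, so any
stage can be rerun in isolation and the whole run is reproducible
bit-for-bit. When an output directory is given, every raster goes out as a
GeoTIFF and every table as CSV, indexed by a manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .fpar import ExtremaTable, FparConstants
from .fusion import FusionParams, fuse_series
from .geo_io import write_raster
from .grids import RasterGrid, RasterSeries
from .metrics import PairedSample, evaluate
from .npp import NppMonthly, casa_npp, zonal_table
from .stress import CROP_NAMES, MAIZE, OTHER, RICE, CropParams, MeteoMonthly
from .synthetic import (
    CloudSpec,
    CropPhenology,
    MeteoSpec,
    SceneSpec,
    apply_cloud_mask,
    default_phenology,
    degrade_to_coarse,
    forward_truth_npp,
    make_fields,
    make_landscape,
    make_meteo,
    render_fine_series,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "validate_config",
           "default_config", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


@dataclass
class PipelineConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    phenology: dict[int, CropPhenology] = field(default_factory=default_phenology)
    cloud: CloudSpec = field(default_factory=CloudSpec)
    meteo: MeteoSpec = field(default_factory=MeteoSpec)
    fusion: FusionParams = field(default_factory=FusionParams)
    fpar_constants: FparConstants = field(default_factory=FparConstants)
    crop_params: CropParams = field(default_factory=CropParams)
    months: list[int] = field(default_factory=lambda: [6, 7, 8, 9, 10])
    noise_sd: float = 0.02
    coarse_bias: float = 0.02
    coarse_noise_sd: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        # one global seed drives every stochastic stage
        self.scene = dataclasses.replace(self.scene, seed=stage_seed(self.seed, "scene"))
        self.cloud = dataclasses.replace(self.cloud, seed=stage_seed(self.seed, "cloud"))
        self.meteo = dataclasses.replace(self.meteo, seed=stage_seed(self.seed, "meteo"))


def default_config(seed: int = 42) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def validate_config(raw: Mapping[str, Any]) -> list[str]:
    """Check a raw (parsed, not yet constructed) configuration mapping.

    Returns an empty list when every cross-module invariant holds; each
    violation names the offending field.
    """
    v: list[str] = []
    fractions = raw.get("crop_fractions", (0.40, 0.35, 0.25))
    if abs(sum(fractions) - 1.0) > 1e-9:
        v.append(f"crop_fractions: sum {sum(fractions):.3f} != 1")
    fpar_min = raw.get("fpar_min", 0.001)
    fpar_max = raw.get("fpar_max", 0.950)
    if not fpar_min < fpar_max:
        v.append(f"fpar_min/fpar_max: need fpar_min < fpar_max, got {fpar_min} >= {fpar_max}")
    if not 0 <= fpar_min and fpar_max <= 1:
        v.append("fpar_min/fpar_max: must lie in [0, 1]")
    scale = raw.get("scale_factor", 10)
    if scale < 2:
        v.append(f"scale_factor: must be >= 2, got {scale}")
    if raw.get("grid_size", 200) < 16:
        v.append("grid_size: must be >= 16")
    months = raw.get("months", [6, 7, 8, 9, 10])
    if not months:
        v.append("months: empty")
    eps = raw.get("epsilon_max", {MAIZE: 1.1, RICE: 0.9})
    eps = {int(k): float(val) for k, val in eps.items()}
    for code, value in eps.items():
        if value <= 0:
            v.append(f"epsilon_max[{code}]: must be > 0")
    # every crop with a positive fraction must be parameterized
    for i, code in enumerate((MAIZE, RICE)):
        if i < len(fractions) and fractions[i] > 0 and code not in eps:
            v.append(f"epsilon_max: missing entry for crop {CROP_NAMES[code]}")
    par_fraction = raw.get("par_fraction", 0.5)
    if not 0 < par_fraction <= 1:
        v.append(f"par_fraction: must be in (0, 1], got {par_fraction}")
    for key in ("noise_sd", "coarse_noise_sd"):
        if raw.get(key, 0.02) < 0:
            v.append(f"{key}: must be >= 0")
    for key in ("jul_aug_gap", "other_gap"):
        p = raw.get(key, 0.1)
        if not 0 <= p <= 1:
            v.append(f"{key}: must be in [0, 1], got {p}")
    return v


def config_from_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a flat mapping (e.g. parsed YAML)."""
    problems = validate_config(raw)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    scene_kwargs: dict[str, Any] = {}
    if "grid_size" in raw:
        n = int(raw["grid_size"])
        base = SceneSpec().grid
        scene_kwargs["grid"] = dataclasses.replace(base, n_rows=n, n_cols=n)
    if "crop_fractions" in raw:
        scene_kwargs["crop_fractions"] = tuple(raw["crop_fractions"])
    if "scale_factor" in raw:
        scene_kwargs["scale_factor"] = int(raw["scale_factor"])
    if "n_fields" in raw:
        scene_kwargs["n_fields"] = int(raw["n_fields"])
    cloud_kwargs = {
        k: raw[k] for k in ("jul_aug_gap", "other_gap", "blob_radius") if k in raw
    }
    fusion_kwargs = {
        k: raw[k]
        for k in ("window_half_size", "n_classes", "min_similar", "pair_mode")
        if k in raw
    }
    crop_kwargs: dict[str, Any] = {}
    if "epsilon_max" in raw:
        crop_kwargs["epsilon_max"] = {
            int(k): float(v) for k, v in raw["epsilon_max"].items()
        }
    if "par_fraction" in raw:
        crop_kwargs["par_fraction"] = float(raw["par_fraction"])
    if "tepsilon2_scale" in raw:
        crop_kwargs["tepsilon2_scale"] = float(raw["tepsilon2_scale"])
    fpar_kwargs = {
        "fpar_min": raw.get("fpar_min", 0.001),
        "fpar_max": raw.get("fpar_max", 0.950),
    }
    return PipelineConfig(
        scene=SceneSpec(**scene_kwargs),
        cloud=CloudSpec(**cloud_kwargs),
        fusion=FusionParams(**fusion_kwargs),
        fpar_constants=FparConstants(
            fpar_max=fpar_kwargs["fpar_max"], fpar_min=fpar_kwargs["fpar_min"]
        ),
        crop_params=CropParams(**crop_kwargs),
        months=list(raw.get("months", [6, 7, 8, 9, 10])),
        noise_sd=float(raw.get("noise_sd", 0.02)),
        coarse_bias=float(raw.get("coarse_bias", 0.02)),
        coarse_noise_sd=float(raw.get("coarse_noise_sd", 0.02)),
        seed=int(raw.get("seed", 42)),
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    crop_map: RasterGrid
    clean_series: RasterSeries
    gapped_series: RasterSeries
    mask_series: RasterSeries
    coarse_series: RasterSeries
    fused_series: RasterSeries
    fusion_report: pd.DataFrame
    fusion_eval: pd.DataFrame
    extrema: ExtremaTable
    meteo: list[MeteoMonthly]
    npp_monthly: list[NppMonthly]
    npp_seasonal: RasterGrid
    truth_monthly: list[NppMonthly]
    truth_seasonal: RasterGrid
    zonal: pd.DataFrame
    recovery_eval: pd.DataFrame
    manifest: pd.DataFrame | None = None


def _fusion_eval(
    fused: RasterSeries, clean: RasterSeries, masks: RasterSeries
) -> pd.DataFrame:
    """Per-date accuracy of the fused series over the filled (previously
    clouded) pixels, against the uncorrupted fine series."""
    rows = []
    for (date, fg), (_, cg), (_, mg) in zip(fused, clean, masks):
        filled = (mg.values > 0) & fg.valid_mask & cg.valid_mask
        if filled.sum() < 2:
            continue
        rep = evaluate(PairedSample(cg.values[filled], fg.values[filled]))
        rows.append({"date": date, **rep.as_dict()})
    return pd.DataFrame(rows)


def _recovery_eval(
    estimated: RasterGrid, truth: RasterGrid, crop_map: RasterGrid
) -> pd.DataFrame:
    rows = []
    for code in sorted(
        int(c)
        for c in np.unique(crop_map.values[crop_map.valid_mask])
        if int(c) != OTHER
    ):
        sel = (
            (crop_map.values == code)
            & crop_map.valid_mask
            & estimated.valid_mask
            & truth.valid_mask
        )
        if sel.sum() < 2:
            continue
        rep = evaluate(PairedSample(truth.values[sel], estimated.values[sel]))
        rows.append({"crop": CROP_NAMES.get(code, str(code)), **rep.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run every stage on a synthetic scene and evaluate against truth.

    Stages: landscape + fine series generation, coarse degradation, cloud
    masking, fusion, scene-derived FPAR extrema, CASA NPP on the fused
    series, forward-model truth NPP on the clean series, and the fusion /
    recovery evaluation tables.
    """
    config = config or PipelineConfig()
    t_start = time.time()

    def _tick(stage: str, t0: float, detail: str = "") -> None:
        log.info("stage %-12s %6.2fs %s", stage, time.time() - t0, detail)

    t0 = time.time()
    crop_map = make_landscape(config.scene)
    fields = make_fields(config.scene)
    clean = render_fine_series(
        crop_map, config.phenology, config.scene, config.noise_sd, fields
    )
    _tick("simulate", t0, f"{len(clean)} dates, {crop_map.spec.shape} grid")

    t0 = time.time()
    coarse = degrade_to_coarse(
        clean,
        config.scene.scale_factor,
        bias=config.coarse_bias,
        noise_sd=config.coarse_noise_sd,
        seed=stage_seed(config.seed, "coarse"),
    )
    gapped, masks = apply_cloud_mask(clean, config.cloud)
    meteo = make_meteo(config.meteo, config.months, config.scene.grid)
    _tick("degrade", t0, "")

    t0 = time.time()
    fused, fusion_report = fuse_series(gapped, coarse, config.fusion)
    fusion_eval = _fusion_eval(fused, clean, masks)
    _tick("fuse", t0, f"{int(fusion_report['n_filled'].sum())} px filled")

    t0 = time.time()
    npp_months, npp_season, extrema = casa_npp(
        fused,
        crop_map,
        meteo,
        crop_params=config.crop_params,
        fpar_constants=config.fpar_constants,
        months=config.months,
    )
    _tick("npp", t0, "")

    t0 = time.time()
    truth_months, truth_season = forward_truth_npp(
        clean, crop_map, meteo, config.crop_params, config.fpar_constants,
        config.months,
    )
    zonal = zonal_table(npp_season, crop_map)
    recovery = _recovery_eval(npp_season, truth_season, crop_map)
    _tick("evaluate", t0, "")

    result = PipelineResult(
        config=config,
        crop_map=crop_map,
        clean_series=clean,
        gapped_series=gapped,
        mask_series=masks,
        coarse_series=coarse,
        fused_series=fused,
        fusion_report=fusion_report,
        fusion_eval=fusion_eval,
        extrema=extrema,
        meteo=meteo,
        npp_monthly=npp_months,
        npp_seasonal=npp_season,
        truth_monthly=truth_months,
        truth_seasonal=truth_season,
        zonal=zonal,
        recovery_eval=recovery,
    )
    if out_dir is not None:
        result.manifest = write_outputs(result, Path(out_dir))
    log.info("pipeline done in %.2fs", time.time() - t_start)
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> pd.DataFrame:
    """Write rasters (GeoTIFF) and tables (CSV) plus a manifest CSV."""
    out_dir = Path(out_dir)
    entries: list[dict[str, str]] = []

    def _raster(stage: str, role: str, rel: str, grid: RasterGrid) -> None:
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        write_raster(grid, path)
        entries.append({"stage": stage, "role": role, "path": rel})

    def _table(stage: str, role: str, rel: str, frame: pd.DataFrame) -> None:
        path = out_dir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False)
        entries.append({"stage": stage, "role": role, "path": rel})

    _raster("simulate", "crop_map", "crop_map.tif", result.crop_map)
    for date, grid in result.fused_series:
        _raster("fuse", "fused_ndvi", f"fused/{date.isoformat()}.tif", grid)
    for m in result.npp_monthly:
        _raster("npp", "npp_monthly", f"npp/month_{m.month:02d}.tif", m.npp)
    _raster("npp", "npp_seasonal", "npp/seasonal.tif", result.npp_seasonal)
    _raster("truth", "npp_truth", "truth/seasonal.tif", result.truth_seasonal)

    _table("fuse", "fusion_report", "fusion_report.csv", result.fusion_report)
    _table("fuse", "fusion_eval", "fusion_eval.csv", result.fusion_eval)
    _table("fpar", "extrema", "extrema.csv", result.extrema.to_frame())
    _table("npp", "zonal", "zonal_npp.csv", result.zonal)
    _table("evaluate", "recovery_eval", "recovery_eval.csv", result.recovery_eval)

    manifest = pd.DataFrame(entries)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
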