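"""APAR and net primary productivity.

NPP(x,t) = APAR(x,t) × LUE(x,t), with APAR(x,t) = PAR(x,t) × FPAR(x,t) and
PAR a fixed fraction (default 50%) of total solar radiation. Monthly maps
are in gC·m⁻²·month⁻¹; the growing-season total (gC·m⁻²·a⁻¹ under a
single-cropping system) is the per-pixel sum over the season's months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fpar import ExtremaTable, FparConstants, build_extrema_table, fpar_monthly
from .grids import RasterGrid, RasterSeries, check_compatible
from .stress import (
    CROP_NAMES,
    OTHER,
    CropParams,
    MeteoMonthly,
    actual_lue,
    optimum_temperature,
    t_stress_high,
    t_stress_low,
    w_stress,
)
from .geo_io import monthly_composite

__all__ = [
    "NppMonthly",
    "ZonalSummary",
    "joules_to_megajoules",
    "par_from_sol",
    "apar",
    "npp_monthly",
    "npp_seasonal",
    "zonal_summary",
    "casa_npp",
]


@dataclass
class NppMonthly:
    month: int
    npp: RasterGrid
    apar: RasterGrid
    par: RasterGrid


@dataclass
class ZonalSummary:
    crop: int
    minimum: float
    maximum: float
    mean: float
    count: int

    def as_dict(self) -> dict:
        return {
            "crop": CROP_NAMES.get(self.crop, str(self.crop)),
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "n": self.count,
        }


def joules_to_megajoules(sol: RasterGrid) -> RasterGrid:
    """Convert raw radiation in J·m⁻² to the MJ·m⁻² the model expects."""
    out = np.where(sol.valid_mask, sol.values / 1e6, np.nan)
    return _wrap(out, sol, sol.label)


def par_from_sol(sol: RasterGrid, par_fraction: float = 0.5) -> RasterGrid:
    """Incident PAR as a fixed fraction of total solar radiation (MJ·m⁻²)."""
    vals = np.where(sol.valid_mask, sol.values, np.nan)
    if np.any(vals < 0):
        raise ValueError("negative solar radiation")
    return _wrap(vals * par_fraction, sol, "PAR")


def apar(par: RasterGrid, fpar: RasterGrid) -> RasterGrid:
    """Absorbed PAR = PAR × FPAR (elementwise; nodata propagates)."""
    check_compatible(par, fpar)
    p = np.where(par.valid_mask, par.values, np.nan)
    f = np.where(fpar.valid_mask, fpar.values, np.nan)
    return _wrap(p * f, par, "APAR")


def npp_monthly(apar_grid: RasterGrid, lue: RasterGrid) -> RasterGrid:
    """Monthly NPP = APAR × LUE, gC·m⁻²·month⁻¹."""
    check_compatible(apar_grid, lue)
    a = np.where(apar_grid.valid_mask, apar_grid.values, np.nan)
    e = np.where(lue.valid_mask, lue.values, np.nan)
    return _wrap(a * e, apar_grid, "NPP")


def npp_seasonal(monthly: list[NppMonthly], strict: bool = False) -> RasterGrid:
    """Per-pixel sum of monthly NPP over the growing season.

    Months where a pixel is nodata are skipped (fusion should leave few
    gaps); ``strict=True`` instead marks any pixel with a missing month as
    nodata. A pixel nodata in every month stays nodata.
    """
    if not monthly:
        raise ValueError("no monthly NPP maps")
    check_compatible(*[m.npp for m in monthly])
    stack = np.stack(
        [np.where(m.npp.valid_mask, m.npp.values, np.nan) for m in monthly]
    )
    if strict:
        out = stack.sum(axis=0)
    else:
        all_nan = np.all(np.isnan(stack), axis=0)
        out = np.nansum(stack, axis=0)
        out[all_nan] = np.nan
    return _wrap(out, monthly[0].npp, "NPP-seasonal")


def zonal_summary(
    seasonal_npp: RasterGrid, crop_map: RasterGrid, crop: int
) -> ZonalSummary:
    """min/max/mean/count of seasonal NPP over one crop's valid pixels."""
    check_compatible(seasonal_npp, crop_map)
    sel = crop_map.valid_mask & (crop_map.values == crop) & seasonal_npp.valid_mask
    vals = seasonal_npp.values[sel]
    if vals.size == 0:
        raise ValueError(f"no valid pixels for crop {crop}")
    return ZonalSummary(
        crop=crop,
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        mean=float(vals.mean()),
        count=int(vals.size),
    )


def zonal_table(seasonal_npp: RasterGrid, crop_map: RasterGrid) -> pd.DataFrame:
    crops = sorted(
        int(c)
        for c in np.unique(crop_map.values[crop_map.valid_mask])
        if int(c) != OTHER
    )
    return pd.DataFrame(
        [zonal_summary(seasonal_npp, crop_map, c).as_dict() for c in crops]
    )


def casa_npp(
    ndvi_series: RasterSeries,
    crop_map: RasterGrid,
    meteo: list[MeteoMonthly],
    crop_params: CropParams | None = None,
    fpar_constants: FparConstants | None = None,
    months: list[int] | None = None,
    extrema: ExtremaTable | None = None,
) -> tuple[list[NppMonthly], RasterGrid, ExtremaTable]:
    """The full CASA chain on a gap-free NDVI series.

    For each month: maximum-value NDVI composite → per-crop FPAR (NDVI + SR
    stretches) → PAR/APAR from solar radiation → stress-scaled LUE → NPP.
    Returns the monthly maps, the seasonal sum, and the extrema table used
    (scene-derived unless one is supplied).
    """
    crop_params = crop_params or CropParams()
    fpar_constants = fpar_constants or FparConstants()
    if months is None:
        months = [m.month for m in meteo]
    meteo_by_month = {m.month: m for m in meteo}
    missing = [m for m in months if m not in meteo_by_month]
    if missing:
        raise ValueError(f"no meteorology for month(s) {missing}")

    if extrema is None:
        extrema = build_extrema_table(
            ndvi_series, crop_map, months, constants=fpar_constants
        )

    ndvi_composites = [monthly_composite(ndvi_series, m, "max") for m in months]
    t_means = [meteo_by_month[m].t_mean for m in months]
    topt = optimum_temperature(ndvi_composites, t_means)

    te1 = RasterGrid(topt.spec, t_stress_low(topt.values), "Te1")

    results: list[NppMonthly] = []
    for month, composite in zip(months, ndvi_composites):
        met = meteo_by_month[month]
        fpar_grid = fpar_monthly(
            ndvi_series, crop_map, extrema, month, fpar_constants
        )
        te2 = RasterGrid(
            topt.spec,
            t_stress_high(
                topt.values, met.t_mean.values, scale=crop_params.tepsilon2_scale
            ),
            "Te2",
        )
        we = RasterGrid(
            topt.spec, w_stress(met.e_actual.values, met.e_potential.values), "We"
        )
        lue = actual_lue(te1, te2, we, crop_map, crop_params)
        par = par_from_sol(met.sol, crop_params.par_fraction)
        apar_grid = apar(par, fpar_grid)
        npp = npp_monthly(apar_grid, lue)
        results.append(NppMonthly(month=month, npp=npp, apar=apar_grid, par=par))

    seasonal = npp_seasonal(results)
    return results, seasonal, extrema


def _wrap(values: np.ndarray, like: RasterGrid, label: str) -> RasterGrid:
    spec = like.spec
    if not np.isnan(spec.nodata):
        values = np.where(np.isnan(values), spec.nodata, values)
    return RasterGrid(spec, values, label)
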