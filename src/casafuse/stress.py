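"""Temperature and water down-regulation of light-use efficiency.

The CASA family of models converts a crop-specific maximum light-use
efficiency εmax (gC·MJ⁻¹) into an actual efficiency by multiplying three
dimensionless stress scalars:

* ``Tε1`` — a quadratic in the pixel's optimum growth temperature ``Topt``
  (the monthly mean temperature of the month in which NDVI peaks), maximal
  (=1) at 20 °C;
* ``Tε2`` — a two-logistic bell in the departure of the month's mean
  temperature from ``Topt``, scaled so its value at ``T = Topt`` is just
  under 1;
* ``Wε`` — a linear function of the ratio of actual to potential
  evapotranspiration, spanning [0.5, 1].

All scalars are clipped to [0, 1] (``Wε`` to [0.5, 1]); clipping is the
conventional guard for temperatures outside the quadratic's physical range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, RasterGrid, check_compatible

__all__ = [
    "MeteoMonthly",
    "CropParams",
    "optimum_temperature",
    "t_stress_low",
    "t_stress_high",
    "w_stress",
    "actual_lue",
]

#: crop codes used throughout the pipeline
OTHER, MAIZE, RICE = 0, 1, 2
CROP_NAMES = {OTHER: "other", MAIZE: "maize", RICE: "rice"}


@dataclass
class MeteoMonthly:
    """Monthly meteorology on the working grid.

    ``t_mean`` in °C, ``sol`` (total solar radiation) in MJ·m⁻²·month⁻¹,
    ``e_actual``/``e_potential`` (actual/potential evapotranspiration) in mm.
    """

    month: int
    t_mean: RasterGrid
    sol: RasterGrid
    e_actual: RasterGrid
    e_potential: RasterGrid

    def __post_init__(self) -> None:
        check_compatible(self.t_mean, self.sol, self.e_actual, self.e_potential)

    @property
    def spec(self) -> GridSpec:
        return self.t_mean.spec


@dataclass
class CropParams:
    """Crop-specific εmax (gC·MJ⁻¹) plus model constants.

    Defaults: maize 1.1, rice 0.9 gC·MJ⁻¹; PAR is taken as 50% of total
    solar radiation; ``tepsilon2_scale`` is the printed scale constant of
    the high-temperature stress bell.
    """

    epsilon_max: dict[int, float] = field(
        default_factory=lambda: {MAIZE: 1.1, RICE: 0.9}
    )
    par_fraction: float = 0.5
    tepsilon2_scale: float = 1.1841

    def __post_init__(self) -> None:
        for code, eps in self.epsilon_max.items():
            if eps <= 0:
                raise ValueError(f"epsilon_max for crop {code} must be > 0")
        if not 0 < self.par_fraction <= 1:
            raise ValueError("par_fraction must be in (0, 1]")


def optimum_temperature(
    monthly_ndvi: list[RasterGrid], monthly_t_mean: list[RasterGrid]
) -> RasterGrid:
    """Per-pixel optimum temperature: the monthly mean temperature of the
    month whose NDVI composite is highest (ties -> earliest month)."""
    if not monthly_ndvi or len(monthly_ndvi) != len(monthly_t_mean):
        raise ValueError("need equal-length, nonempty aligned month lists")
    check_compatible(*monthly_ndvi, *monthly_t_mean)
    ndvi = np.stack([g.values.astype(float) for g in monthly_ndvi])
    for g, arr in zip(monthly_ndvi, ndvi):
        arr[g.nodata_mask] = np.nan
    temps = np.stack([g.values.astype(float) for g in monthly_t_mean])

    all_nan = np.all(np.isnan(ndvi), axis=0)
    # nanargmax errors on all-NaN columns; give them a dummy then blank out
    safe = np.where(all_nan[None, :, :], -np.inf, np.where(np.isnan(ndvi), -np.inf, ndvi))
    best = np.argmax(safe, axis=0)  # first max wins the tie
    rows, cols = np.indices(best.shape)
    topt = temps[best, rows, cols]
    topt[all_nan] = np.nan

    spec = monthly_ndvi[0].spec
    if not np.isnan(spec.nodata):
        topt = np.where(np.isnan(topt), spec.nodata, topt)
    return RasterGrid(spec, topt, "Topt")


def t_stress_low(t_opt):
    """Low-temperature stress Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt², in [0, 1]."""
    t = np.asarray(t_opt, dtype=float)
    out = 0.8 + 0.02 * t - 0.0005 * t**2
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def t_stress_high(t_opt, t_mean, scale: float = 1.1841, clip: bool = True):
    """High-temperature stress Tε2: a two-logistic bell around ``Topt``.

    ``scale / [(1+exp(0.2(Topt−10−T))) (1+exp(0.3(−Topt−10+T)))]``,
    clipped to [0, 1] unless ``clip=False`` (useful for checking the
    pre-clip value at ``T = Topt``, ≈ 0.9935 with the default scale).
    """
    topt = np.asarray(t_opt, dtype=float)
    t = np.asarray(t_mean, dtype=float)
    out = (
        scale
        / (1.0 + np.exp(0.2 * (topt - 10.0 - t)))
        / (1.0 + np.exp(0.3 * (-topt - 10.0 + t)))
    )
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def w_stress(e_actual, e_potential):
    """Water stress Wε = 0.5 + 0.5·E/P, in [0.5, 1]; nonpositive P -> NaN."""
    e = np.asarray(e_actual, dtype=float)
    p = np.asarray(e_potential, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 + 0.5 * e / p
    out = np.where(p > 0, out, np.nan)
    out = np.clip(out, 0.5, 1.0)
    return out if out.ndim else float(out)


def actual_lue(
    t1: RasterGrid,
    t2: RasterGrid,
    w: RasterGrid,
    crop_map: RasterGrid,
    params: CropParams,
) -> RasterGrid:
    """Actual light-use efficiency Tε1·Tε2·Wε·εmax(crop), gC·MJ⁻¹.

    Pixels whose crop code has no εmax entry raise (a crop present in the
    map but missing a parameterization is a configuration error); code-0
    ("other") pixels are returned as nodata.
    """
    check_compatible(t1, t2, w, crop_map)
    codes = crop_map.values
    crop_valid = crop_map.valid_mask
    present = set(np.unique(codes[crop_valid]).astype(int)) - {OTHER}
    missing = present - set(params.epsilon_max)
    if missing:
        raise ValueError(f"no epsilon_max for crop code(s) {sorted(missing)}")

    eps = np.full(codes.shape, np.nan)
    for code, value in params.epsilon_max.items():
        eps[crop_valid & (codes == code)] = value

    stress = np.where(t1.valid_mask, t1.values, np.nan)
    stress = stress * np.where(t2.valid_mask, t2.values, np.nan)
    stress = stress * np.where(w.valid_mask, w.values, np.nan)
    out = stress * eps

    spec = t1.spec
    if not np.isnan(spec.nodata):
        out = np.where(np.isnan(out), spec.nodata, out)
    return RasterGrid(spec, out, "LUE")
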