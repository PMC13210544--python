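"""Vegetation indices and dual-index FPAR retrieval.

FPAR (the fraction of photosynthetically active radiation absorbed by the
canopy) is estimated twice — by linearly stretching NDVI and the simple
ratio SR = NIR/Red between per-crop, per-month extrema — and the two
estimates are averaged. NDVI-based FPAR tends to overestimate and SR-based
FPAR to underestimate under dense canopies, so the mean is more robust than
either alone. Both stretches map the observed extrema onto the fixed
constants FPARmin = 0.001 and FPARmax = 0.950.

Because the fusion stage reconstructs NDVI (not the underlying bands), SR is
recovered from NDVI through the exact algebraic identity
``SR = (1 + NDVI) / (1 − NDVI)``, capped near the NDVI→1 singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import monthly_composite
from .grids import RasterGrid, RasterSeries, check_compatible
from .stress import CROP_NAMES, OTHER

__all__ = [
    "FparConstants",
    "ExtremaTable",
    "ndvi_from_bands",
    "sr_from_bands",
    "sr_from_ndvi",
    "monthly_extrema",
    "build_extrema_table",
    "fpar_linear",
    "fpar_combined",
    "fpar_monthly",
]


@dataclass(frozen=True)
class FparConstants:
    fpar_max: float = 0.950
    fpar_min: float = 0.001
    weight_ndvi: float = 0.5
    sr_cap: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.fpar_min < self.fpar_max <= 1:
            raise ValueError("need 0 <= fpar_min < fpar_max <= 1")
        if not 0 <= self.weight_ndvi <= 1:
            raise ValueError("weight_ndvi must be in [0, 1]")


@dataclass
class ExtremaTable:
    """Per-crop, per-month NDVI and SR extrema used to scale FPAR.

    Keyed by ``(crop_code, month)``; each entry is
    ``(ndvi_min, ndvi_max, sr_min, sr_max)``.
    """

    entries: dict[tuple[int, int], tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def set(self, crop: int, month: int, ndvi_min, ndvi_max, sr_min, sr_max) -> None:
        if not (ndvi_min < ndvi_max and sr_min < sr_max):
            raise ValueError(
                f"degenerate extrema for crop {crop} month {month}: "
                f"min must be < max"
            )
        self.entries[(crop, month)] = (
            float(ndvi_min),
            float(ndvi_max),
            float(sr_min),
            float(sr_max),
        )

    def get(self, crop: int, month: int) -> tuple[float, float, float, float]:
        try:
            return self.entries[(crop, month)]
        except KeyError:
            raise KeyError(f"no extrema for crop {crop}, month {month}") from None

    def crops(self) -> list[int]:
        return sorted({c for c, _ in self.entries})

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: crop, month, index, min, max."""
        rows = []
        for (crop, month), (nmin, nmax, smin, smax) in sorted(self.entries.items()):
            name = CROP_NAMES.get(crop, str(crop))
            rows.append({"crop": name, "month": month, "index": "NDVI",
                         "min": nmin, "max": nmax})
            rows.append({"crop": name, "month": month, "index": "SR",
                         "min": smin, "max": smax})
        return pd.DataFrame(rows)


def ndvi_from_bands(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """NDVI = (NIR − Red)/(NIR + Red); zero-sum pixels become nodata."""
    check_compatible(red, nir)
    r = np.where(red.valid_mask, red.values, np.nan)
    n = np.where(nir.valid_mask, nir.values, np.nan)
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (n - r) / denom, np.nan)
    return _wrap(out, red, "NDVI")


def sr_from_bands(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """Simple ratio SR = NIR/Red; zero red becomes nodata."""
    check_compatible(red, nir)
    r = np.where(red.valid_mask, red.values, np.nan)
    n = np.where(nir.valid_mask, nir.values, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r != 0, n / r, np.nan)
    return _wrap(out, red, "SR")


def sr_from_ndvi(ndvi: RasterGrid, sr_cap: float = 30.0) -> RasterGrid:
    """SR recovered from NDVI via SR = (1+NDVI)/(1−NDVI).

    NDVI within 1e−6 of 1 hits the singularity and is capped at ``sr_cap``;
    NDVI ≤ −1 has no defined ratio and becomes nodata. The result is also
    capped at ``sr_cap`` so noise-inflated NDVI cannot blow up the SR
    stretch.
    """
    v = np.where(ndvi.valid_mask, ndvi.values, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (1.0 + v) / (1.0 - v)
    out = np.where(v >= 1.0 - 1e-6, sr_cap, out)
    out = np.where(v <= -1.0, np.nan, out)
    out = np.minimum(out, sr_cap)
    return _wrap(out, ndvi, "SR")


def _wrap(values: np.ndarray, like: RasterGrid, label: str) -> RasterGrid:
    spec = like.spec
    if not np.isnan(spec.nodata):
        values = np.where(np.isnan(values), spec.nodata, values)
    return RasterGrid(spec, values, label)


def monthly_extrema(
    index_series: RasterSeries,
    crop_map: RasterGrid,
    crop: int,
    month: int,
    percentile_trim: float = 0.0,
) -> tuple[float, float]:
    """(min, max) of the monthly maximum-value composite over one crop's
    pixels, optionally trimmed to the (p, 100−p) percentiles."""
    composite = monthly_composite(index_series, month, method="max")
    check_compatible(composite, crop_map)
    sel = crop_map.valid_mask & (crop_map.values == crop) & composite.valid_mask
    vals = composite.values[sel]
    if vals.size == 0:
        raise ValueError(f"no valid pixels for crop {crop} in month {month}")
    if percentile_trim > 0:
        lo = float(np.percentile(vals, percentile_trim))
        hi = float(np.percentile(vals, 100 - percentile_trim))
    else:
        lo, hi = float(vals.min()), float(vals.max())
    return lo, hi


def build_extrema_table(
    fused_ndvi_series: RasterSeries,
    crop_map: RasterGrid,
    months: list[int],
    crops: list[int] | None = None,
    percentile_trim: float = 0.0,
    constants: FparConstants | None = None,
) -> ExtremaTable:
    """Scene-derived scaling extrema for every (crop, month).

    SR extrema are taken from the SR transform of the same monthly NDVI
    composite (the transform is monotone, so compositing and converting
    commute).
    """
    constants = constants or FparConstants()
    if crops is None:
        crops = sorted(
            int(c)
            for c in np.unique(crop_map.values[crop_map.valid_mask])
            if int(c) != OTHER
        )
    table = ExtremaTable()
    for month in months:
        composite = monthly_composite(fused_ndvi_series, month, method="max")
        sr = sr_from_ndvi(composite, sr_cap=constants.sr_cap)
        for crop in crops:
            sel = (
                crop_map.valid_mask
                & (crop_map.values == crop)
                & composite.valid_mask
            )
            nvals = composite.values[sel]
            svals = sr.values[sel & sr.valid_mask]
            if nvals.size == 0:
                raise ValueError(f"no valid pixels for crop {crop}, month {month}")
            if percentile_trim > 0:
                p = percentile_trim
                table.set(
                    crop, month,
                    np.percentile(nvals, p), np.percentile(nvals, 100 - p),
                    np.percentile(svals, p), np.percentile(svals, 100 - p),
                )
            else:
                table.set(
                    crop, month,
                    nvals.min(), nvals.max(), svals.min(), svals.max(),
                )
    return table


def fpar_linear(x, x_min: float, x_max: float, constants: FparConstants | None = None):
    """Linear stretch of an index between its extrema onto [FPARmin, FPARmax].

    Values outside [x_min, x_max] are clipped to the endpoints (individual
    pixels can exceed monthly composite extrema after fusion).
    """
    constants = constants or FparConstants()
    if not x_max > x_min:
        raise ValueError(f"degenerate scaling range: min={x_min} max={x_max}")
    x = np.asarray(x, dtype=float)
    out = constants.fpar_min + (x - x_min) * (
        constants.fpar_max - constants.fpar_min
    ) / (x_max - x_min)
    out = np.clip(out, constants.fpar_min, constants.fpar_max)
    return out if out.ndim else float(out)


def fpar_combined(
    fpar_ndvi: RasterGrid,
    fpar_sr: RasterGrid,
    constants: FparConstants | None = None,
) -> RasterGrid:
    """Weighted mean of the two FPAR estimates (equal weights by default)."""
    constants = constants or FparConstants()
    check_compatible(fpar_ndvi, fpar_sr)
    a = np.where(fpar_ndvi.valid_mask, fpar_ndvi.values, np.nan)
    b = np.where(fpar_sr.valid_mask, fpar_sr.values, np.nan)
    w = constants.weight_ndvi
    out = w * a + (1.0 - w) * b
    out = np.clip(out, constants.fpar_min, constants.fpar_max)
    return _wrap(out, fpar_ndvi, "FPAR")


def fpar_monthly(
    fused_ndvi_series: RasterSeries,
    crop_map: RasterGrid,
    extrema: ExtremaTable,
    month: int,
    constants: FparConstants | None = None,
) -> RasterGrid:
    """Monthly FPAR map: per-crop NDVI and SR stretches of the monthly
    composite, averaged. Non-crop pixels are nodata."""
    constants = constants or FparConstants()
    composite = monthly_composite(fused_ndvi_series, month, method="max")
    check_compatible(composite, crop_map)
    sr = sr_from_ndvi(composite, sr_cap=constants.sr_cap)

    present = sorted(
        int(c)
        for c in np.unique(crop_map.values[crop_map.valid_mask])
        if int(c) != OTHER
    )
    missing = [c for c in present if (c, month) not in extrema.entries]
    if missing:
        raise KeyError(f"missing extrema for crop(s) {missing} in month {month}")

    out = np.full(composite.spec.shape, np.nan)
    for crop in present:
        nmin, nmax, smin, smax = extrema.get(crop, month)
        sel = (
            crop_map.valid_mask
            & (crop_map.values == crop)
            & composite.valid_mask
            & sr.valid_mask
        )
        fn = fpar_linear(composite.values[sel], nmin, nmax, constants)
        fs = fpar_linear(sr.values[sel], smin, smax, constants)
        out[sel] = np.clip(
            constants.weight_ndvi * fn + (1 - constants.weight_ndvi) * fs,
            constants.fpar_min,
            constants.fpar_max,
        )
    return _wrap(out, composite, f"FPAR-{month:02d}")
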