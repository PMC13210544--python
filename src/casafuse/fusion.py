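"""ESTARFM-style spatiotemporal fusion of fine and coarse NDVI.

A fine-resolution image at a target date t2 is predicted from a fine/coarse
pair at a reference date t1 plus the coarse image at t2:

    F(x0, t2) = F(x0, t1) + Σ_i W_i · V · [C(x_i, t2) − C(x_i, t1)]

where the sum runs over *similar pixels* inside a moving window — pixels
spectrally close to the center in the fine reference (|ΔNDVI| ≤ 2σ/m for a
window standard deviation σ and class count m). W_i combines spatial
distance and fine/coarse spectral agreement; V is the conversion
coefficient, the least-squares slope of fine on coarse over the similar
pixels (falling back to 1 when the regression is degenerate). When two
reference pairs bracket the target, the two single-pair predictions are
blended with per-pixel temporal weights favouring the reference whose
coarse image better matches the coarse target.

Coarse images are bilinearly resampled to the fine grid before fusion, so
all indexing happens in fine-pixel coordinates. The heavy per-pixel loop is
a numba kernel; the module-level operations mirror it step by step on plain
windows for inspection and testing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .geo_io import align_to_grid
from .grids import RasterGrid, RasterSeries, check_compatible

__all__ = [
    "FusionParams",
    "ReferencePair",
    "select_similar_pixels",
    "similar_pixel_weights",
    "conversion_coefficient",
    "predict_single_pair",
    "predict_two_pair",
    "fuse_series",
]


@dataclass(frozen=True)
class FusionParams:
    """Moving-window controls for the fusion predictor."""

    window_half_size: int = 15
    n_classes: int = 3
    min_similar: int = 5
    pair_mode: str = "double"
    regression_min_points: int = 10
    min_correlation: float = 0.3
    max_ref_gap_fraction: float = 0.5
    normalize_coarse: bool = True

    def __post_init__(self) -> None:
        if self.window_half_size < 1:
            raise ValueError("window_half_size must be >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.min_similar < 1:
            raise ValueError("min_similar must be >= 1")
        if self.pair_mode not in ("single", "double"):
            raise ValueError("pair_mode must be 'single' or 'double'")


@dataclass
class ReferencePair:
    """A clear fine image and the coarse image of the same date, both on
    the fine grid."""

    fine: RasterGrid
    coarse: RasterGrid
    date: _dt.date

    def __post_init__(self) -> None:
        check_compatible(self.fine, self.coarse)


# ---------------------------------------------------------------------------
# window-level operations (reference semantics, used directly in tests)


def select_similar_pixels(
    fine_window: np.ndarray, center: tuple[int, int], n_classes: int
) -> list[tuple[int, int]]:
    """Pixels spectrally similar to the window center.

    A pixel qualifies when |fine(p) − fine(center)| ≤ 2σ/m, with σ the
    standard deviation of the valid window pixels and m the class count.
    The center always qualifies; NaN (nodata) pixels never do.
    """
    fine_window = np.asarray(fine_window, dtype=float)
    ci, cj = center
    fc = fine_window[ci, cj]
    if np.isnan(fc):
        raise ValueError("window center is nodata")
    valid = ~np.isnan(fine_window)
    sigma = float(fine_window[valid].std())
    threshold = 2.0 * sigma / n_classes
    sel = valid & (np.abs(fine_window - fc) <= threshold)
    sel[ci, cj] = True
    return [tuple(p) for p in np.argwhere(sel)]


def similar_pixel_weights(
    similar: list[tuple[int, int]],
    center: tuple[int, int],
    fine_window: np.ndarray,
    coarse_window_t1: np.ndarray,
    window_half_size: int | None = None,
) -> np.ndarray:
    """Normalized weights W_i ∝ 1/(D_i·S_i).

    D_i = 1 + dist(p, center)/h penalizes spatial distance; S_i = 1 +
    |fine(p) − coarse(p)| penalizes fine/coarse disagreement at the
    reference date. Weights are positive and sum to 1.
    """
    if not similar:
        raise ValueError("empty similar-pixel set")
    h = window_half_size or max(fine_window.shape) // 2 or 1
    ci, cj = center
    w = np.empty(len(similar))
    for k, (i, j) in enumerate(similar):
        dist = np.hypot(i - ci, j - cj)
        d = 1.0 + dist / h
        s = 1.0 + abs(fine_window[i, j] - coarse_window_t1[i, j])
        w[k] = 1.0 / (d * s)
    return w / w.sum()


def conversion_coefficient(
    similar: list[tuple[int, int]],
    pairs: list[ReferencePair] | list[tuple[np.ndarray, np.ndarray]],
    regression_min_points: int = 10,
    min_correlation: float = 0.3,
) -> float:
    """Conversion coefficient V: slope of fine on coarse over the similar
    pixels, pooled across reference pairs.

    With two reference pairs the pooled cloud contains each similar pixel
    at both dates, so the slope captures how a unit of coarse change maps
    to fine change for this pixel class. Falls back to V = 1 when the
    regression is degenerate: too few points, coarse variance below 1e−8,
    fine/coarse correlation below ``min_correlation`` (a spatial-noise
    slope carries no conversion information), or |V| outside (0, 5].
    """
    fine_vals: list[float] = []
    coarse_vals: list[float] = []
    for pair in pairs:
        if isinstance(pair, ReferencePair):
            f_arr, c_arr = pair.fine.values, pair.coarse.values
        else:
            f_arr, c_arr = pair
        for i, j in similar:
            f, c = f_arr[i, j], c_arr[i, j]
            if not (np.isnan(f) or np.isnan(c)):
                fine_vals.append(f)
                coarse_vals.append(c)
    if len(fine_vals) < regression_min_points:
        return 1.0
    f = np.asarray(fine_vals)
    c = np.asarray(coarse_vals)
    var_c = float(c.var())
    var_f = float(f.var())
    if var_c < 1e-8:
        return 1.0
    cov = float(((c - c.mean()) * (f - f.mean())).mean())
    if var_f > 0 and abs(cov) / np.sqrt(var_c * var_f) < min_correlation:
        return 1.0
    v = cov / var_c
    if not (0.0 < abs(v) <= 5.0):
        return 1.0
    return v


# ---------------------------------------------------------------------------
# fast kernel


@njit(cache=True)
def _predict_kernel(fine1, coarse1, coarse2, fine_b, coarse_b, has_b,
                    need, h, n_classes, min_similar, reg_min,
                    min_corr):  # pragma: no cover - numba
    nr, nc = fine1.shape
    out = np.full((nr, nc), np.nan)
    max_pix = (2 * h + 1) * (2 * h + 1)
    rows = np.empty(max_pix, np.int64)
    cols = np.empty(max_pix, np.int64)
    for i in range(nr):
        for j in range(nc):
            if not need[i, j]:
                continue
            fc = fine1[i, j]
            if np.isnan(fc):
                continue
            r0 = i - h if i - h > 0 else 0
            r1 = i + h + 1 if i + h + 1 < nr else nr
            c0 = j - h if j - h > 0 else 0
            c1 = j + h + 1 if j + h + 1 < nc else nc

            # std of valid fine pixels in the window
            s = 0.0
            s2 = 0.0
            cnt = 0
            for r in range(r0, r1):
                for c in range(c0, c1):
                    v = fine1[r, c]
                    if not np.isnan(v):
                        s += v
                        s2 += v * v
                        cnt += 1
            mean = s / cnt
            var = s2 / cnt - mean * mean
            sigma = np.sqrt(var) if var > 0.0 else 0.0
            threshold = 2.0 * sigma / n_classes

            # similar pixels with valid fine and coarse values
            n_sim = 0
            for r in range(r0, r1):
                for c in range(c0, c1):
                    v = fine1[r, c]
                    if np.isnan(v) or np.isnan(coarse1[r, c]) or np.isnan(coarse2[r, c]):
                        continue
                    if abs(v - fc) <= threshold or (r == i and c == j):
                        rows[n_sim] = r
                        cols[n_sim] = c
                        n_sim += 1

            if n_sim < min_similar:
                # too heterogeneous a neighbourhood: fall back to the
                # center pixel's own coarse change
                if not (np.isnan(coarse1[i, j]) or np.isnan(coarse2[i, j])):
                    pred = fc + (coarse2[i, j] - coarse1[i, j])
                else:
                    pred = fc
                out[i, j] = min(1.0, max(-1.0, pred))
                continue

            # conversion coefficient: slope of fine on coarse over the
            # similar pixels, pooled across the available reference pairs
            sf = 0.0
            sc = 0.0
            n_reg = 0
            for k in range(n_sim):
                sf += fine1[rows[k], cols[k]]
                sc += coarse1[rows[k], cols[k]]
                n_reg += 1
                if has_b:
                    fb = fine_b[rows[k], cols[k]]
                    cb = coarse_b[rows[k], cols[k]]
                    if not (np.isnan(fb) or np.isnan(cb)):
                        sf += fb
                        sc += cb
                        n_reg += 1
            mf = sf / n_reg
            mc = sc / n_reg
            s_cc = 0.0
            s_ff = 0.0
            s_cf = 0.0
            for k in range(n_sim):
                dc = coarse1[rows[k], cols[k]] - mc
                df = fine1[rows[k], cols[k]] - mf
                s_cc += dc * dc
                s_ff += df * df
                s_cf += dc * df
                if has_b:
                    fb = fine_b[rows[k], cols[k]]
                    cb = coarse_b[rows[k], cols[k]]
                    if not (np.isnan(fb) or np.isnan(cb)):
                        dc = cb - mc
                        df = fb - mf
                        s_cc += dc * dc
                        s_ff += df * df
                        s_cf += dc * df
            v_coef = 1.0
            if n_reg >= reg_min and s_cc / n_reg >= 1e-8:
                ok = True
                if s_ff > 0.0:
                    corr = abs(s_cf) / np.sqrt(s_cc * s_ff)
                    if corr < min_corr:
                        ok = False
                if ok:
                    slope = s_cf / s_cc
                    if 0.0 < abs(slope) <= 5.0:
                        v_coef = slope

            # weights and the weighted coarse change
            wsum = 0.0
            acc = 0.0
            for k in range(n_sim):
                r = rows[k]
                c = cols[k]
                dist = np.sqrt(float((r - i) * (r - i) + (c - j) * (c - j)))
                d = 1.0 + dist / h
                sdiff = 1.0 + abs(fine1[r, c] - coarse1[r, c])
                w = 1.0 / (d * sdiff)
                wsum += w
                acc += w * (coarse2[r, c] - coarse1[r, c])
            pred = fc + v_coef * acc / wsum
            out[i, j] = min(1.0, max(-1.0, pred))
    return out


def _nanvals(grid: RasterGrid) -> np.ndarray:
    out = grid.values.astype(float, copy=True)
    out[grid.nodata_mask] = np.nan
    return out


def predict_single_pair(
    pair: ReferencePair,
    coarse_t2: RasterGrid,
    params: FusionParams | None = None,
    need: np.ndarray | None = None,
    aux_pair: ReferencePair | None = None,
) -> RasterGrid:
    """Predict the fine image at the coarse target date from one reference
    pair. Output is clipped to [−1, 1]; pixels nodata in the fine
    reference stay nodata. ``need`` restricts prediction to a pixel mask.

    ``aux_pair`` optionally contributes a second reference date to the
    conversion-coefficient regression (similar-pixel selection and the
    weighted sum still use ``pair`` alone); :func:`predict_two_pair` uses
    this so V captures the temporal fine/coarse relation.
    """
    params = params or FusionParams()
    check_compatible(pair.fine, pair.coarse, coarse_t2)
    fine1 = _nanvals(pair.fine)
    coarse1 = _nanvals(pair.coarse)
    coarse2 = _nanvals(coarse_t2)
    if aux_pair is not None:
        check_compatible(aux_pair.fine, aux_pair.coarse, coarse_t2)
        fine_b = _nanvals(aux_pair.fine)
        coarse_b = _nanvals(aux_pair.coarse)
        has_b = True
    else:
        fine_b = np.empty((0, 0))
        coarse_b = np.empty((0, 0))
        has_b = False
    if need is None:
        need = np.ones(fine1.shape, dtype=bool)
    out = _predict_kernel(
        fine1,
        coarse1,
        coarse2,
        fine_b,
        coarse_b,
        has_b,
        need,
        params.window_half_size,
        float(params.n_classes),
        params.min_similar,
        params.regression_min_points,
        params.min_correlation,
    )
    return _wrap(out, coarse_t2, coarse_t2.label or "predicted")


def _window_mean(values: np.ndarray, h: int) -> np.ndarray:
    """Nodata-aware mean over the (2h+1)² truncated moving window."""
    size = 2 * h + 1
    filled = np.where(np.isnan(values), 0.0, values)
    valid = (~np.isnan(values)).astype(float)
    num = ndimage.uniform_filter(filled, size=size, mode="constant")
    den = ndimage.uniform_filter(valid, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def predict_two_pair(
    pair1: ReferencePair,
    pair2: ReferencePair,
    coarse_t2: RasterGrid,
    params: FusionParams | None = None,
    need: np.ndarray | None = None,
) -> RasterGrid:
    """Blend predictions from two reference pairs with temporal weights.

    Per pixel, each pair's weight is inversely proportional to the mean
    absolute coarse change between its reference date and the target over
    the moving window; when both changes are below 1e−8 the weights are
    equal. A pixel predicted by only one pair takes that prediction.
    """
    params = params or FusionParams()
    p1 = predict_single_pair(pair1, coarse_t2, params, need, aux_pair=pair2).values
    p2 = predict_single_pair(pair2, coarse_t2, params, need, aux_pair=pair1).values

    h = params.window_half_size
    c2 = _nanvals(coarse_t2)
    d1 = np.abs(_window_mean(_nanvals(pair1.coarse), h) - _window_mean(c2, h))
    d2 = np.abs(_window_mean(_nanvals(pair2.coarse), h) - _window_mean(c2, h))
    tiny = 1e-8
    both_tiny = (d1 < tiny) & (d2 < tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv1 = 1.0 / np.maximum(d1, tiny)
        inv2 = 1.0 / np.maximum(d2, tiny)
    w1 = np.where(both_tiny, 0.5, inv1 / (inv1 + inv2))
    w2 = 1.0 - w1

    out = w1 * p1 + w2 * p2
    only1 = np.isnan(p2) & ~np.isnan(p1)
    only2 = np.isnan(p1) & ~np.isnan(p2)
    out[only1] = p1[only1]
    out[only2] = p2[only2]
    out = np.clip(out, -1.0, 1.0)
    return _wrap(out, coarse_t2, coarse_t2.label or "predicted")


def _gap_fraction(grid: RasterGrid) -> float:
    return float(grid.nodata_mask.mean())


def fuse_series(
    fine_series: RasterSeries,
    coarse_series: RasterSeries,
    params: FusionParams | None = None,
) -> tuple[RasterSeries, pd.DataFrame]:
    """Fill cloud gaps in a fine NDVI series from the coarse series.

    For each date with gaps, the nearest sufficiently clear fine dates
    (gap fraction ≤ ``params.max_ref_gap_fraction``) serve as references —
    a bracketing pair when available (two-pair prediction, if
    ``params.pair_mode`` allows), otherwise the nearest one (ties go to
    the earlier date). Clear pixels are kept verbatim; pixels that no
    reference can predict (nodata in every usable reference) fall back to
    the bilinearly resampled coarse value, so the output series is
    gap-free. Returns the fused series and a per-date report
    (date, mode, n_filled, fraction_filled).
    """
    params = params or FusionParams()
    if len(fine_series) == 0:
        raise ValueError("empty fine series")

    # bring every coarse image onto the fine grid (bilinear)
    fine_spec = fine_series.spec
    coarse_on_fine: dict[_dt.date, RasterGrid] = {}
    for date, grid in coarse_series:
        if grid.spec.compatible_with(fine_spec):
            coarse_on_fine[date] = grid
        else:
            coarse_on_fine[date] = align_to_grid(grid, fine_spec, "bilinear")
    missing = [d for d in fine_series.dates if d not in coarse_on_fine]
    if missing:
        raise ValueError(f"no coarse image for date(s) {missing}")

    if params.normalize_coarse:
        # relative radiometric normalization, offset only: remove the mean
        # fine/coarse difference per date. A gain term would absorb the
        # fine→coarse variance attenuation, which is the conversion
        # coefficient's job, so only the additive bias is corrected.
        for date, fine in fine_series:
            cg = coarse_on_fine[date]
            both = fine.valid_mask & cg.valid_mask
            if both.sum() < 100:
                continue
            offset = float(fine.values[both].mean() - cg.values[both].mean())
            vals = np.where(cg.valid_mask, cg.values + offset, np.nan)
            coarse_on_fine[date] = _wrap(vals, cg, cg.label)

    clear_dates = [
        d
        for d, g in fine_series
        if _gap_fraction(g) <= params.max_ref_gap_fraction
    ]
    if not clear_dates:
        raise ValueError(
            "no reference date with gap fraction <= "
            f"{params.max_ref_gap_fraction}"
        )

    fused_grids: list[RasterGrid] = []
    rows = []
    for date, fine in fine_series:
        gaps = fine.nodata_mask
        n_gaps = int(gaps.sum())
        if n_gaps == 0:
            fused_grids.append(fine.copy())
            rows.append({"date": date, "mode": "clear", "n_filled": 0,
                         "fraction_filled": 0.0})
            continue

        refs = [d for d in clear_dates if d != date]
        if not refs:
            raise ValueError(f"no clear reference date available for {date}")
        before = [d for d in refs if d < date]
        after = [d for d in refs if d > date]

        def _make_pair(ref_date: _dt.date) -> ReferencePair:
            return ReferencePair(
                fine=fine_series.grid_for(ref_date),
                coarse=coarse_on_fine[ref_date],
                date=ref_date,
            )

        coarse_t2 = coarse_on_fine[date]
        ranked = sorted(
            refs, key=lambda d: (abs((d - date).days), d.toordinal())
        )
        if before and after and params.pair_mode == "double":
            mode = "two-pair"
            pred = predict_two_pair(
                _make_pair(before[-1]), _make_pair(after[0]),
                coarse_t2, params, need=gaps,
            )
        else:
            # nearest reference; equidistant -> earlier. The clear date
            # farthest from it, when available, joins the
            # conversion-coefficient regression only (a wide seasonal arc
            # conditions the fine-on-coarse slope; prediction still uses
            # the nearest pair alone).
            mode = "single-pair"
            primary = ranked[0]
            others = [d for d in ranked if d != primary]
            aux = None
            if others:
                far = max(others, key=lambda d: abs((d - primary).days))
                aux = _make_pair(far)
            pred = predict_single_pair(
                _make_pair(primary), coarse_t2, params, need=gaps,
                aux_pair=aux,
            )

        out = fine.values.astype(float, copy=True)
        out[gaps] = np.nan
        pv = pred.values.astype(float, copy=True)
        pv[pred.nodata_mask] = np.nan
        fill = gaps & ~np.isnan(pv)
        out[fill] = pv[fill]
        # pixels clouded in the reference(s) too fall back to the
        # (normalized, smoothed) coarse observation at the target date —
        # a direct measurement, which beats extrapolating from a distant
        # reference
        rest = gaps & np.isnan(out)
        if rest.any():
            cv = coarse_t2.values.astype(float, copy=True)
            cv[coarse_t2.nodata_mask] = np.nan
            out[rest] = np.clip(cv[rest], -1.0, 1.0)

        fused_grids.append(_wrap(out, fine, fine.label))
        rows.append({
            "date": date,
            "mode": mode,
            "n_filled": n_gaps,
            "fraction_filled": n_gaps / gaps.size,
        })

    report = pd.DataFrame(rows)
    return RasterSeries(list(fine_series.dates), fused_grids), report


def _wrap(values: np.ndarray, like: RasterGrid, label: str) -> RasterGrid:
    spec = like.spec
    if not np.isnan(spec.nodata):
        values = np.where(np.isnan(values), spec.nodata, values)
    return RasterGrid(spec, values, label)
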