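"""Fully synthetic, ground-truthed scenes for exercising the pipeline.

The generator emulates a single-cropping maize/rice landscape of
rectangular fields observed by a fine (10 m, 16-day) and a coarse (250 m
class) NDVI sensor:

* a rectangular-field landscape with requested crop area fractions;
* per-crop double-logistic NDVI phenology (maize greening rapidly in July,
  collapsing after September; rice sustaining high NDVI July–September and
  senescing late; "other" flat and low);
* per-field variability — planting-date offsets with small early/late
  minorities and a vigor multiplier with a "poor/newly planted" minority —
  which is what gives monthly NDVI distributions the skew that real
  agricultural scenes show (most fields low with a few advanced ones in
  June; most at peak with a few laggards in August);
* the coarse sensor as block-mean of the fine image plus additive bias and
  noise;
* cloud gaps as circular blobs, concentrated in July–August;
* smooth seasonal meteorology (temperature sinusoid peaking in July,
  radiation and evapotranspiration following suit).

Everything is bit-reproducible under a fixed seed. ``forward_truth_npp``
runs the CASA chain on the *uncorrupted* fine series, giving the ground
truth that parameter-recovery tests compare the cloud-degraded + fused
pipeline against.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fpar import FparConstants
from .geo_io import aggregate_to_coarse
from .grids import GridSpec, RasterGrid, RasterSeries
from .npp import NppMonthly, casa_npp
from .stress import MAIZE, OTHER, RICE, CropParams, MeteoMonthly

__all__ = [
    "SceneSpec",
    "CropPhenology",
    "default_phenology",
    "CloudSpec",
    "MeteoSpec",
    "FieldSet",
    "make_landscape",
    "make_fields",
    "phenology_ndvi",
    "render_fine_series",
    "degrade_to_coarse",
    "apply_cloud_mask",
    "make_meteo",
    "forward_truth_npp",
]


def default_season(year: int = 2025) -> list[_dt.date]:
    """16-day composite start dates covering June–October (MOD13Q1-like
    day-of-year schedule)."""
    doys = [161, 177, 193, 209, 225, 241, 257, 273, 289]
    base = _dt.date(year, 1, 1)
    return [base + _dt.timedelta(days=d - 1) for d in doys]


def _default_grid() -> GridSpec:
    return GridSpec(
        n_rows=200,
        n_cols=200,
        origin_x=500000.0,
        origin_y=4540000.0,
        pixel_size_x=10.0,
        pixel_size_y=-10.0,
        crs_id="EPSG:32651",
    )


@dataclass
class SceneSpec:
    """Scene geometry, crop mix and observation calendar."""

    grid: GridSpec = field(default_factory=_default_grid)
    scale_factor: int = 10
    n_fields: int = 80
    crop_fractions: tuple[float, float, float] = (0.40, 0.35, 0.25)  # maize, rice, other
    season: list[_dt.date] = field(default_factory=default_season)
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.crop_fractions) - 1.0) > 1e-9:
            raise ValueError("crop_fractions must sum to 1")
        if self.scale_factor < 2:
            raise ValueError("scale_factor must be >= 2")
        if len(self.season) < 6:
            raise ValueError("season needs at least 6 dates")


@dataclass(frozen=True)
class CropPhenology:
    """Double-logistic NDVI curve parameters for one crop."""

    base_ndvi: float
    peak_ndvi: float
    green_up_day: float
    senescence_day: float
    green_up_rate: float
    senescence_rate: float

    def __post_init__(self) -> None:
        if not 0 <= self.base_ndvi < self.peak_ndvi < 1:
            raise ValueError("need 0 <= base_ndvi < peak_ndvi < 1")
        if not self.green_up_day < self.senescence_day:
            raise ValueError("green_up_day must precede senescence_day")


def default_phenology() -> dict[int, CropPhenology]:
    """Season curves: maize greens through July, peaks July–August and
    collapses by October; rice starts dark (flooded paddies), ramps
    steeply from late July, holds a plateau into September and senesces
    late; "other" (grass, trees, field margins) is already green in June
    and stays moderate all season. The between-class June contrast is
    what real scenes show and what the fusion stage relies on."""
    return {
        MAIZE: CropPhenology(0.15, 0.90, 185.0, 260.0, 0.10, 0.12),
        RICE: CropPhenology(0.10, 0.85, 204.0, 292.0, 0.12, 0.07),
        OTHER: CropPhenology(0.15, 0.45, 130.0, 305.0, 0.06, 0.05),
    }


@dataclass
class CloudSpec:
    """Blob-shaped cloud gaps, heavier in July–August."""

    jul_aug_gap: float = 0.30
    other_gap: float = 0.10
    blob_radius: int = 12
    seed: int = 0
    per_date: dict[_dt.date, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.jul_aug_gap, self.other_gap, *self.per_date.values()):
            if not 0 <= p <= 1:
                raise ValueError("gap probabilities must be in [0, 1]")

    def gap_probability(self, date: _dt.date) -> float:
        if date in self.per_date:
            return self.per_date[date]
        return self.jul_aug_gap if date.month in (7, 8) else self.other_gap


@dataclass
class MeteoSpec:
    """Seasonal meteorology: sinusoids in month peaking in July, plus a
    gentle spatial gradient and smooth spatial noise."""

    t_mean_annual: float = 9.3     # °C
    t_amplitude: float = 15.0      # °C, July peak
    sol_base: float = 350.0        # MJ·m⁻²·month⁻¹
    sol_amplitude: float = 280.0
    ep_base: float = 80.0          # potential ET, mm·month⁻¹
    ep_amplitude: float = 50.0
    et_ratio_base: float = 0.55    # E/P seasonal midpoint
    et_ratio_amplitude: float = 0.25
    t_gradient: float = 1.5        # °C across the scene
    rel_gradient: float = 0.05     # relative gradient for SOL and ET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sol_base - self.sol_amplitude < 0:
            raise ValueError("solar radiation must stay nonnegative")
        lo = self.et_ratio_base - self.et_ratio_amplitude
        hi = self.et_ratio_base + self.et_ratio_amplitude
        if not (0 < lo and hi <= 1):
            raise ValueError("E/P ratio must stay within (0, 1]")


@dataclass
class FieldSet:
    """Field geometry plus per-field phenological character."""

    field_ids: np.ndarray          # int field index per pixel
    rects: list[tuple[int, int, int, int]]   # (r0, r1, c0, c1) half-open
    planting_offset: np.ndarray    # days, per field (+ = later planting)
    vigor: np.ndarray              # multiplier on (peak − base), per field


# ---------------------------------------------------------------------------
# landscape


def _partition(spec: SceneSpec) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Binary-space partition of the grid into n_fields rectangles."""
    nr, nc = spec.grid.shape
    min_side = 4
    if spec.n_fields > (nr // min_side) * (nc // min_side):
        raise ValueError("n_fields exceeds grid capacity")
    rng = np.random.default_rng(spec.seed)
    rects = [(0, nr, 0, nc)]
    while len(rects) < spec.n_fields:
        # split the largest rectangle that can still be split
        order = sorted(
            range(len(rects)),
            key=lambda k: (rects[k][1] - rects[k][0]) * (rects[k][3] - rects[k][2]),
            reverse=True,
        )
        for k in order:
            r0, r1, c0, c1 = rects[k]
            height, width = r1 - r0, c1 - c0
            if max(height, width) < 2 * min_side:
                continue
            if height >= width:
                cut = r0 + int(rng.integers(min_side, height - min_side + 1))
                new = [(r0, cut, c0, c1), (cut, r1, c0, c1)]
            else:
                cut = c0 + int(rng.integers(min_side, width - min_side + 1))
                new = [(r0, r1, c0, cut), (r0, r1, cut, c1)]
            rects.pop(k)
            rects.extend(new)
            break
        else:  # nothing splittable
            break
    ids = np.empty((nr, nc), dtype=np.int64)
    for k, (r0, r1, c0, c1) in enumerate(rects):
        ids[r0:r1, c0:c1] = k
    return ids, rects


def _assign_crops(spec: SceneSpec, rects) -> np.ndarray:
    """Per-field crop codes tracking the requested area fractions."""
    rng = np.random.default_rng(spec.seed + 1)
    total = spec.grid.n_rows * spec.grid.n_cols
    targets = {
        MAIZE: spec.crop_fractions[0] * total,
        RICE: spec.crop_fractions[1] * total,
        OTHER: spec.crop_fractions[2] * total,
    }
    assigned = {MAIZE: 0.0, RICE: 0.0, OTHER: 0.0}
    codes = np.empty(len(rects), dtype=np.int64)
    order = rng.permutation(len(rects))
    for k in order:
        r0, r1, c0, c1 = rects[k]
        area = (r1 - r0) * (c1 - c0)
        # assign to the crop with the largest remaining area deficit
        code = max(targets, key=lambda c: targets[c] - assigned[c])
        codes[k] = code
        assigned[code] += area
    return codes


def make_landscape(spec: SceneSpec) -> RasterGrid:
    """Categorical crop map (1=maize, 2=rice, 0=other) of rectangular
    fields whose realized crop fractions track the requested ones."""
    ids, rects = _partition(spec)
    codes = _assign_crops(spec, rects)
    return RasterGrid(spec.grid, codes[ids].astype(float), "crop_map")


def make_fields(spec: SceneSpec) -> FieldSet:
    """Field ids plus per-field planting offsets and vigor.

    Within each crop, 10% of fields plant early (−25 d), 10% late
    (+25 d) and the rest on schedule (±4 d jitter); 12% have poor vigor
    (newly planted or struggling stands, amplitude ≈ 0.65 of normal).
    The minority counts are stratified per crop (rounded shares, not coin
    flips) so every scene actually contains its early, late and poor
    fields — the contrast real field mosaics show in every month.
    """
    ids, rects = _partition(spec)
    codes = _assign_crops(spec, rects)
    rng = np.random.default_rng(spec.seed + 2)
    n = len(rects)
    offset = rng.normal(0.0, 4.0, size=n)
    vigor = np.clip(rng.normal(1.0, 0.04, size=n), 0.4, 1.06)
    for crop_code in (MAIZE, RICE, OTHER):
        members = np.flatnonzero(codes == crop_code)
        if members.size == 0:
            continue
        members = rng.permutation(members)
        n_early = int(round(0.10 * members.size))
        n_late = int(round(0.10 * members.size))
        early = members[:n_early]
        late = members[n_early : n_early + n_late]
        offset[early] = rng.normal(-25.0, 4.0, size=early.size)
        offset[late] = rng.normal(25.0, 4.0, size=late.size)
        n_poor = int(round(0.12 * members.size))
        poor = rng.permutation(members)[:n_poor]
        vigor[poor] = np.clip(rng.normal(0.65, 0.08, size=poor.size), 0.4, 1.06)
    return FieldSet(field_ids=ids, rects=rects, planting_offset=offset, vigor=vigor)


# ---------------------------------------------------------------------------
# NDVI series


def phenology_ndvi(
    crop: int, doy, params: Mapping[int, CropPhenology]
):
    """Double-logistic seasonal NDVI:
    base + (peak − base)·[logistic(green-up) − logistic(senescence)],
    clipped to [−1, 1]."""
    if crop not in params:
        raise ValueError(f"unknown crop code {crop}")
    p = params[crop]
    d = np.asarray(doy, dtype=float)
    up = 1.0 / (1.0 + np.exp(-p.green_up_rate * (d - p.green_up_day)))
    down = 1.0 / (1.0 + np.exp(-p.senescence_rate * (d - p.senescence_day)))
    out = p.base_ndvi + (p.peak_ndvi - p.base_ndvi) * (up - down)
    out = np.clip(out, -1.0, 1.0)
    return out if out.ndim else float(out)


def render_fine_series(
    landscape: RasterGrid,
    params: Mapping[int, CropPhenology],
    spec: SceneSpec,
    noise_sd: float = 0.02,
    fields: FieldSet | None = None,
) -> RasterSeries:
    """Fine NDVI series from phenology + Gaussian noise.

    Without ``fields`` every pixel of a crop follows the crop curve
    exactly (plus noise). With a :class:`FieldSet` the curve is shifted by
    the field's planting offset and its amplitude scaled by the field's
    vigor, producing realistic between-field spread.
    """
    codes = landscape.values.astype(np.int64)
    present = np.unique(codes)
    for code in present:
        if int(code) not in params:
            raise ValueError(f"crop code {int(code)} has no phenology parameters")
    rng = np.random.default_rng(spec.seed + 3)
    grids = []
    for date in spec.season:
        doy = date.timetuple().tm_yday
        ndvi = np.empty(landscape.spec.shape, dtype=float)
        for code in present:
            sel = codes == code
            p = params[int(code)]
            if fields is None:
                ndvi[sel] = phenology_ndvi(int(code), doy, params)
            else:
                off = fields.planting_offset[fields.field_ids[sel]]
                vig = fields.vigor[fields.field_ids[sel]]
                d = doy - off
                up = 1.0 / (1.0 + np.exp(-p.green_up_rate * (d - p.green_up_day)))
                down = 1.0 / (
                    1.0 + np.exp(-p.senescence_rate * (d - p.senescence_day))
                )
                ndvi[sel] = p.base_ndvi + vig * (p.peak_ndvi - p.base_ndvi) * (
                    up - down
                )
        if noise_sd > 0:
            ndvi = ndvi + rng.normal(0.0, noise_sd, size=ndvi.shape)
        ndvi = np.clip(ndvi, -1.0, 1.0)
        grids.append(RasterGrid(landscape.spec, ndvi, date.isoformat()))
    return RasterSeries(list(spec.season), grids)


def degrade_to_coarse(
    fine_series: RasterSeries,
    scale_factor: int,
    bias: float = 0.02,
    noise_sd: float = 0.02,
    seed: int = 0,
    gain: float = 1.0,
) -> RasterSeries:
    """Coarse-sensor series: block mean of the fine image, then an
    affine radiometric perturbation (gain 1 by default) plus noise."""
    rng = np.random.default_rng(seed)
    grids = []
    for date, grid in fine_series:
        coarse = aggregate_to_coarse(grid, scale_factor)
        vals = coarse.values * gain + bias
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        vals = np.clip(vals, -1.0, 1.0)
        grids.append(RasterGrid(coarse.spec, vals, grid.label))
    return RasterSeries(list(fine_series.dates), grids)


def apply_cloud_mask(
    series: RasterSeries, cloud: CloudSpec
) -> tuple[RasterSeries, RasterSeries]:
    """Mask circular cloud blobs into the series.

    Blobs of the configured radius are dropped at random centers until the
    date's target gap fraction is reached, so realized fractions slightly
    overshoot the target (by at most about one blob). Returns the gapped
    series and a 0/1 mask series (1 = masked).
    """
    nr, nc = series.spec.shape
    rows, cols = np.indices((nr, nc))
    gapped, masks = [], []
    for date, grid in series:
        p = cloud.gap_probability(date)
        rng = np.random.default_rng(
            np.random.SeedSequence([cloud.seed, date.toordinal()])
        )
        mask = np.zeros((nr, nc), dtype=bool)
        if p >= 1.0:
            mask[:] = True
        elif p > 0:
            # cap iterations defensively; each blob adds ~πr² pixels
            for _ in range(100000):
                if mask.mean() >= p:
                    break
                ci = rng.integers(0, nr)
                cj = rng.integers(0, nc)
                blob = (rows - ci) ** 2 + (cols - cj) ** 2 <= cloud.blob_radius**2
                mask |= blob
        vals = grid.values.astype(float, copy=True)
        vals[mask] = np.nan
        spec = grid.spec
        if not np.isnan(spec.nodata):
            vals = np.where(np.isnan(vals), spec.nodata, vals)
        gapped.append(RasterGrid(spec, vals, grid.label))
        masks.append(RasterGrid(spec, mask.astype(float), f"mask-{grid.label}"))
    return (
        RasterSeries(list(series.dates), gapped),
        RasterSeries(list(series.dates), masks),
    )


# ---------------------------------------------------------------------------
# meteorology


def _seasonal(month: int, base: float, amplitude: float, peak_month: float = 7.0):
    return base + amplitude * np.cos(2.0 * np.pi * (month - peak_month) / 12.0)


def make_meteo(
    spec: MeteoSpec,
    months: Sequence[int],
    grid: GridSpec,
) -> list[MeteoMonthly]:
    """Monthly meteorology fields on ``grid``.

    Temperature follows a sinusoid peaking in July around the annual mean;
    radiation and potential ET follow the same phase; actual ET is a
    seasonal fraction of potential ET, so E ≤ P everywhere. Spatial
    structure is a linear north–south gradient plus smooth random
    undulation scaled by the gradient magnitudes.
    """
    nr, nc = grid.shape
    rng = np.random.default_rng(spec.seed)
    # one smooth unit-amplitude surface shared by all variables
    ramp = np.linspace(-0.5, 0.5, nr)[:, None] * np.ones((1, nc))
    wobble = rng.standard_normal((max(nr // 20, 2), max(nc // 20, 2)))
    zoom = (nr / wobble.shape[0], nc / wobble.shape[1])
    from scipy import ndimage as _ndi

    smooth = _ndi.zoom(wobble, zoom, order=3)[:nr, :nc]
    if smooth.std() > 0:
        smooth = smooth / (2 * smooth.std())
    surface = ramp + 0.3 * smooth  # roughly unit peak-to-peak

    out = []
    for month in months:
        t0 = _seasonal(month, spec.t_mean_annual, spec.t_amplitude)
        sol0 = _seasonal(month, spec.sol_base, spec.sol_amplitude)
        ep0 = _seasonal(month, spec.ep_base, spec.ep_amplitude)
        ratio0 = _seasonal(month, spec.et_ratio_base, spec.et_ratio_amplitude)

        t = t0 + spec.t_gradient * surface
        sol = np.maximum(sol0 * (1.0 + spec.rel_gradient * surface), 0.0)
        ep = np.maximum(ep0 * (1.0 + spec.rel_gradient * surface), 1e-6)
        ratio = np.clip(ratio0 + 0.5 * spec.rel_gradient * surface, 0.0, 1.0)
        ea = ep * ratio

        out.append(
            MeteoMonthly(
                month=month,
                t_mean=RasterGrid(grid, t, f"t_mean-{month:02d}"),
                sol=RasterGrid(grid, sol, f"sol-{month:02d}"),
                e_actual=RasterGrid(grid, ea, f"e_actual-{month:02d}"),
                e_potential=RasterGrid(grid, ep, f"e_potential-{month:02d}"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# forward truth


def forward_truth_npp(
    clean_fine_series: RasterSeries,
    crop_map: RasterGrid,
    meteo: list[MeteoMonthly],
    crop_params: CropParams | None = None,
    fpar_constants: FparConstants | None = None,
    months: Sequence[int] | None = None,
) -> tuple[list[NppMonthly], RasterGrid]:
    """Ground-truth NPP: the CASA chain run on the uncorrupted fine series.

    Identical to running the pipeline with no clouds and perfect fusion,
    which is exactly what parameter-recovery tests need.
    """
    monthly, seasonal, _ = casa_npp(
        clean_fine_series,
        crop_map,
        meteo,
        crop_params=crop_params,
        fpar_constants=fpar_constants,
        months=list(months) if months is not None else None,
    )
    return monthly, seasonal
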