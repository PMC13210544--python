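# Methods

This note describes the models implemented in `casafuse`, the defaults
they ship with, what the synthetic scenes do and do not emulate, and the
numerical choices a user should know about.

## The productivity model

NPP is estimated with the light-use-efficiency (CASA-family) formulation,
per pixel x and month t:

```
NPP(x,t)  = APAR(x,t) · LUE(x,t)          [gC·m⁻²·month⁻¹]
APAR(x,t) = PAR(x,t) · FPAR(x,t)          [MJ·m⁻²·month⁻¹]
PAR(x,t)  = 0.5 · SOL(x,t)
LUE(x,t)  = Tε1(x) · Tε2(x,t) · Wε(x,t) · εmax(crop)
```

with total solar radiation SOL in MJ·m⁻²·month⁻¹ (a converter divides raw
J·m⁻² archives by 10⁶). The growing-season total (reported per annum under
single cropping) is the per-pixel sum over June–October; months where a
pixel is nodata are skipped by default (`strict=True` invalidates instead).

**εmax** is crop-specific: maize 1.1, rice 0.9 gC·MJ⁻¹ — literature
parameterizations for the two crops, exposed in `CropParams` for local
calibration.

**Stress scalars.** `Topt(x)` is the monthly mean temperature of the month
whose NDVI composite peaks at x (ties → earliest month). Then

```
Tε1 = 0.8 + 0.02·Topt − 0.0005·Topt²                          clipped to [0,1]
Tε2 = 1.1841 / [(1+exp(0.2(Topt−10−T))) (1+exp(0.3(−Topt−10+T)))]  clipped to [0,1]
Wε  = 0.5 + 0.5·E/P                                           clipped to [0.5,1]
```

Tε1 attains its maximum, exactly 1, at Topt = 20 °C. Tε2 at T = Topt is
≈ 0.9935 before clipping; the scale constant 1.1841 is configurable
(`tepsilon2_scale`; the CASA literature also uses 1.1814, a < 0.3%
difference). E and P are actual and potential evapotranspiration in mm;
clipping is the standard guard for temperatures outside the quadratic's
physical range. No cold-month cutoff is applied — out of scope for a
June–October season, and noted for future extension.

## FPAR from NDVI and SR

Per crop and month, the minimum and maximum of the monthly maximum-value
NDVI composite over that crop's pixels define a linear stretch onto
[FPARmin, FPARmax] = [0.001, 0.950]; the same is done for the simple ratio
SR, and FPAR is the equally weighted mean of the two stretches. Extrema
are taken over the monthly *composite* (not the individual 16-day scenes)
and are absolute min/max by default (`percentile_trim` is available but
defaults to 0). Values outside the stretch range are clipped rather than
rejected: individual pixels can exceed composite extrema after fusion.
A degenerate stretch (min = max) is an error — it indicates a broken
scene or mask, not a condition to silently absorb.

Because the fusion stage reconstructs NDVI and not the underlying bands,
SR is recovered through the exact identity SR = (1+NDVI)/(1−NDVI), capped
at `sr_cap` = 30 to guard the singularity as NDVI → 1 (noise-inflated
NDVI would otherwise dominate the SR stretch).

## Fusion

`predict_single_pair` evaluates, inside a truncated moving window of
half-size 15 (31×31 pixels):

* **Similar pixels:** valid pixels with |fine(p) − fine(center)| ≤ 2σ/m,
  σ the window standard deviation, m = `n_classes` (default 3); the center
  always qualifies; pixels nodata in the fine reference or either coarse
  image never do. Fewer than `min_similar` (default 5) similar pixels
  triggers a center-only fallback (the pixel's own coarse change).
* **Weights:** Wᵢ ∝ 1/(Dᵢ·Sᵢ) with Dᵢ = 1 + dist/h and
  Sᵢ = 1 + |fine(p) − coarse(p)|, normalized to sum to 1.
* **Conversion coefficient:** the least-squares slope of fine on coarse
  over the similar pixels, pooled across the available reference pairs.
  The regression is declared degenerate — and V falls back to 1 — when it
  has fewer than `regression_min_points` (10) points, the coarse variance
  is below 1e−8, |V| lies outside (0, 5], or the fine/coarse correlation
  is below `min_correlation` (0.3). The correlation guard matters: with a
  single reference date the regression is purely spatial, and over
  same-class similar pixels the fine values are essentially constant, so
  the slope is a noise artifact. With two reference dates pooled, the
  between-date variation dominates and the slope measures how a unit of
  coarse change maps to fine change for that pixel class — which is the
  quantity V exists to capture.

`predict_two_pair` blends the two single-pair predictions with per-pixel
temporal weights ∝ 1/|window-mean coarse change| (equal when both changes
are below 1e−8); a pixel only one pair can predict takes that prediction.

`fuse_series` resamples the coarse series to the fine grid (bilinear),
normalizes each coarse image to the fine series by a per-date **offset**
(a fitted gain would absorb the fine→coarse variance attenuation, which
is V's job), then fills each gapped date: bracketing clear references →
two-pair; otherwise the nearest reference (ties → earlier), single-pair,
with the clear date farthest from the primary reference joining the V
regression only (a wide seasonal arc conditions the slope). Dates with a
gap fraction ≤ `max_ref_gap_fraction` (0.5) may serve as references —
their clear pixels are perfectly usable. Clear pixels of the target date
are kept verbatim; pixels clouded in every usable reference fall back to
the normalized bilinear coarse observation at the target date, which
measured better than extrapolating from a distant reference. Output is
clipped to [−1, 1] and gap-free within the scene footprint.

## The synthetic scenes

The generator emulates a north-Chinese single-cropping maize/rice plain
at 10 m with a 250 m-class coarse companion:

* **Landscape:** a binary-space partition into 80 axis-aligned rectangular
  fields (~2.2 ha each on the default 2×2 km scene), crops assigned so
  realized area fractions track the requested (0.40 maize, 0.35 rice,
  0.25 other).
* **Phenology:** double-logistic NDVI per crop. Defaults: maize base 0.15,
  peak 0.90, green-up day 185 (rate 0.10 d⁻¹), senescence day 260 (rate
  0.12 d⁻¹); rice base 0.10 (flooded paddies are dark in June), peak 0.85,
  green-up 204 (0.12 d⁻¹), senescence 292 (0.07 d⁻¹); "other" a gentle
  grass/tree curve (0.15→0.45) already green in June. These defaults were
  set so the monthly FPAR trajectories show the published seasonal shape
  (maize peaking July–August and bare by October; rice ramping later,
  peaking in September and senescing late); the rice green-up is later
  than a real Liaoning paddy's, a deliberate trade favouring the seasonal
  FPAR pattern over mid-July NDVI levels.
* **Between-field spread:** per crop, 10% of fields plant ~25 d early,
  10% ~25 d late (others jitter ±4 d), and 12% have poor vigor (amplitude
  ×0.65 — newly planted or struggling stands). Counts are stratified per
  crop rather than drawn independently, so every scene contains its
  minorities. This spread is what gives monthly NDVI distributions the
  skew real scenes show; without it the per-month extrema stretch would
  pin every month's mean FPAR near the middle of its range.
* **Coarse sensor:** block mean (factor 10) + additive bias 0.02 + noise
  0.02 (a multiplicative gain is available but off by default).
* **Cloud:** circular blobs (radius 12 px) dropped until the date's target
  gap fraction is reached — 0.30 on July–August dates, 0.10 otherwise.
  Blobs, not i.i.d. pixels, because contiguous gaps are what the fusion's
  similar-pixel search actually has to survive.
* **Meteorology:** sinusoids peaking in July (temperature around a 9.3 °C
  annual mean with 15 °C amplitude; radiation 350 ± 280 MJ·m⁻²·month⁻¹;
  potential ET 80 ± 50 mm with E/P 0.55 ± 0.25), plus a gentle
  north–south gradient and smooth random undulation. E ≤ P everywhere by
  construction.

Everything is bit-reproducible given a seed; the pipeline derives each
stage's seed by hashing the stage name against one global seed.

**What the scenes do not emulate:** radiative-transfer effects, topography,
mixed pixels within a field, irregular field shapes, multi-year dynamics,
co-registration error between the two sensors, and real cloud morphology.
Passing the recovery tests therefore shows the chain is implemented
coherently and survives the stated degradation — not that it reproduces
any particular real-world accuracy level.

## Evaluation

R² (against the observed mean), MAE, MAPE (×100, in percent; pairs with
observed value 0 are excluded with a logged count) and RMSE, plus a
random-point validation sampler (uniform, without replacement, over
jointly valid pixels). The pipeline reports fusion accuracy per date over
exactly the pixels that were cloud-filled, and seasonal-NPP recovery per
crop against the forward-model truth (the CASA chain run on the
uncorrupted series — identical to a run with no clouds and perfect
fusion).

## Known limitations

* Single-pair prediction at the series endpoints is temporal
  extrapolation; its accuracy is visibly below the bracketed dates and,
  on unlucky cloud/field draws, a date at the series edge can fall short
  of the quality the interior dates reach.
* The conversion coefficient is one value per window; true mixed-pixel
  unmixing (per-class V from endmember fractions) is out of scope.
* εmax is fixed per crop for the whole season; real light-use efficiency
  varies within the season and with management.
* The water scalar uses the actual/potential evapotranspiration ratio as
  defined; precipitation-based alternatives are not implemented.
* Problem sizes in the test suite (200×200 default scene, 9 dates) were
  chosen as the smallest scenes that exercise every mechanism with stable
  statistics.
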