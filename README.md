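# casafuse

Crop net primary productivity (NPP) mapping from fused fine/coarse NDVI
time series with an improved CASA light-use-efficiency model.

## The problem

Optical satellite time series over intensively cropped regions lose their
most important scenes to summer cloud: the July–August peak of canopy
development is exactly when fine-resolution imagery is least available.
Light-use-efficiency models such as CASA need a continuous vegetation-index
series to retrieve the fraction of absorbed photosynthetically active
radiation (FPAR), so cloud gaps propagate directly into the carbon
estimates.

`casafuse` addresses this for a maize/rice single-cropping landscape with
three ingredients:

1. **Spatiotemporal fusion (ESTARFM-style).** A fine image at a gapped
   date t₂ is reconstructed from a clear fine/coarse reference pair at t₁
   and the coarse image at t₂:

   F(x₀,t₂) = F(x₀,t₁) + Σᵢ Wᵢ·Vᵢ·[C(xᵢ,t₂) − C(xᵢ,t₁)]

   where the sum runs over spectrally *similar pixels* in a moving window
   (|ΔNDVI| ≤ 2σ/m), Wᵢ combines spatial distance and fine/coarse
   agreement, and Vᵢ is a conversion coefficient from a fine-on-coarse
   regression with a V=1 fallback when the regression is degenerate.

2. **Dual-index FPAR.** Per crop and month, NDVI and the simple ratio
   SR = (1+NDVI)/(1−NDVI) are each stretched linearly between their
   monthly extrema onto [FPARmin, FPARmax] = [0.001, 0.950], and the two
   estimates are averaged — NDVI-based FPAR saturates high, SR-based FPAR
   runs low, and the mean is more robust than either.

3. **Crop-specific light-use efficiency.** NPP(x,t) = APAR(x,t)·LUE(x,t)
   with APAR = 0.5·SOL·FPAR and
   LUE = Tε1(Topt) · Tε2(Topt,T) · Wε(E/P) · εmax(crop),
   εmax 1.1 gC·MJ⁻¹ for maize and 0.9 gC·MJ⁻¹ for rice; Tε1 is a
   quadratic in the optimum temperature (the monthly mean temperature of
   the peak-NDVI month), Tε2 a two-logistic bell around it, and
   Wε = 0.5 + 0.5·E/P the evapotranspiration-ratio water scalar.

Because no public scene ships with the package, a first-class synthetic
generator produces ground-truthed inputs — rectangular field mosaics,
double-logistic phenology with realistic between-field spread, a coarse
sensor (block mean + bias + noise), blob-shaped summer cloud gaps and
seasonal meteorology — so every stage is testable end to end against a
forward-model truth.

## Worked example

```bash
python examples/evaluate_recovery.py
```

runs the whole chain on the default 200×200 scene (10 m pixels, coarse
factor 10, 16-day season June–October, 30% July–August cloud) and prints,
among others:

```
seasonal NPP recovery vs forward truth, per crop:
 crop    r2    mae  mape_percent   rmse     n
maize 0.903 19.633         5.266 29.198 15781
 rice 0.971  9.119         3.068 15.297 14308

modelled seasonal NPP by crop (gC m-2 a-1):
 crop   min   max  mean     n
maize 142.2 722.0 411.2 15781
 rice  85.9 574.7 319.5 14308
```

Reading this: after degrading the scene with cloud and reconstructing it
by fusion, the recovered growing-season NPP still explains 90–97% of the
per-pixel variance of the truth, with mean absolute percentage errors of
3–5%. The zonal table is the modelled analogue of a per-crop field-survey
summary. The other scripts in `examples/` demonstrate each capability in
isolation (scene simulation, fusion, FPAR retrieval, NPP estimation).

A thin CLI wraps the same stages for shell use:

```bash
casafuse simulate --out-dir scene/
casafuse fuse --fine-dir scene/fine --coarse-dir scene/coarse --out-dir fused/
casafuse run-all --out-dir run/
```

## Layout

```
src/casafuse/
  grids.py       raster containers (GridSpec, RasterGrid, RasterSeries)
  geo_io.py      GeoTIFF I/O, alignment, aggregation, monthly composites
  synthetic.py   ground-truthed scene generator
  fusion.py      ESTARFM-style gap filling
  fpar.py        vegetation indices and dual-index FPAR
  stress.py      temperature/water stress scalars and LUE
  npp.py         APAR, monthly/seasonal NPP, zonal summaries
  metrics.py     R², MAE, MAPE, RMSE, random-point validation
  pipeline.py    one-config orchestration with per-stage seeds
  cli.py         casafuse simulate|fuse|fpar|npp|evaluate|run-all
```

See `docs/methods.md` for the model description, parameter defaults and
known limitations.
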