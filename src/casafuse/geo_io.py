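"""Raster I/O and grid manipulation.

GeoTIFF reading/writing is built on :mod:`tifffile`, storing the standard
GeoTIFF tags directly (ModelPixelScale, ModelTiepoint, GeoKeyDirectory and
the GDAL nodata tag). Files are single-band float32, which every mainstream
GIS reads. Reprojection between different coordinate systems is deliberately
refused: grids must be aligned explicitly via :func:`align_to_grid`, and only
within one CRS.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
import os
import warnings

import numpy as np
import tifffile
from scipy import ndimage

from .grids import GridSpec, RasterGrid, RasterSeries

__all__ = [
    "read_raster",
    "write_raster",
    "align_to_grid",
    "aggregate_to_coarse",
    "monthly_composite",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

_KEY_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


def _epsg_code(crs_id: str) -> int:
    try:
        authority, code = crs_id.split(":")
    except ValueError:
        raise ValueError(f"crs_id must look like 'EPSG:32651', got {crs_id!r}")
    if authority.upper() != "EPSG":
        raise ValueError(f"only EPSG CRS identifiers are supported, got {crs_id!r}")
    return int(code)


def write_raster(grid: RasterGrid, path: str | os.PathLike) -> None:
    """Write a single-band float32 GeoTIFF with nodata and georeferencing tags."""
    spec = grid.spec
    code = _epsg_code(spec.crs_id)
    # geographic CRSs (lat/lon) use key 2048, projected ones 3072
    if 4000 <= code < 5000:
        geo_keys = (1, 1, 0, 2, _KEY_MODEL_TYPE, 0, 1, 2, _KEY_GEOGRAPHIC_CS, 0, 1, code)
    else:
        geo_keys = (1, 1, 0, 2, _KEY_MODEL_TYPE, 0, 1, 1, _KEY_PROJECTED_CS, 0, 1, code)
    nodata_str = "nan" if np.isnan(spec.nodata) else repr(float(spec.nodata))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(spec.pixel_size_x), abs(spec.pixel_size_y), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geo_keys), geo_keys),
        (_TAG_GDAL_NODATA, "s", len(nodata_str) + 1, nodata_str),
    ]
    data = grid.values.astype(np.float32)
    tifffile.imwrite(path, data, extratags=extratags, description=grid.label or None)


def read_raster(path: str | os.PathLike, band: int | None = None) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale + tiepoint tags).

    Parameters
    ----------
    band:
        Page index for multi-page files. Required when the file holds more
        than one band.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        tif = tifffile.TiffFile(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path}: not a readable TIFF raster: {exc}") from exc
    with tif:
        n_bands = len(tif.pages)
        page = tif.pages[0]
        if page.samplesperpixel > 1:
            raise ValueError(f"{path}: multi-sample rasters are not supported")
        if n_bands > 1:
            if band is None:
                raise ValueError(
                    f"{path}: file has {n_bands} bands; pass band= to select one"
                )
            page = tif.pages[band]
        elif band not in (None, 0):
            raise ValueError(f"{path}: band {band} requested from single-band file")

        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing (GeoTIFF tags)")
        sx, sy, _ = tags[_TAG_PIXEL_SCALE].value[:3]
        tie = tags[_TAG_TIEPOINT].value
        origin_x, origin_y = float(tie[3]), float(tie[4])

        crs_id = "EPSG:32651"
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for i in range(4, len(keys), 4):
                key_id, _, _, value = keys[i : i + 4]
                if key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
                    crs_id = f"EPSG:{value}"

        nodata = float("nan")
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            if isinstance(raw, bytes):
                raw = raw.decode("ascii", "ignore")
            raw = raw.strip().strip("\x00")
            nodata = float(raw) if raw else float("nan")

        values = page.asarray().astype(np.float64)
        label = ""
        if page.description:
            label = str(page.description)

    spec = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        origin_x=origin_x,
        origin_y=origin_y,
        pixel_size_x=float(sx),
        pixel_size_y=-float(sy),
        crs_id=crs_id,
        nodata=nodata,
    )
    return RasterGrid(spec, values, label)


def _nan_values(grid: RasterGrid) -> np.ndarray:
    """Grid values with nodata replaced by NaN."""
    out = grid.values.astype(np.float64, copy=True)
    out[grid.nodata_mask] = np.nan
    return out


def _finish(values: np.ndarray, spec: GridSpec, label: str) -> RasterGrid:
    """Convert NaN cells back to the spec's sentinel and wrap."""
    if not np.isnan(spec.nodata):
        values = np.where(np.isnan(values), spec.nodata, values)
    return RasterGrid(spec, values, label)


def align_to_grid(
    src: RasterGrid, target: GridSpec, method: str = "nearest"
) -> RasterGrid:
    """Resample ``src`` onto ``target``.

    ``method`` is one of ``nearest``, ``mean`` (block average of source cells
    whose centers fall inside each target cell — for downsampling) or
    ``bilinear``. Cells outside source coverage become nodata. Differing CRSs
    raise: reprojection must be done explicitly upstream.
    """
    if src.spec.crs_id != target.crs_id:
        raise ValueError(
            f"CRS mismatch ({src.spec.crs_id} vs {target.crs_id}): "
            "reprojection is not supported; align inputs explicitly"
        )
    if src.spec.compatible_with(target):
        return RasterGrid(target, src.values.copy(), src.label)

    vals = _nan_values(src)
    rows_t, cols_t = np.meshgrid(
        np.arange(target.n_rows), np.arange(target.n_cols), indexing="ij"
    )
    # target cell centers in map coordinates
    x = target.origin_x + (cols_t + 0.5) * target.pixel_size_x
    y = target.origin_y + (rows_t + 0.5) * target.pixel_size_y
    # fractional source indices of those centers
    col_f = (x - src.spec.origin_x) / src.spec.pixel_size_x - 0.5
    row_f = (y - src.spec.origin_y) / src.spec.pixel_size_y - 0.5

    if method == "nearest":
        r = np.rint(row_f).astype(np.int64)
        c = np.rint(col_f).astype(np.int64)
        inside = (r >= 0) & (r < src.spec.n_rows) & (c >= 0) & (c < src.spec.n_cols)
        out = np.full(target.shape, np.nan)
        out[inside] = vals[r[inside], c[inside]]
    elif method == "bilinear":
        # clamp at edges so the half-pixel rim inside the source extent
        # still interpolates; anything outside the extent becomes nodata
        out = ndimage.map_coordinates(
            vals, [row_f, col_f], order=1, mode="nearest"
        )
        inside = (
            (row_f > -0.5)
            & (row_f < src.spec.n_rows - 0.5)
            & (col_f > -0.5)
            & (col_f < src.spec.n_cols - 0.5)
        )
        out[~inside] = np.nan
    elif method == "mean":
        # scatter each source cell center into the target cell containing it
        rows_s, cols_s = np.meshgrid(
            np.arange(src.spec.n_rows), np.arange(src.spec.n_cols), indexing="ij"
        )
        xs = src.spec.origin_x + (cols_s + 0.5) * src.spec.pixel_size_x
        ys = src.spec.origin_y + (rows_s + 0.5) * src.spec.pixel_size_y
        ct = np.floor((xs - target.origin_x) / target.pixel_size_x).astype(np.int64)
        rt = np.floor((ys - target.origin_y) / target.pixel_size_y).astype(np.int64)
        ok = (
            (rt >= 0)
            & (rt < target.n_rows)
            & (ct >= 0)
            & (ct < target.n_cols)
            & ~np.isnan(vals)
        )
        acc = np.zeros(target.shape)
        cnt = np.zeros(target.shape)
        np.add.at(acc, (rt[ok], ct[ok]), vals[ok])
        np.add.at(cnt, (rt[ok], ct[ok]), 1.0)
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    else:
        raise ValueError(f"unknown resampling method {method!r}")

    return _finish(out, target, src.label)


def aggregate_to_coarse(fine: RasterGrid, factor: int) -> RasterGrid:
    """Block-mean aggregation by an integer ``factor``, ignoring nodata.

    Trailing partial blocks are averaged over the cells available, so fine
    dimensions need not divide evenly. A block that is entirely nodata
    stays nodata.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return fine.copy()

    vals = _nan_values(fine)
    nr, nc = vals.shape
    out_r = math.ceil(nr / factor)
    out_c = math.ceil(nc / factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = vals
    blocks = padded.reshape(out_r, factor, out_c, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(blocks, axis=(1, 3))

    spec = GridSpec(
        n_rows=out_r,
        n_cols=out_c,
        origin_x=fine.spec.origin_x,
        origin_y=fine.spec.origin_y,
        pixel_size_x=fine.spec.pixel_size_x * factor,
        pixel_size_y=fine.spec.pixel_size_y * factor,
        crs_id=fine.spec.crs_id,
        nodata=fine.spec.nodata,
    )
    return _finish(out, spec, fine.label)


def monthly_composite(
    series: RasterSeries, month: int, method: str = "max"
) -> RasterGrid:
    """Per-pixel composite over all series dates falling in ``month``.

    ``max`` is the maximum-value composite conventionally used for
    vegetation indices (suppresses residual cloud-depressed values);
    ``mean`` suits meteorological fields. Pixels nodata on every date in
    the month stay nodata.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    dates = series.dates_in_month(month)
    if not dates:
        raise ValueError(f"no dates in month {month} ({calendar.month_abbr[month]})")
    stack = np.stack([_nan_values(series.grid_for(d)) for d in dates])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if method == "max":
            out = np.nanmax(stack, axis=0)
        elif method == "mean":
            out = np.nanmean(stack, axis=0)
        else:
            raise ValueError(f"unknown composite method {method!r}")
    label = f"{calendar.month_abbr[month]}-{method}"
    return _finish(out, series.spec, label)
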