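"""Core raster containers: a georeferenced 2-D grid and a date-indexed stack.

Every stage of the pipeline passes these two containers around. Conventions
are fixed once here: coordinates are 0-based (row, col), extents are
half-open, rasters are north-up (negative y pixel size), and invalid cells
carry a nodata sentinel (NaN by default) that all pipeline math skips.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["GridSpec", "RasterGrid", "RasterSeries"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, origin, pixel size, CRS and nodata.

    ``origin_x``/``origin_y`` are the map coordinates of the outer corner of
    the top-left pixel. ``pixel_size_y`` is negative for north-up rasters.
    Two specs are *compatible* when everything except ``nodata`` matches.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size_x: float = 1.0
    pixel_size_y: float = -1.0
    crs_id: str = "EPSG:32651"
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size_x == 0 or self.pixel_size_y == 0:
            raise ValueError("pixel sizes must be nonzero")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def compatible_with(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.pixel_size_x, other.pixel_size_x)
            and np.isclose(self.pixel_size_y, other.pixel_size_y)
            and self.crs_id == other.crs_id
        )

    def cell_center(self, row: float, col: float) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col)."""
        x = self.origin_x + (col + 0.5) * self.pixel_size_x
        y = self.origin_y + (row + 0.5) * self.pixel_size_y
        return x, y

    def with_nodata(self, nodata: float) -> "GridSpec":
        return replace(self, nodata=nodata)


def _is_nodata(values: np.ndarray, sentinel: float) -> np.ndarray:
    if np.isnan(sentinel):
        return np.isnan(values)
    # NaN cells are always treated as invalid, whatever the sentinel
    return np.isnan(values) | (values == sentinel)


@dataclass
class RasterGrid:
    """A single-band georeferenced field: values + :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )

    @classmethod
    def full(cls, spec: GridSpec, fill: float = 0.0, label: str = "") -> "RasterGrid":
        return cls(spec, np.full(spec.shape, fill, dtype=np.float64), label)

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of invalid cells."""
        return _is_nodata(self.values, self.spec.nodata)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.nodata_mask)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "RasterGrid":
        return RasterGrid(self.spec, values, self.label if label is None else label)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.spec, self.values.copy(), self.label)

    def count_nodata(self) -> int:
        return int(self.nodata_mask.sum())


def check_compatible(*grids: RasterGrid) -> None:
    """Raise ``ValueError`` unless all grids share a compatible GridSpec."""
    first = grids[0].spec
    for g in grids[1:]:
        if not first.compatible_with(g.spec):
            raise ValueError(
                f"incompatible grids: {first} vs {g.spec}"
            )


@dataclass
class RasterSeries:
    """A date-indexed stack of :class:`RasterGrid` on one common grid."""

    dates: list[_dt.date] = field(default_factory=list)
    grids: list[RasterGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.grids):
            raise ValueError("dates and grids must have equal length")
        for a, b in zip(self.dates, self.dates[1:]):
            if not a < b:
                raise ValueError("dates must be strictly increasing")
        if self.grids:
            check_compatible(*self.grids)

    def __len__(self) -> int:
        return len(self.dates)

    def __iter__(self) -> Iterator[tuple[_dt.date, RasterGrid]]:
        return iter(zip(self.dates, self.grids))

    @property
    def spec(self) -> GridSpec:
        if not self.grids:
            raise ValueError("empty series has no spec")
        return self.grids[0].spec

    def grid_for(self, date: _dt.date) -> RasterGrid:
        try:
            return self.grids[self.dates.index(date)]
        except ValueError:
            raise KeyError(f"no grid for date {date}") from None

    def dates_in_month(self, month: int) -> list[_dt.date]:
        return [d for d in self.dates if d.month == month]

    def subset(self, dates: Sequence[_dt.date]) -> "RasterSeries":
        wanted = set(dates)
        pairs = [(d, g) for d, g in self if d in wanted]
        return RasterSeries([d for d, _ in pairs], [g for _, g in pairs])

    def map(self, fn) -> "RasterSeries":
        """Apply ``fn(grid) -> RasterGrid`` to every date."""
        return RasterSeries(list(self.dates), [fn(g) for g in self.grids])
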