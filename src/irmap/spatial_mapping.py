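"""Raster pipeline: per-pixel R0 maps, risk classes, CI layers, validation.

Rasters are small georeferenced 2-D fields in geographic coordinates
(WGS84 by default), read and written as ESRI ASCII grids — a plain-text
format with a six-line header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by rows of values, northernmost row
first.  In memory, nodata cells are NaN; the sentinel only appears in
files.

The mapping pipeline evaluates the climate-driven R0 independently at
every pixel of co-registered temperature (degC) and rainfall (mm/month)
grids, classifies pixels into low/moderate/high risk, aggregates the 12
monthly maps into an annual mean, and derives 95% confidence-interval
layers ``mean +/- 1.96 * sd`` across months.  Observed resistance points
are validated by overlay: the fraction of confirmed-resistant points
whose containing pixel carries the target risk class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_response import ClimateSample, LifeHistoryParameters
from .model_core import ModelParameters
from .reproduction_number import (
    MODERATE_HIGH,
    MODERATE_LOW,
    RiskClass,
    r0_climate,
)

__all__ = [
    "RasterGrid",
    "CIRasterPair",
    "ResistancePoint",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_points_csv",
    "write_points_csv",
    "r0_map",
    "classify_map",
    "annual_aggregate",
    "ci_rasters",
    "OverlayResult",
    "overlay_accuracy",
]

DEFAULT_NODATA = -9999.0

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass(frozen=True)
class RasterGrid:
    """A georeferenced 2-D field.

    ``values[0, :]`` is the NORTHERNMOST row (ESRI ASCII convention);
    nodata cells are NaN.  ``origin`` is the (x, y) of the lower-left
    corner in degrees, ``cellsize`` the square cell edge in degrees.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cellsize: float
    nodata: float = DEFAULT_NODATA
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"values must be a non-empty 2-D array, got shape {v.shape}")
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be > 0, got {self.cellsize!r}")
        finite = v[np.isfinite(v)]
        if finite.size and np.any(finite == self.nodata):
            raise ValueError(
                f"nodata sentinel {self.nodata!r} collides with a data value; "
                "in-memory nodata must be NaN"
            )

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """Same georeferencing, new cell values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if off-grid.

        Cells are half-open ``[x, x+cellsize) x [y, y+cellsize)``: points
        exactly on the top or right grid boundary fall off-grid.
        """
        col = math.floor((lon - self.origin[0]) / self.cellsize)
        row_s = math.floor((lat - self.origin[1]) / self.cellsize)  # from south
        if not (0 <= col < self.ncols and 0 <= row_s < self.nrows):
            return None
        return (self.nrows - 1 - row_s, col)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin[0] + (col + 0.5) * self.cellsize
        lat = self.origin[1] + (self.nrows - 1 - row + 0.5) * self.cellsize
        return (lon, lat)


def _check_aligned(grids: list[RasterGrid]) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.values.shape != ref.values.shape:
            raise ValueError(
                f"grid shape mismatch: {g.values.shape} vs {ref.values.shape}"
            )
        if not np.allclose(g.origin, ref.origin):
            raise ValueError(f"grid origin mismatch: {g.origin} vs {ref.origin}")
        if not math.isclose(g.cellsize, ref.cellsize):
            raise ValueError(
                f"grid cellsize mismatch: {g.cellsize} vs {ref.cellsize}"
            )


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and len(header) < 6:
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS[:5] if k not in header]
    if missing:
        raise ValueError(f"malformed ESRI ASCII header in {path}: missing {missing}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"data block shape {values.shape} does not match header "
            f"({nrows}, {ncols}) in {path}"
        )
    values[values == nodata] = np.nan
    return RasterGrid(
        values=values,
        origin=(header["xllcorner"], header["yllcorner"]),
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid; NaN cells become the NODATA sentinel."""
    path = Path(path)
    out = grid.values.copy()
    out[~np.isfinite(out)] = grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


@dataclass(frozen=True)
class ResistancePoint:
    """A georeferenced insecticide-resistance bioassay record."""

    lon: float
    lat: float
    year: int
    status: str  # "resistant" | "susceptible"

    def __post_init__(self) -> None:
        if not -180 <= self.lon <= 180:
            raise ValueError(f"lon out of range: {self.lon!r}")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"lat out of range: {self.lat!r}")
        if self.status not in ("resistant", "susceptible"):
            raise ValueError(f"status must be resistant|susceptible, got {self.status!r}")


def read_points_csv(path) -> list[ResistancePoint]:
    """Read resistance points from CSV columns lon, lat, year, status."""
    df = pd.read_csv(path)
    required = {"lon", "lat", "year", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"points CSV missing columns: {sorted(missing)}")
    return [
        ResistancePoint(float(r.lon), float(r.lat), int(r.year), str(r.status))
        for r in df.itertuples()
    ]


def write_points_csv(points: list[ResistancePoint], path) -> None:
    pd.DataFrame(
        [(p.lon, p.lat, p.year, p.status) for p in points],
        columns=["lon", "lat", "year", "status"],
    ).to_csv(path, index=False)


def r0_map(
    temp: RasterGrid,
    rain: RasterGrid,
    params: ModelParameters,
    lh: LifeHistoryParameters,
) -> RasterGrid:
    """Per-pixel climate-driven R0; nodata where either input is nodata
    or the temperature makes the mortality rate undefined."""
    _check_aligned([temp, rain])
    out = np.full(temp.values.shape, np.nan)
    mask = temp.valid_mask & rain.valid_mask
    for row, col in zip(*np.nonzero(mask)):
        sample = ClimateSample(T=temp.values[row, col], rain=rain.values[row, col])
        out[row, col] = r0_climate(sample, params, lh).value
    return temp.with_values(out)


def classify_map(r0map: RasterGrid) -> RasterGrid:
    """Class-code raster: 1=low (<1), 2=moderate ([1, 1.1]), 3=high (>1.1)."""
    v = r0map.values
    out = np.full(v.shape, np.nan)
    valid = np.isfinite(v)
    out[valid & (v < MODERATE_LOW)] = RiskClass.LOW
    out[valid & (v >= MODERATE_LOW) & (v <= MODERATE_HIGH)] = RiskClass.MODERATE
    out[valid & (v > MODERATE_HIGH)] = RiskClass.HIGH
    return r0map.with_values(out)


def annual_aggregate(monthly: list[RasterGrid], method: str = "mean") -> RasterGrid:
    """Pixel-wise aggregate of 12 monthly maps over the valid months.

    A pixel is nodata only if all 12 months are nodata there.
    """
    if len(monthly) != 12:
        raise ValueError(f"expected 12 monthly grids, got {len(monthly)}")
    if method not in ("mean", "median"):
        raise ValueError(f"method must be mean|median, got {method!r}")
    _check_aligned(monthly)
    stack = np.stack([g.values for g in monthly])
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(stack, axis=0) if method == "mean" else np.nanmedian(stack, axis=0)
    return monthly[0].with_values(agg)


@dataclass(frozen=True)
class CIRasterPair:
    """95% confidence-interval layers across the 12 monthly maps."""

    lower: RasterGrid
    upper: RasterGrid
    mean: RasterGrid
    sd: RasterGrid


def ci_rasters(monthly: list[RasterGrid], z: float = 1.96) -> CIRasterPair:
    """Per-pixel mean, sample SD (n-1 divisor) and mean +/- z*SD layers.

    A pixel needs at least two valid months for a defined SD; otherwise
    all four layers are nodata there.
    """
    if len(monthly) != 12:
        raise ValueError(f"expected 12 monthly grids, got {len(monthly)}")
    _check_aligned(monthly)
    stack = np.stack([g.values for g in monthly])
    n_valid = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    too_few = n_valid < 2
    mean = np.where(too_few, np.nan, mean)
    sd = np.where(too_few, np.nan, sd)
    ref = monthly[0]
    return CIRasterPair(
        lower=ref.with_values(mean - z * sd),
        upper=ref.with_values(mean + z * sd),
        mean=ref.with_values(mean),
        sd=ref.with_values(sd),
    )


@dataclass(frozen=True)
class OverlayResult:
    """Point-overlay validation statistics."""

    fraction: float  # scored points whose pixel has the target class
    counts: dict[int, int]  # class code -> number of scored points
    n_scored: int
    n_dropped: int  # off-grid, nodata-pixel or non-resistant points


def overlay_accuracy(
    points: list[ResistancePoint],
    classmap: RasterGrid,
    target_class: int | RiskClass = RiskClass.HIGH,
) -> OverlayResult:
    """Fraction of confirmed-resistant points falling in the target class.

    Only ``status == "resistant"`` points are scored; points off-grid or
    on nodata pixels are dropped.  Raises if no point can be scored.
    """
    target = int(target_class)
    counts: dict[int, int] = {}
    n_scored = 0
    n_dropped = 0
    for p in points:
        if p.status != "resistant":
            n_dropped += 1
            continue
        idx = classmap.cell_index(p.lon, p.lat)
        if idx is None or not np.isfinite(classmap.values[idx]):
            n_dropped += 1
            continue
        code = int(classmap.values[idx])
        counts[code] = counts.get(code, 0) + 1
        n_scored += 1
    if n_scored == 0:
        raise ValueError(
            "no scorable points: all are off-grid, on nodata pixels, or "
            "not confirmed-resistant"
        )
    return OverlayResult(
        fraction=counts.get(target, 0) / n_scored,
        counts=counts,
        n_scored=n_scored,
        n_dropped=n_dropped,
    )
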