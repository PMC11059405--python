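"""Synthetic climate rasters and resistance points for end-to-end testing.

The generator emulates the statistical structure the mapping pipeline
assumes — co-registered monthly temperature and rainfall grids with a
latitudinal gradient and a seasonal cycle, plus a point set whose
placement relative to the risk classes is known by construction — so
every pipeline stage can be exercised without external downloads.  It
does not emulate real African climatology or the geography of observed
resistance.

Defaults give an Africa-like extent at toy resolution: a 40 x 40 grid of
0.5 degree cells with lower-left corner (-20, -35).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial_mapping import RasterGrid, ResistancePoint
from .reproduction_number import RiskClass

__all__ = ["SyntheticClimateSpec", "make_climate", "make_points"]


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic monthly climate generator.

    Temperature (degC) is a mean plus a latitudinal gradient (cooler
    away from the central latitude), a sinusoidal seasonal cycle and
    truncated Gaussian noise, clipped to [0, 45].  Rainfall (mm/month)
    is a seasonal bump peaking at ``rain_peak`` in the month
    ``wet_season_center`` at the central latitude, tapering with
    latitude, plus noise, floored at 0.
    """

    rows: int = 40
    cols: int = 40
    months: int = 12
    cellsize: float = 0.5
    origin: tuple[float, float] = (-20.0, -35.0)
    T_mean: float = 25.0
    T_amplitude: float = 4.0
    T_lat_gradient: float = 0.15  # degC cooling per degree of latitude off-center
    rain_peak: float = 25.0  # mm at the wettest pixel-month
    rain_lat_taper: float = 0.5  # fractional reduction at the latitudinal edges
    wet_season_center: int = 7  # 0-based month index of peak rainfall
    noise_sd_T: float = 0.5
    noise_sd_rain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.months != 12:
            raise ValueError("generator produces calendar years; months must be 12")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1 x 1")
        if self.rain_peak < 0:
            raise ValueError("rain_peak must be >= 0")
        if not 0 <= self.wet_season_center < 12:
            raise ValueError("wet_season_center must be a month index in [0, 12)")


def make_climate(spec: SyntheticClimateSpec) -> tuple[list[RasterGrid], list[RasterGrid]]:
    """Generate 12 temperature and 12 rainfall grids, deterministic under seed.

    With zero noise, the wettest pixel-month (central latitude, month
    ``wet_season_center``) receives exactly ``rain_peak`` mm.
    """
    rng = np.random.default_rng(spec.seed)
    lats = spec.origin[1] + (np.arange(spec.rows - 1, -1, -1) + 0.5) * spec.cellsize
    lat_c = spec.origin[1] + spec.rows * spec.cellsize / 2.0
    off = np.abs(lats - lat_c)
    # normalize so the row nearest the central latitude gets factor 1
    # (exactly rain_peak at the wet-season center) even on even-row grids
    span = off.max() - off.min()
    off_frac = (off - off.min()) / span if span > 0 else np.zeros_like(off)

    t_base = spec.T_mean - spec.T_lat_gradient * off  # (rows,)
    rain_base = spec.rain_peak * (1.0 - spec.rain_lat_taper * off_frac)

    temp_maps, rain_maps = [], []
    shape = (spec.rows, spec.cols)
    for m in range(12):
        seasonal_T = spec.T_amplitude * np.sin(2.0 * np.pi * m / 12.0)
        # cos^2 bump: 1 at the wet-season center, 0 half a year away
        seasonal_rain = np.cos(np.pi * (m - spec.wet_season_center) / 12.0) ** 2
        temp = (
            t_base[:, None]
            + seasonal_T
            + rng.normal(0.0, spec.noise_sd_T, shape) * (spec.noise_sd_T > 0)
        )
        rain = (
            rain_base[:, None] * seasonal_rain
            + rng.normal(0.0, spec.noise_sd_rain, shape) * (spec.noise_sd_rain > 0)
        )
        temp_maps.append(
            RasterGrid(
                values=np.clip(temp, 0.0, 45.0),
                origin=spec.origin,
                cellsize=spec.cellsize,
            )
        )
        rain_maps.append(
            RasterGrid(
                values=np.clip(rain, 0.0, None),
                origin=spec.origin,
                cellsize=spec.cellsize,
            )
        )
    return temp_maps, rain_maps


def make_points(
    classmap: RasterGrid, n: int, frac_high: float, seed: int, year: int = 2019
) -> list[ResistancePoint]:
    """Place resistant validation points with known class membership.

    ``round(n * frac_high)`` points are placed uniformly inside randomly
    chosen high-class pixels; the remainder uniformly inside pixels
    drawn from all valid (non-nodata) pixels.  Deterministic under seed.
    """
    if n <= 0:
        raise ValueError(f"need at least one point, got n={n}")
    if not 0 <= frac_high <= 1:
        raise ValueError(f"frac_high must be in [0, 1], got {frac_high!r}")
    rng = np.random.default_rng(seed)
    valid = np.argwhere(classmap.valid_mask)
    if len(valid) == 0:
        raise ValueError("classmap has no valid pixels")
    high = np.argwhere(
        np.isfinite(classmap.values) & (classmap.values == int(RiskClass.HIGH))
    )
    n_high = round(n * frac_high)
    if n_high > 0 and len(high) == 0:
        raise ValueError("frac_high > 0 but classmap has no high-class pixels")

    def draw(pixels: np.ndarray, count: int) -> list[ResistancePoint]:
        pts = []
        idx = rng.integers(0, len(pixels), size=count)
        # uniform offsets in [0, 1) keep points inside the half-open cell
        u = rng.random((count, 2))
        for (row, col), (ux, uy) in zip(pixels[idx], u):
            lon = classmap.origin[0] + (col + ux) * classmap.cellsize
            lat = (
                classmap.origin[1]
                + (classmap.nrows - 1 - row + uy) * classmap.cellsize
            )
            pts.append(ResistancePoint(lon=lon, lat=lat, year=year, status="resistant"))
        return pts

    points = draw(high, n_high) if n_high > 0 else []
    if n - n_high > 0:
        points.extend(draw(valid, n - n_high))
    return points
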