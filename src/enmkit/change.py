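"""Scenario-to-scenario range dynamics and centroid migration.

Suitability surfaces binarize at the MTSPS threshold (strictly greater
than the threshold counts as suitable). Two binary maps combine into a
change map coded 0 (absent in both periods), -1 (range expansion), 1
(stable presence), 2 (range contraction); the associated statistics are
latitude-corrected gain/stable/loss areas and the percentage columns
relative to the current-period area. The distribution centroid is the
area-weighted mean of suitable-cell centers; its shift between periods is
summarized by great-circle distance, initial bearing (with an 8-sector
compass label), and speed over the period spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AlignmentError, Raster, haversine_km, initial_bearing_deg

__all__ = [
    "ChangeMap",
    "ChangeStats",
    "CentroidShift",
    "binarize",
    "change_map",
    "change_stats",
    "centroid",
    "centroid_shift",
    "compass_sector",
]

CODE_ABSENT, CODE_EXPANSION, CODE_STABLE, CODE_CONTRACTION = 0, -1, 1, 2


def binarize(suit: Raster, mtsps: float) -> Raster:
    """1 where suitability strictly exceeds the threshold, else 0.

    Equality falls to non-suitable: 'suitable' means exceeding MTSPS.
    """
    vals = suit.valid_values()
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("suitability values outside [0, 1]")
    out = np.zeros_like(suit.values)
    out[suit.mask] = (suit.values[suit.mask] > mtsps).astype(float)
    return Raster(suit.header, out, suit.mask.copy())


@dataclass
class ChangeMap:
    """Coded expansion/stable/contraction raster ({0, -1, 1, 2})."""

    codes: Raster


def change_map(current_bin: Raster, future_bin: Raster) -> ChangeMap:
    """Combine two binary occupancy maps into the change coding.

    (0,0) -> 0 absent; (0,1) -> -1 expansion; (1,1) -> 1 stable;
    (1,0) -> 2 contraction.
    """
    if not current_bin.header.approx_equal(future_bin.header):
        raise AlignmentError("current and future binary maps are not aligned")
    mask = current_bin.mask & future_bin.mask
    c = current_bin.values > 0.5
    f = future_bin.values > 0.5
    out = np.zeros_like(current_bin.values)
    out[~c & f] = CODE_EXPANSION
    out[c & f] = CODE_STABLE
    out[c & ~f] = CODE_CONTRACTION
    out[~mask] = 0.0
    return ChangeMap(Raster(current_bin.header, out, mask))


@dataclass
class ChangeStats:
    """Area accounting of a change map (km^2 and percentages).

    By construction ``area_future = area_current + gain - loss`` and
    ``stable = area_current - loss``; percentages are relative to the
    current-period area.
    """

    area_current: float
    area_future: float
    gain: float
    stable: float
    loss: float

    @property
    def range_change_pct(self) -> float:
        return 100.0 * (self.area_future - self.area_current) / self.area_current

    @property
    def pct_loss(self) -> float:
        return 100.0 * self.loss / self.area_current

    @property
    def pct_gain(self) -> float:
        return 100.0 * self.gain / self.area_current

    @classmethod
    def from_areas(
        cls,
        area_current: float,
        gain: float,
        loss: float,
        area_future: float | None = None,
        stable: float | None = None,
    ) -> "ChangeStats":
        """Build the statistics from area figures directly (any area unit).

        ``area_future`` defaults to the accounting identity
        ``current + gain - loss``; ``stable`` to ``current - loss``.
        """
        if area_current <= 0:
            raise ValueError("area_current must be positive")
        if stable is None:
            stable = area_current - loss
        if area_future is None:
            area_future = area_current + gain - loss
        return cls(area_current, area_future, gain, stable, loss)

    def to_row(self) -> dict[str, float]:
        return {
            "area_future": self.area_future,
            "gain": self.gain,
            "stable": self.stable,
            "loss": self.loss,
            "range_change_pct": self.range_change_pct,
            "pct_loss": self.pct_loss,
            "pct_gain": self.pct_gain,
        }


def change_stats(cmap: ChangeMap) -> ChangeStats:
    """Latitude-corrected gain/stable/loss areas and percentage columns."""
    r = cmap.codes
    areas = r.cell_areas_km2()
    gain = float(areas[r.mask & (r.values == CODE_EXPANSION)].sum())
    stable = float(areas[r.mask & (r.values == CODE_STABLE)].sum())
    loss = float(areas[r.mask & (r.values == CODE_CONTRACTION)].sum())
    area_current = stable + loss
    if area_current <= 0:
        raise ValueError("current-period suitable area is zero; percentages undefined")
    return ChangeStats(area_current, stable + gain, gain, stable, loss)


def centroid(bin_raster: Raster) -> tuple[float, float]:
    """Area-weighted centroid (lon, lat) of the suitable (value 1) cells."""
    sel = bin_raster.mask & (bin_raster.values > 0.5)
    if not np.any(sel):
        raise ValueError("no suitable cells; centroid undefined")
    rows, cols = np.nonzero(sel)
    lon, lat = bin_raster.header.rowcol_to_lonlat(rows, cols)
    w = bin_raster.cell_areas_km2()[sel]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def compass_sector(bearing_deg: float) -> str:
    """8-sector compass label; sectors are 45 degrees wide, centered on N, NE, ..."""
    return _SECTORS[int(((bearing_deg % 360.0) + 22.5) // 45.0) % 8]


@dataclass
class CentroidShift:
    """Kinematics of the distribution centroid between two periods."""

    from_lonlat: tuple[float, float]
    to_lonlat: tuple[float, float]
    distance_km: float
    bearing_deg: float
    direction: str
    years: float
    speed_km_per_yr: float

    def to_row(self) -> dict:
        return {
            "from_lon": self.from_lonlat[0],
            "from_lat": self.from_lonlat[1],
            "to_lon": self.to_lonlat[0],
            "to_lat": self.to_lonlat[1],
            "distance_km": self.distance_km,
            "bearing_deg": self.bearing_deg,
            "direction": self.direction,
            "years": self.years,
            "speed_km_per_yr": self.speed_km_per_yr,
        }


def centroid_shift(
    c_from: tuple[float, float], c_to: tuple[float, float], years: float
) -> CentroidShift:
    """Great-circle shift of the centroid over a period spacing in years."""
    if years <= 0:
        raise ValueError("years must be positive")
    d = haversine_km(c_from[0], c_from[1], c_to[0], c_to[1])
    b = initial_bearing_deg(c_from[0], c_from[1], c_to[0], c_to[1])
    return CentroidShift(
        from_lonlat=tuple(map(float, c_from)),
        to_lonlat=tuple(map(float, c_to)),
        distance_km=float(d),
        bearing_deg=float(b),
        direction=compass_sector(b),
        years=float(years),
        speed_km_per_yr=float(d) / float(years),
    )
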