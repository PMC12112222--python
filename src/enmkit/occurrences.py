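"""Presence records: loading, validation, deduplication, spatial thinning.

Occurrence data arrive as CSV with columns ``name, longitude, latitude``
(WGS84 decimal degrees). Cleaning drops unparseable or out-of-range
coordinates, collapses exact coordinate duplicates, and optionally drops
records that fall on masked (invalid) raster cells. Spatial thinning
enforces a minimum pairwise great-circle distance to blunt sampling bias
and spatial autocorrelation before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Raster, haversine_km

__all__ = ["OccurrenceSet", "CleaningReport", "load_and_clean", "thin"]


class SchemaError(ValueError):
    """Input table does not have the required columns."""


@dataclass
class CleaningReport:
    n_input: int = 0
    n_unparseable: int = 0
    n_out_of_range: int = 0
    n_duplicate: int = 0
    n_masked: int = 0
    n_kept: int = 0

    def lines(self) -> list[str]:
        return [
            f"input records: {self.n_input}",
            f"dropped unparseable coordinates: {self.n_unparseable}",
            f"dropped out-of-range coordinates: {self.n_out_of_range}",
            f"collapsed duplicate coordinates: {self.n_duplicate}",
            f"dropped on masked cells: {self.n_masked}",
            f"kept: {self.n_kept}",
        ]


@dataclass
class OccurrenceSet:
    """Cleaned presence records (name, lon, lat)."""

    names: list[str]
    lon: np.ndarray
    lat: np.ndarray
    report: CleaningReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if not (len(self.names) == self.lon.size == self.lat.size):
            raise ValueError("names, lon, lat must have equal length")

    def __len__(self) -> int:
        return self.lon.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "longitude": self.lon, "latitude": self.lat})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def subset(self, idx: np.ndarray) -> "OccurrenceSet":
        idx = np.asarray(idx)
        return OccurrenceSet([self.names[i] for i in idx], self.lon[idx], self.lat[idx])


def load_and_clean(
    csv_path: str | Path | pd.DataFrame,
    raster_mask: Raster | None = None,
) -> OccurrenceSet:
    """Load occurrence CSV and clean it.

    Rows with unparseable or out-of-range coordinates are dropped and
    counted; exact-coordinate duplicates collapse to the first record; if
    ``raster_mask`` is given, records outside the grid or on masked cells
    are dropped. Counts land in ``result.report``.
    """
    if isinstance(csv_path, pd.DataFrame):
        df = csv_path.copy()
    else:
        df = pd.read_csv(csv_path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise SchemaError(f"missing columns: {sorted(required - set(df.columns))}")

    rep = CleaningReport(n_input=len(df))
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    parseable = lon.notna() & lat.notna()
    rep.n_unparseable = int((~parseable).sum())
    df, lon, lat = df[parseable], lon[parseable], lat[parseable]

    in_range = (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
    rep.n_out_of_range = int((~in_range).sum())
    df, lon, lat = df[in_range], lon[in_range], lat[in_range]

    # exact-match dedup after parsing; no rounding before comparison
    dup = pd.DataFrame({"lon": lon, "lat": lat}).duplicated()
    rep.n_duplicate = int(dup.sum())
    df, lon, lat = df[~dup.values], lon[~dup.values], lat[~dup.values]

    if raster_mask is not None:
        vals = raster_mask.sample(lon.to_numpy(), lat.to_numpy())
        on_valid = ~np.isnan(vals)
        rep.n_masked = int((~on_valid).sum())
        df, lon, lat = df[on_valid], lon[on_valid], lat[on_valid]

    rep.n_kept = len(df)
    return OccurrenceSet(
        [str(n) for n in df["name"]], lon.to_numpy(), lat.to_numpy(), report=rep
    )


def thin(occ: OccurrenceSet, min_km: float = 2.5, seed: int | None = 0) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise distance.

    Records are visited in a seed-shuffled order; a record is kept iff its
    haversine distance to every already-kept record is >= ``min_km``. The
    result's pairwise minimum distance is therefore >= ``min_km``, and
    re-thinning a thinned set (same seed convention) is a no-op.

    The shuffled visiting order removes any bias toward file order; pass
    ``seed=None`` to keep input order.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    n = len(occ)
    if n == 0:
        return OccurrenceSet([], np.empty(0), np.empty(0))
    order = np.arange(n)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(order)
    kept: list[int] = []
    kept_lon = np.empty(n)
    kept_lat = np.empty(n)
    for i in order:
        k = len(kept)
        if k:
            d = haversine_km(occ.lon[i], occ.lat[i], kept_lon[:k], kept_lat[:k])
            if np.min(d) < min_km:
                continue
        kept_lon[k] = occ.lon[i]
        kept_lat[k] = occ.lat[i]
        kept.append(i)
    kept_sorted = sorted(kept)  # stable output order: original record order
    return occ.subset(np.array(kept_sorted, dtype=int))
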