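"""Suitability thresholding, grading, and area accounting.

The grading threshold is the maximum test sensitivity plus specificity
logistic threshold (MTSPS): the prediction value maximizing sensitivity of
the test presences plus specificity of the background pseudo-absences.
Grade bounds are MTSPS multiples — (1x, 2x, 3x) — so the published scheme
(0.22 / 0.44 / 0.66) is the MTSPS = 0.22 case: non-suitable below MTSPS,
then low, medium, and high suitability in half-open intervals, the
boundary value belonging to the higher class.

Areas are latitude-corrected sums of spherical cell areas; reports print
in units of 10^4 km^2 to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster

__all__ = [
    "GradeScheme",
    "AreaReport",
    "mtsps_threshold",
    "classify",
    "area_report",
    "distribution_proportion",
    "GRADE_NAMES",
]

GRADE_NAMES = ("none", "low", "medium", "high")


@dataclass(frozen=True)
class GradeScheme:
    """Four-grade suitability scheme anchored on the MTSPS threshold."""

    mtsps: float

    def __post_init__(self) -> None:
        t1, t2, t3 = self.bounds
        if not (0.0 < t1 < t2 < t3 <= 1.0):
            raise ValueError(f"degenerate grade bounds {self.bounds} for mtsps={self.mtsps}")

    @property
    def bounds(self) -> tuple[float, float, float]:
        m = self.mtsps
        return (m, min(2 * m, 1.0), min(3 * m, 1.0))


def mtsps_threshold(test_presence_pred: np.ndarray, background_pred: np.ndarray) -> float:
    """Threshold maximizing sensitivity(test presences) + specificity(background).

    Candidates are the observed prediction values (pooled); sensitivity is
    the fraction of presences >= t, specificity the fraction of background
    < t. Ties resolve to the smallest maximizing candidate.
    """
    p = np.asarray(test_presence_pred, dtype=float)
    b = np.asarray(background_pred, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both prediction sets must be nonempty")
    cand = np.unique(np.concatenate([p, b]))
    ps = np.sort(p)
    bs = np.sort(b)
    sens = 1.0 - np.searchsorted(ps, cand, side="left") / p.size  # P(p >= t)
    spec = np.searchsorted(bs, cand, side="left") / b.size  # P(b < t)
    score = sens + spec
    return float(cand[int(np.argmax(score))])  # argmax takes the first (smallest) on ties


def classify(suit: Raster, scheme: GradeScheme) -> Raster:
    """Grade a suitability raster into codes 0..3 (none/low/medium/high).

    Half-open intervals exactly as printed for the MTSPS = 0.22 scheme:
    p < t1 -> 0, t1 <= p < t2 -> 1, t2 <= p < t3 -> 2, p >= t3 -> 3.
    """
    vals = suit.valid_values()
    if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
        raise ValueError("suitability values outside [0, 1]")
    t1, t2, t3 = scheme.bounds
    g = np.zeros_like(suit.values)
    g[suit.mask] = np.digitize(suit.values[suit.mask], [t1, t2, t3], right=False)
    return Raster(suit.header, g, suit.mask.copy())


@dataclass
class AreaReport:
    """Per-grade latitude-corrected areas (km^2)."""

    area_km2: dict[str, float]

    @property
    def total_suitable(self) -> float:
        return sum(self.area_km2[g] for g in ("low", "medium", "high"))

    @property
    def total_valid(self) -> float:
        return sum(self.area_km2.values())

    def to_frame(self) -> pd.DataFrame:
        """Table in units of 10^4 km^2, rounded to 2 decimals."""
        rows = {f"{g.capitalize()}-suitable" if g != "none" else "None-suitable":
                round(self.area_km2[g] / 1e4, 2) for g in GRADE_NAMES}
        rows["Total-suitable"] = round(self.total_suitable / 1e4, 2)
        return pd.DataFrame({"area_1e4_km2": rows})


def area_report(grades: Raster) -> AreaReport:
    """Sum cell areas per grade over the valid landscape."""
    areas = grades.cell_areas_km2()
    out = {}
    for code, name in enumerate(GRADE_NAMES):
        sel = grades.mask & (grades.values == code)
        out[name] = float(areas[sel].sum())
    return AreaReport(out)


def distribution_proportion(counts_or_areas: dict[str, float]) -> dict[str, float]:
    """Percentage of the species' distribution falling in each grade.

    proportion(grade) = amount(grade) / total * 100; the amounts may be
    record counts or areas. Raises on zero total.
    """
    total = float(sum(counts_or_areas.values()))
    if total <= 0:
        raise ValueError("total count/area is zero; proportions undefined")
    return {g: 100.0 * v / total for g, v in counts_or_areas.items()}
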