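"""Collinearity screening of candidate predictor layers.

Pairwise Pearson correlation is computed over landscape cells (optionally a
seeded subsample), and highly collinear pairs (|r| above a threshold,
default 0.8) are resolved by dropping the member with the lower model
contribution — or the lower user-supplied biological priority, when one is
given. Screening repeats on the surviving set until every kept pair is
below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import RasterStack

__all__ = ["CorrelationMatrix", "pearson_matrix", "screen_variables"]


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray  # symmetric, diagonal 1; NaN rows for zero-variance layers

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.names)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape does not match names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def pearson_matrix(
    stack: RasterStack,
    sample: tuple[np.ndarray, np.ndarray] | None = None,
    max_cells: int | None = None,
    seed: int = 0,
) -> CorrelationMatrix:
    """Pairwise Pearson r between layers over valid landscape cells.

    ``sample`` is an optional (rows, cols) cell set; by default all jointly
    valid cells are used, subsampled to ``max_cells`` with the given seed if
    requested. A zero-variance layer yields NaN in its row/column (treated
    as uncorrelated by :func:`screen_variables`) and a warning.
    """
    if sample is None:
        rows, cols = np.nonzero(stack.joint_mask())
    else:
        rows, cols = (np.asarray(a, dtype=int) for a in sample)
    if rows.size > 3 and max_cells is not None and rows.size > max_cells:
        idx = np.random.default_rng(seed).choice(rows.size, size=max_cells, replace=False)
        rows, cols = rows[idx], cols[idx]
    if rows.size < 3:
        raise ValueError("need at least 3 valid cells for correlation")
    X = stack.values_at_cells(rows, cols)
    sd = X.std(axis=0)
    zero_var = sd == 0
    if np.any(zero_var):
        bad = [stack.names[i] for i in np.nonzero(zero_var)[0]]
        warnings.warn(f"zero-variance layers (correlation undefined): {bad}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(stack.names, r)


def screen_variables(
    corr: CorrelationMatrix,
    contribution: dict[str, float],
    threshold: float = 0.8,
    priority: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Iteratively drop one member of each excessively correlated pair.

    Repeatedly finds the surviving pair with the largest |r| >= threshold
    and drops the member with the lower contribution. ``priority`` (an
    ordered list, most important first) expresses biological significance
    and, where it covers both members, overrides the contribution
    comparison. Ties fall to the later name in the matrix's canonical
    order, so the kept set does not depend on input shuffling.

    Returns ``(kept_names, dropped)`` where each drop is
    ``(dropped_name, kept_partner, r)``.
    """
    names = corr.names
    missing = [n for n in names if n not in contribution]
    if missing:
        raise KeyError(f"contribution missing for: {missing}")
    rank = {n: i for i, n in enumerate(priority)} if priority else {}
    absr = np.abs(np.nan_to_num(corr.r, nan=0.0))
    np.fill_diagonal(absr, 0.0)
    alive = list(range(len(names)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = absr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() < threshold:
            break
        i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_s], alive[j_s]
        a, b = names[i], names[j]
        if a in rank and b in rank:
            loser = i if rank[a] > rank[b] else j
        elif contribution[a] != contribution[b]:
            loser = i if contribution[a] < contribution[b] else j
        else:
            loser = max(i, j)  # tie: drop the later name in canonical order
        winner = j if loser == i else i
        dropped.append((names[loser], names[winner], float(corr.r[i, j])))
        alive.remove(loser)
    return [names[i] for i in alive], dropped
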