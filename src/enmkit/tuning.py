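"""Model tuning: FC x RM grid search with checkerboard spatial partitions.

The candidate grid crosses seven feature-class codes (L, LQ, H, LQH, LQP,
LQHP, LQHPT) with eight regularization multipliers (0.5 to 4.0 in steps of
0.5) — 56 combinations. Presences and background points are split into four
spatial groups by a two-level ("checkerboard 2") partition; each
combination is scored by cross-validated discrimination (mean train/test
AUC, their difference, and the 10th-percentile omission rate) and by AICc
of the full-data fit, with the likelihood standardized over the whole
landscape (Warren–Seifert convention). The combination with delta AICc = 0
is selected; ties go to fewer parameters, then smaller RM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from math import ceil, log

import numpy as np
import pandas as pd

from .evaluation import auc
from .features import FC_CODES, FeatureSet
from .grids import GridHeader, RasterStack
from .model import MaxEnt, MaxEntResults, fit_penalized, sample_background
from .occurrences import OccurrenceSet

__all__ = [
    "TuneRecord",
    "PartitionAssignment",
    "checkerboard2",
    "or10",
    "aicc",
    "tune",
    "TuneResults",
    "DEFAULT_RMS",
]

DEFAULT_RMS = tuple(np.arange(0.5, 4.01, 0.5))


class PartitionError(ValueError):
    """No valid spatial partition could be constructed."""


@dataclass
class PartitionAssignment:
    """Group ids in {1..4} per presence and per background point."""

    presence: np.ndarray
    background: np.ndarray
    agg: tuple[int, int]

    def is_valid(self) -> bool:
        return bool(np.all(np.isin([1, 2, 3, 4], self.presence)))


def _cb2_groups(lon: np.ndarray, lat: np.ndarray, header: GridHeader, agg1: int, agg2: int) -> np.ndarray:
    cs = header.cellsize
    fine = agg1 * cs
    coarse = agg1 * agg2 * cs
    fx = np.floor((np.asarray(lon) - header.xll) / fine).astype(int)
    fy = np.floor((np.asarray(lat) - header.yll) / fine).astype(int)
    cx = np.floor((np.asarray(lon) - header.xll) / coarse).astype(int)
    cy = np.floor((np.asarray(lat) - header.yll) / coarse).astype(int)
    bit_b = (fx + fy) % 2
    bit_a = (cx + cy) % 2
    return 2 * bit_a + bit_b + 1


def checkerboard2(
    pres_lonlat: tuple[np.ndarray, np.ndarray],
    bg_lonlat: tuple[np.ndarray, np.ndarray],
    header: GridHeader,
    agg1: int = 10,
    agg2: int = 2,
) -> PartitionAssignment:
    """Two-level checkerboard partition into four groups.

    The coarse board (blocks of ``agg1*agg2`` cells) sets bit A by block
    parity, the fine board (blocks of ``agg1`` cells) sets bit B; the group
    is ``2A + B + 1``. Deterministic from the grid origin; translating all
    points by a full parity period leaves the assignment unchanged.
    """
    if agg1 < 1 or agg2 < 1:
        raise ValueError("aggregation factors must be >= 1")
    return PartitionAssignment(
        presence=_cb2_groups(*pres_lonlat, header, agg1, agg2),
        background=_cb2_groups(*bg_lonlat, header, agg1, agg2),
        agg=(agg1, agg2),
    )


def find_partition(
    pres_lonlat, bg_lonlat, header, agg1: int = 10, agg2: int = 2
) -> PartitionAssignment:
    """Checkerboard-2 partition with fallback to finer boards when a
    presence group comes out empty."""
    candidates = []
    a = agg1
    while a >= 1:
        candidates.append((a, agg2))
        a //= 2
    candidates.append((1, 1))
    for a1, a2 in candidates:
        part = checkerboard2(pres_lonlat, bg_lonlat, header, a1, a2)
        if part.is_valid():
            return part
    raise PartitionError("no checkerboard aggregation yields four nonempty presence groups")


def or10(train_pred: np.ndarray, test_pred: np.ndarray) -> float:
    """10th-percentile training omission rate.

    The threshold excludes the lowest 10% of training presence predictions
    (ceiling count convention: with n training presences, the
    ``ceil(0.1 n)`` lowest values fall below it); the rate is the fraction
    of test presences strictly below that threshold.
    """
    train = np.sort(np.asarray(train_pred, dtype=float))
    n = train.size
    if n < 10:
        raise ValueError("need at least 10 training presences")
    n_excluded = ceil(0.1 * n)
    thr = train[n_excluded]
    return float(np.mean(np.asarray(test_pred) < thr))


def aicc_formula(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``2k - 2 lnL + 2k(k+1)/(n-k-1)``.

    NaN when ``k >= n - 1`` (the correction term blows up)."""
    if k >= n - 1:
        return float("nan")
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)


def aicc(results: MaxEntResults, stack: RasterStack, presence_rc=None) -> float:
    """Sample-size-corrected AIC of a fitted model.

    The raw prediction is standardized to sum to one over all valid
    landscape cells; the log-likelihood is the sum of the standardized raw
    values (logged) at the presence cells; ``k`` counts nonzero
    coefficients. Returns NaN when ``k >= n - 1`` (correction undefined).
    """
    if presence_rc is None:
        if results.model is None or results.model.presence_rc is None:
            raise ValueError("presence cells unknown; pass presence_rc")
        presence_rc = results.model.presence_rc
    prow, pcol = presence_rc
    raw = results.predict(stack, output="raw")
    on_valid = raw.mask[prow, pcol]
    if not np.all(on_valid):
        warnings.warn(
            f"{int((~on_valid).sum())} presences on masked cells excluded from AICc",
            stacklevel=2,
        )
        prow, pcol = prow[on_valid], pcol[on_valid]
    total = raw.values[raw.mask].sum()
    p = raw.values[prow, pcol] / total
    lnL = float(np.sum(np.log(np.maximum(p, 1e-300))))
    return aicc_formula(lnL, results.k_nonzero, p.size)


@dataclass
class TuneRecord:
    """Per-combination ledger entry of the tuning grid."""

    fc: str
    rm: float
    auc_train: float
    auc_test: float
    auc_diff: float
    or10: float
    k: int
    aicc: float
    delta_aicc: float = float("nan")


class TuneResults:
    """Outcome of the grid search: the ledger, the winner, and its fit."""

    def __init__(
        self,
        records: list[TuneRecord],
        selected: tuple[str, float],
        best: MaxEntResults,
        partition: PartitionAssignment,
    ):
        self.records = records
        self.selected = selected
        self.best = best
        self.partition = partition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tune(
    stack: RasterStack,
    occurrences: OccurrenceSet,
    fcs: tuple[str, ...] = FC_CODES,
    rms: tuple[float, ...] = DEFAULT_RMS,
    n_background: int = 10_000,
    seed: int = 0,
    agg: tuple[int, int] = (10, 2),
    n_knots: int = 50,
    max_iter: int = 5000,
    tol: float = 1e-5,
) -> TuneResults:
    """Grid-search FC x RM and select the lowest-AICc combination.

    For each combination: a full-data fit provides the nonzero-coefficient
    count and AICc; four checkerboard train/test splits provide mean train
    and test AUC, their mean difference, and the mean 10th-percentile
    omission rate. Fits along the RM path of one FC are warm-started from
    the next-larger RM. Raises if every AICc is undefined.
    """
    mask = stack.joint_mask()
    h = stack.header
    inside = h.contains(occurrences.lon, occurrences.lat)
    prow, pcol = h.lonlat_to_rowcol(occurrences.lon[inside], occurrences.lat[inside])
    ok = mask[prow, pcol]
    prow, pcol = prow[ok], pcol[ok]
    if prow.size < 10:
        raise ValueError("need at least 10 usable presences for tuning")
    brow, bcol = sample_background(stack, n=n_background, seed=seed)
    plon, plat = h.rowcol_to_lonlat(prow, pcol)
    blon, blat = h.rowcol_to_lonlat(brow, bcol)
    part = find_partition((plon, plat), (blon, blat), h, *agg)

    X_p = stack.values_at_cells(prow, pcol)
    X_b = stack.values_at_cells(brow, bcol)
    rms_desc = sorted(set(float(r) for r in rms), reverse=True)

    records: list[TuneRecord] = []
    fits: dict[tuple[str, float], MaxEntResults] = {}
    for fc in fcs:
        feats = FeatureSet.from_background(X_b, stack.names, fc, n_knots=n_knots)
        F_p = feats.transform(X_p)
        F_b = feats.transform(X_b)
        reg_full = feats.reg_scale_for(F_p)
        folds = []
        for g in (1, 2, 3, 4):
            tr_p, te_p = part.presence != g, part.presence == g
            tr_b, te_b = part.background != g, part.background == g
            folds.append((tr_p, te_p, tr_b, te_b, feats.reg_scale_for(F_p[tr_p])))
        warm_full: np.ndarray | None = None
        warm_cv: list[np.ndarray | None] = [None] * 4
        for rm in rms_desc:
            sol = fit_penalized(
                F_p, F_b, rm * reg_full, max_iter=max_iter, tol=tol, start=warm_full
            )
            warm_full = sol["beta"]
            res = MaxEntResults(
                features=feats,
                beta=sol["beta"],
                logZsum=sol["logZsum"],
                entropy=sol["entropy"],
                gain=sol["gain"],
                converged=sol["converged"],
                n_iter=sol["n_iter"],
                path=sol["path"],
                meta={"fc": fc, "rm": rm, "n_presence": int(prow.size), "n_background": int(brow.size)},
            )
            fits[(fc, rm)] = res
            a_tr, a_te, orr = [], [], []
            for i, (tr_p, te_p, tr_b, te_b, reg_cv) in enumerate(folds):
                s = fit_penalized(
                    F_p[tr_p], F_b[tr_b], rm * reg_cv, max_iter=max_iter, tol=tol, start=warm_cv[i]
                )
                warm_cv[i] = s["beta"]
                b = s["beta"]
                eta_p, eta_b = F_p @ b, F_b @ b
                a_tr.append(auc(eta_p[tr_p], eta_b[tr_b]))
                a_te.append(auc(eta_p[te_p], eta_b[te_b]))
                orr.append(or10(eta_p[tr_p], eta_p[te_p]))
            aicc_val = _aicc_from_design(res, stack, (prow, pcol))
            records.append(
                TuneRecord(
                    fc=fc,
                    rm=rm,
                    auc_train=float(np.mean(a_tr)),
                    auc_test=float(np.mean(a_te)),
                    auc_diff=float(np.mean(np.array(a_tr) - np.array(a_te))),
                    or10=float(np.mean(orr)),
                    k=res.k_nonzero,
                    aicc=aicc_val,
                )
            )

    defined = [r for r in records if np.isfinite(r.aicc)]
    if not defined:
        raise PartitionError("AICc undefined for every combination (k >= n-1 throughout)")
    best_aicc = min(r.aicc for r in defined)
    for r in records:
        r.delta_aicc = r.aicc - best_aicc if np.isfinite(r.aicc) else float("nan")
    # tie rule: smallest AICc, then fewer parameters, then smaller RM
    winner = min(defined, key=lambda r: (r.aicc, r.k, r.rm))
    sel = (winner.fc, winner.rm)
    records.sort(key=lambda r: (FC_CODES.index(r.fc) if r.fc in FC_CODES else 99, r.rm))
    return TuneResults(records, sel, fits[sel], part)


def _aicc_from_design(results: MaxEntResults, stack: RasterStack, presence_rc) -> float:
    return aicc(results, stack.subset(results.features.layer_names), presence_rc=presence_rc)
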