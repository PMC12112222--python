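"""Model evaluation and variable-importance diagnostics.

Discrimination is summarized by the rank (Mann-Whitney) AUC of presence
versus background predictions and by the True Skill Statistic at a chosen
threshold. Variable importance comes in three flavors, mirroring standard
MaxEnt reporting: jackknife gains (each variable alone / model without
it), percent contribution (descent-path credit of the fitted model), and
permutation importance (training-AUC drop when a variable's values are
shuffled across presence and background jointly). Response curves show the
marginal suitability profile of one variable with the others held at their
background means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .model import MaxEnt, MaxEntResults

__all__ = [
    "auc",
    "auc_band",
    "tss",
    "EvaluationReport",
    "evaluate",
    "jackknife",
    "percent_contribution",
    "permutation_importance",
    "response_curve",
    "threshold_crossings",
]


def auc(pred_presence: np.ndarray, pred_background: np.ndarray) -> float:
    """Rank AUC: P(presence > background) + 0.5 P(equal)."""
    x = np.asarray(pred_presence, dtype=float)
    y = np.asarray(pred_background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both prediction sets must be nonempty")
    u = mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(u / (x.size * y.size))


#: AUC quality bands (left-closed intervals; 0.9 and up is "excellent").
_BANDS = ((0.9, "excellent"), (0.8, "good"), (0.7, "fair"), (0.5, "poor"), (0.0, "fail"))


def auc_band(value: float) -> str:
    for lo, name in _BANDS:
        if value >= lo:
            return name
    return "fail"


def tss(pred_presence: np.ndarray, pred_background: np.ndarray, threshold: float) -> float:
    """True Skill Statistic = sensitivity + specificity - 1.

    Presence is predicted where the score is >= threshold; background
    points act as pseudo-absences.
    """
    sens = float(np.mean(np.asarray(pred_presence) >= threshold))
    spec = float(np.mean(np.asarray(pred_background) < threshold))
    return sens + spec - 1.0


@dataclass
class EvaluationReport:
    auc_train: float
    auc_test: float
    tss: float
    band: str


def evaluate(
    train_presence: np.ndarray,
    test_presence: np.ndarray,
    background: np.ndarray,
    threshold: float,
) -> EvaluationReport:
    """Bundle train/test AUC, TSS at the threshold, and the AUC band."""
    a_tr = auc(train_presence, background)
    a_te = auc(test_presence, background)
    return EvaluationReport(a_tr, a_te, tss(test_presence, background, threshold), auc_band(a_te))


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------


def jackknife(model: MaxEnt, max_iter: int = 5000, tol: float = 1e-5) -> pd.DataFrame:
    """Jackknife gains per variable.

    For each variable v, refit with only v (``rtg_alone``) and with all
    variables but v (``gain_without``), same FC/RM and knot budget. A refit
    failure flags that variable's row with NaN and leaves others intact.
    Index: variable names; includes the full-model gain as attribute
    ``df.attrs['gain_full']``.
    """
    names = model.layer_names
    if len(names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    full = model.fit(max_iter=max_iter, tol=tol)
    alone = {}
    without = {}
    for i, v in enumerate(names):
        keep_one = [i]
        keep_rest = [j for j in range(len(names)) if j != i]
        for keep, store in ((keep_one, alone), (keep_rest, without)):
            try:
                sub = MaxEnt(
                    model.X_presence[:, keep],
                    model.X_background[:, keep],
                    [names[j] for j in keep],
                    fc=model.fc,
                    rm=model.rm,
                )
                store[v] = sub.fit(max_iter=max_iter, tol=tol).gain
            except Exception:
                store[v] = float("nan")
    df = pd.DataFrame(
        {"rtg_alone": [alone[v] for v in names], "gain_without": [without[v] for v in names]},
        index=names,
    )
    df.attrs["gain_full"] = full.gain
    return df


def percent_contribution(results: MaxEntResults) -> pd.Series:
    """Percent contribution per variable from the descent path.

    Each coordinate-descent step's objective improvement is credited to the
    variable(s) owning the updated feature (products split evenly between
    their two layers); credits are normalized to sum to 100.
    """
    if not results.path:
        raise ValueError(
            "model was fitted without a recorded descent path (or nothing moved); "
            "use permutation_importance instead"
        )
    names = results.features.layer_names
    credit = np.zeros(len(names))
    owners = results.features.variable_of()
    for j, improvement in results.path:
        for v in owners[j]:
            credit[v] += improvement / len(owners[j])
    total = credit.sum()
    if total <= 0:
        raise ValueError("no positive objective improvement recorded")
    return pd.Series(100.0 * credit / total, index=names, name="percent_contribution")


def permutation_importance(
    results: MaxEntResults,
    X_presence: np.ndarray | None = None,
    X_background: np.ndarray | None = None,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.Series:
    """Permutation importance per variable (percent).

    For each variable, its values are permuted jointly across presence and
    background rows, predictions recomputed, and the drop in training AUC
    recorded (averaged over ``n_repeats`` shuffles). Negative drops floor
    at zero before normalizing the drops to sum to 100.
    """
    if X_presence is None or X_background is None:
        if results.model is None:
            raise ValueError("pass X_presence and X_background for a detached results object")
        X_presence = results.model.X_presence
        X_background = results.model.X_background
    rng = np.random.default_rng(seed)
    n_p = X_presence.shape[0]
    X_all = np.vstack([X_presence, X_background])
    base_eta = results.linear_predictor(X_all, clamp=False)
    base_auc = auc(base_eta[:n_p], base_eta[n_p:])
    names = results.features.layer_names
    drops = np.zeros(len(names))
    for i in range(len(names)):
        d = 0.0
        for _ in range(n_repeats):
            Xp = X_all.copy()
            Xp[:, i] = rng.permutation(Xp[:, i])
            eta = results.linear_predictor(Xp, clamp=True)
            d += base_auc - auc(eta[:n_p], eta[n_p:])
        drops[i] = max(d / n_repeats, 0.0)
    total = drops.sum()
    if total <= 0:
        return pd.Series(np.zeros(len(names)), index=names, name="permutation_importance")
    return pd.Series(100.0 * drops / total, index=names, name="permutation_importance")


# ---------------------------------------------------------------------------
# Response curves
# ---------------------------------------------------------------------------


def response_curve(
    results: MaxEntResults,
    variable: str,
    n_grid: int = 101,
    X_background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Marginal response curve of one variable.

    The variable sweeps its training background range while every other
    variable sits at its background mean; the curve reports the logistic
    suitability. ``df.attrs['argmax']`` holds the variable value of peak
    suitability.
    """
    names = results.features.layer_names
    if variable not in names:
        raise KeyError(f"{variable!r} not among model variables {names}")
    i = names.index(variable)
    if X_background is None:
        if results.model is None:
            raise ValueError("pass X_background for a detached results object")
        X_background = results.model.X_background
    lo, hi = results.features.layer_min[i], results.features.layer_max[i]
    grid = np.linspace(lo, hi, n_grid)
    X = np.tile(X_background.mean(axis=0), (n_grid, 1))
    X[:, i] = grid
    y = results.predict_points(X, output="logistic")
    df = pd.DataFrame({variable: grid, "logistic": y})
    df.attrs["argmax"] = float(grid[int(np.argmax(y))])
    return df


def threshold_crossings(x: np.ndarray, y: np.ndarray, level: float) -> list[float]:
    """Variable values where a response curve crosses ``level``.

    Linear interpolation between grid points; an exact hit reports the grid
    value itself. Used to read 'suitable survival' limits off response
    curves at the suitability threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out: list[float] = []
    d = y - level
    for i in range(len(x) - 1):
        if d[i] == 0.0:
            out.append(float(x[i]))
        if d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            out.append(float(x[i] + t * (x[i + 1] - x[i])))
    if d[-1] == 0.0:
        out.append(float(x[-1]))
    return out
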