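"""Presence-background maximum-entropy model (statsmodels-style API).

:class:`MaxEnt` holds the data — environmental values at presence points
and at a background sample — plus the feature-class code (FC) and the
regularization multiplier (RM). :meth:`MaxEnt.fit` minimizes the
L1-penalized negative log-likelihood of the Gibbs distribution over the
background,

    obj(beta) = -mean_presence(eta) + log mean_background(e^eta)
                + sum_j rm * reg_scale_j * |beta_j|,   eta = beta . f(x),

by greedy coordinate descent with per-coordinate proximal Newton steps.
The descent path (which feature moved, and how much the objective
improved) is recorded, which is what the percent-contribution accounting
in :mod:`enmkit.evaluation` consumes.

The fitted raw distribution ``e^eta / Z`` sums to one over the background;
the logistic output is ``q / (1 + q)`` with ``q = raw * e^H`` and ``H`` the
entropy of the raw distribution, so a featureless (null) model scores 0.5
everywhere — the standard MaxEnt logistic transform with prevalence 0.5.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .features import FeatureSet, ConfigurationError
from .grids import Raster, RasterStack
from .occurrences import OccurrenceSet

__all__ = ["MaxEnt", "MaxEntResults", "FitError", "sample_background"]


class FitError(RuntimeError):
    """The model cannot be fitted (degenerate design)."""


def sample_background(
    stack: RasterStack, n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample background cells uniformly, without replacement, from the
    jointly valid mask. Returns (rows, cols); all valid cells if fewer
    than ``n`` exist."""
    rows, cols = np.nonzero(stack.joint_mask())
    if rows.size == 0:
        raise ValueError("stack has no valid cells")
    if rows.size > n:
        idx = np.random.default_rng(seed).choice(rows.size, size=n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return rows, cols


class MaxEnt:
    """Maximum-entropy SDM specification.

    Parameters
    ----------
    X_presence, X_background
        Layer-value matrices, shape (n_points, n_layers), same column order.
    layer_names
        Names of the layers (columns).
    fc
        Feature-class code: any subset string of ``LQPHT``
        (e.g. ``"LQP"``).
    rm
        Regularization multiplier scaling every per-feature L1 penalty.
    n_knots
        Knots per layer for hinge/threshold classes, at background
        quantiles.
    """

    def __init__(
        self,
        X_presence: np.ndarray,
        X_background: np.ndarray,
        layer_names: list[str],
        fc: str = "LQP",
        rm: float = 1.0,
        n_knots: int = 50,
    ):
        self.X_presence = np.asarray(X_presence, dtype=float)
        self.X_background = np.asarray(X_background, dtype=float)
        if self.X_presence.shape[0] < 5:
            raise ValueError("need at least 5 presence points")
        if rm <= 0:
            raise ValueError("rm must be positive")
        self.layer_names = list(layer_names)
        self.fc = fc
        self.rm = float(rm)
        self.features = FeatureSet.from_background(
            self.X_background, self.layer_names, fc, n_knots=n_knots
        )
        self.F_p = self.features.transform(self.X_presence)
        self.F_b = self.features.transform(self.X_background)
        if np.all(self.F_b.std(axis=0) == 0):
            raise FitError("all features are constant over the background")
        self.features.compute_reg_scale(self.F_p)
        self.lam = self.rm * self.features.reg_scale
        # filled by from_stack for landscape-aware operations (AICc)
        self.presence_rc: tuple[np.ndarray, np.ndarray] | None = None
        self.background_rc: tuple[np.ndarray, np.ndarray] | None = None
        self.seed: int | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_stack(
        cls,
        stack: RasterStack,
        occurrences: OccurrenceSet,
        fc: str = "LQP",
        rm: float = 1.0,
        n_background: int = 10_000,
        seed: int = 0,
        n_knots: int = 50,
    ) -> "MaxEnt":
        """Build the model from a raster stack and an occurrence set.

        Background cells are drawn uniformly (seeded, without replacement)
        from the jointly valid mask; presences are not added to the
        background. Presences falling outside the grid or on masked cells
        are dropped with a warning.
        """
        mask = stack.joint_mask()
        h = stack.header
        inside = h.contains(occurrences.lon, occurrences.lat)
        prow, pcol = h.lonlat_to_rowcol(occurrences.lon[inside], occurrences.lat[inside])
        on_valid = mask[prow, pcol]
        n_drop = int((~inside).sum() + (~on_valid).sum())
        if n_drop:
            warnings.warn(f"dropped {n_drop} presences off-grid or on masked cells", stacklevel=2)
        prow, pcol = prow[on_valid], pcol[on_valid]
        brow, bcol = sample_background(stack, n=n_background, seed=seed)
        mdl = cls(
            stack.values_at_cells(prow, pcol),
            stack.values_at_cells(brow, bcol),
            stack.names,
            fc=fc,
            rm=rm,
            n_knots=n_knots,
        )
        mdl.presence_rc = (prow, pcol)
        mdl.background_rc = (brow, bcol)
        mdl.seed = seed
        return mdl

    # ------------------------------------------------------------------
    def fit(
        self,
        max_iter: int = 5000,
        tol: float = 1e-5,
        start: np.ndarray | None = None,
        batch: int = 8,
    ) -> "MaxEntResults":
        """Fit by greedy coordinate descent on the penalized objective.

        ``max_iter`` caps the number of coordinate updates; ``tol`` is the
        KKT violation threshold declaring convergence. ``start`` warm-starts
        the coefficients (used along the RM path in tuning).
        """
        sol = fit_penalized(
            self.F_p, self.F_b, self.lam, max_iter=max_iter, tol=tol, start=start, batch=batch
        )
        return MaxEntResults(
            model=self,
            features=self.features,
            beta=sol["beta"],
            logZsum=sol["logZsum"],
            entropy=sol["entropy"],
            gain=sol["gain"],
            converged=sol["converged"],
            n_iter=sol["n_iter"],
            path=sol["path"],
        )


def fit_penalized(
    F_p: np.ndarray,
    F_b: np.ndarray,
    lam: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-5,
    start: np.ndarray | None = None,
    batch: int = 8,
) -> dict:
    """Design-level L1-penalized Gibbs fit (greedy coordinate descent).

    Minimizes ``-mean_rows(F_p) . beta + log mean(exp(F_b beta)) +
    lam . |beta|``. Each outer pass computes the full gradient over the
    background, picks the coordinates with the largest KKT violation, and
    applies per-coordinate proximal Newton steps with backtracking on the
    true objective. Returns beta plus the background-distribution summaries
    (log-normalizer, entropy), the regularized gain (null model = 0), and
    the descent path as (feature, objective improvement) pairs.
    """
    F_p = np.asarray(F_p, dtype=float)
    F_b = np.asarray(F_b, dtype=float)
    lam = np.asarray(lam, dtype=float)
    m_bg, K = F_b.shape
    a = F_p.mean(axis=0)  # presence feature means
    beta = np.zeros(K) if start is None else np.asarray(start, dtype=float).copy()
    eta_b = F_b @ beta
    mean_eta_p = float(a @ beta)
    path: list[tuple[int, float]] = []

    def current(eta):
        m = eta.max()
        e = np.exp(eta - m)
        s = e.sum()
        return e / s, m + np.log(s / m_bg)

    w, lme = current(eta_b)
    obj = -mean_eta_p + lme + float(lam @ np.abs(beta))
    n_updates = 0
    converged = False
    batch = max(1, batch)
    while n_updates < max_iter:
        grad = F_b.T @ w - a
        viol = np.where(
            beta == 0.0,
            np.maximum(np.abs(grad) - lam, 0.0),
            np.abs(grad + lam * np.sign(beta)),
        )
        if viol.max() < tol:
            converged = True
            break
        order = np.argsort(viol)[::-1][:batch]
        moved = False
        for j in order:
            if viol[j] < tol:
                break
            f_bj = F_b[:, j]
            m1 = float(w @ f_bj)
            g = m1 - a[j]
            h = max(float(w @ (f_bj * f_bj)) - m1 * m1, 1e-12)
            z = beta[j] - g / h
            new_bj = np.sign(z) * max(abs(z) - lam[j] / h, 0.0)
            d = new_bj - beta[j]
            if d == 0.0:
                continue
            # backtrack on the true objective (prox-Newton step may overshoot)
            for _ in range(12):
                eta_try = eta_b + d * f_bj
                w_try, lme_try = current(eta_try)
                pen = float(lam @ np.abs(beta)) - lam[j] * abs(beta[j]) + lam[j] * abs(beta[j] + d)
                obj_try = -(mean_eta_p + d * a[j]) + lme_try + pen
                if obj_try <= obj + 1e-12:
                    break
                d *= 0.5
            else:
                continue
            if obj - obj_try > 0:
                path.append((int(j), obj - obj_try))
            beta[j] += d
            mean_eta_p += d * a[j]
            eta_b = eta_try
            w, lme = w_try, lme_try
            obj = obj_try
            n_updates += 1
            moved = True
            if n_updates >= max_iter:
                break
        if not moved:
            # no productive coordinate among the batch: accept the stall
            converged = bool(viol.max() < 10 * tol)
            break

    logZsum = lme + np.log(m_bg)
    p = np.exp(eta_b - logZsum)
    p = p / p.sum()  # guard rounding
    H = float(-(p * np.log(np.maximum(p, 1e-300))).sum())
    return {
        "beta": beta,
        "logZsum": float(logZsum),
        "entropy": H,
        "gain": float(-obj),  # null objective is exactly 0
        "converged": converged,
        "n_iter": n_updates,
        "path": path,
    }


class MaxEntResults:
    """Fitted MaxEnt model: coefficients, normalizer, entropy, diagnostics."""

    def __init__(
        self,
        features: FeatureSet,
        beta: np.ndarray,
        logZsum: float,
        entropy: float,
        gain: float,
        converged: bool,
        n_iter: int,
        path: list[tuple[int, float]] | None = None,
        model: "MaxEnt | None" = None,
        meta: dict | None = None,
    ):
        self.model = model
        self.features = features
        self.beta = np.asarray(beta, dtype=float)
        self.logZsum = float(logZsum)
        self.entropy = float(entropy)
        self.gain = float(gain)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.path = path or []
        self.meta = meta or {}
        if model is not None:
            self.meta.setdefault("fc", model.fc)
            self.meta.setdefault("rm", model.rm)
            self.meta.setdefault("n_presence", model.X_presence.shape[0])
            self.meta.setdefault("n_background", model.X_background.shape[0])

    # -- core prediction ---------------------------------------------------
    @property
    def k_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def linear_predictor(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        F = self.features.transform(np.asarray(X, dtype=float), clamp=clamp)
        return F @ self.beta

    def predict_points(
        self, X: np.ndarray, output: str = "logistic", clamp: bool = True
    ) -> np.ndarray:
        """Raw or logistic suitability at arbitrary layer-value rows."""
        eta = self.linear_predictor(X, clamp=clamp)
        if output == "raw":
            return np.exp(eta - self.logZsum)
        if output == "logistic":
            q = np.exp(eta - self.logZsum + self.entropy)
            return q / (1.0 + q)
        raise ConfigurationError(f"unknown output {output!r}")

    def predict(self, stack: RasterStack, output: str = "logistic") -> Raster:
        """Project the model over a raster stack (masked in = masked out)."""
        missing = [n for n in self.features.layer_names if n not in stack]
        if missing:
            raise ConfigurationError(f"stack lacks model layers: {missing}")
        sub = stack.subset(self.features.layer_names)
        mask = sub.joint_mask()
        rows, cols = np.nonzero(mask)
        vals = self.predict_points(sub.values_at_cells(rows, cols), output=output)
        out = np.zeros(mask.shape)
        out[rows, cols] = vals
        return Raster(sub.header, out, mask)

    def training_gain(self) -> float:
        """Regularized training gain over the uniform null (null = 0)."""
        return self.gain

    # -- reporting ---------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        labels = self.features.labels
        nz = np.nonzero(self.beta)[0]
        order = nz[np.argsort(-np.abs(self.beta[nz]))][:top]
        lines = [
            "MaxEnt model results",
            "=" * 44,
            f"feature classes:      {self.meta.get('fc', '?')}",
            f"regularization mult.: {self.meta.get('rm', '?')}",
            f"presences:            {self.meta.get('n_presence', '?')}",
            f"background points:    {self.meta.get('n_background', '?')}",
            f"features (nonzero):   {len(self.beta)} ({self.k_nonzero})",
            f"regularized gain:     {self.gain:.4f}",
            f"entropy:              {self.entropy:.4f}",
            f"converged:            {self.converged} ({self.n_iter} updates)",
            "-" * 44,
            f"{'feature':<28}{'coef':>14}",
        ]
        for j in order:
            lines.append(f"{labels[j]:<28}{self.beta[j]:>14.5f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "features": self.features.to_dict(),
            "beta": self.beta.tolist(),
            "logZsum": self.logZsum,
            "entropy": self.entropy,
            "gain": self.gain,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "meta": self.meta,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxEntResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            features=FeatureSet.from_dict(doc["features"]),
            beta=np.array(doc["beta"]),
            logZsum=doc["logZsum"],
            entropy=doc["entropy"],
            gain=doc["gain"],
            converged=doc["converged"],
            n_iter=doc["n_iter"],
            meta=doc.get("meta", {}),
        )
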