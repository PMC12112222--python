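"""MaxEnt feature expansion and default regularization.

Environmental layers are expanded into model features by class:

* ``L`` linear — the layer value itself
* ``Q`` quadratic — its square
* ``P`` product — all pairwise products of layers
* ``H`` hinge — forward ``max(0, (x-k)/(max-k))`` and reverse
  ``max(0, (k-x)/(k-min))`` pieces at knots placed on background quantiles
* ``T`` threshold — step functions ``1[x > k]`` at the same knots

Every feature is min-max scaled so its background values lie in [0, 1]
(hinge and threshold features are constructed on that scale already). At
projection time features may be clamped back to [0, 1], the standard MaxEnt
extrapolation rule for novel climates.

Per-feature L1 penalty weights follow the published MaxEnt defaults: a
class-specific base beta interpolated against the presence sample size,
multiplied by the feature's presence-sample standard deviation over
sqrt(n_presence). The full penalty in the fit is ``rm * reg_scale_j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["FeatureDef", "FeatureSet", "build_features", "default_reg_scale", "FC_CODES"]

FC_CODES = ("L", "LQ", "H", "LQH", "LQP", "LQHP", "LQHPT")

KINDS = ("linear", "quadratic", "product", "forward_hinge", "reverse_hinge", "threshold")

# Sample-size interpolation tables for the class base beta
# (piecewise-linear, clamped at the ends).
_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "linear": ((10, 30, 100), (1.0, 0.2, 0.05)),
    "quadratic": ((0, 10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25, 0.05)),
    "product": ((0, 10, 17, 30, 100), (2.6, 1.6, 1.4, 1.0, 0.05)),
    "forward_hinge": ((0, 1), (0.5, 0.5)),
    "reverse_hinge": ((0, 1), (0.5, 0.5)),
    "threshold": ((0, 100), (2.0, 1.0)),
}

#: Floor on the presence-sample feature SD entering the penalty, so that
#: near-constant features keep a nonzero penalty weight.
SD_FLOOR = 1e-3


class ConfigurationError(ValueError):
    """Unknown feature-class code or mismatched layers."""


@dataclass(frozen=True)
class FeatureDef:
    """One feature: its class, source layer index/indices, optional knot."""

    kind: str
    layers: tuple[int, ...]
    knot: float | None = None

    def label(self, names: list[str]) -> str:
        a = names[self.layers[0]]
        if self.kind == "linear":
            return a
        if self.kind == "quadratic":
            return f"{a}^2"
        if self.kind == "product":
            return f"{a}*{names[self.layers[1]]}"
        if self.kind == "forward_hinge":
            return f"hinge({a},{self.knot:.6g})"
        if self.kind == "reverse_hinge":
            return f"revhinge({a},{self.knot:.6g})"
        return f"thresh({a},{self.knot:.6g})"


def default_reg_scale(kind: str, n_presence: int) -> float:
    """Class base beta for the given presence sample size.

    Linear interpolation in the published default tables; hinge classes are
    a constant 0.5, the others decrease with sample size.
    """
    if kind not in _BETA_TABLES:
        raise ConfigurationError(f"unknown feature kind {kind!r}")
    if n_presence < 2:
        raise ValueError("need at least 2 presences")
    xs, ys = _BETA_TABLES[kind]
    return float(np.interp(n_presence, xs, ys))


def _parse_fc(fc: str) -> set[str]:
    letters = set(fc.upper())
    if not letters or not letters.issubset(set("LQPHT")):
        raise ConfigurationError(f"unknown feature-class code {fc!r}")
    return letters


class FeatureSet:
    """Feature definitions plus the background-derived scaling.

    Built once from background layer values; ``transform`` then maps any
    (n_points, n_layers) value matrix to the (n_points, n_features) design
    matrix on the common [0, 1] scale.
    """

    def __init__(
        self,
        layer_names: list[str],
        defs: list[FeatureDef],
        layer_min: np.ndarray,
        layer_max: np.ndarray,
        scale_min: np.ndarray,
        scale_max: np.ndarray,
    ):
        self.layer_names = list(layer_names)
        self.defs = defs
        self.layer_min = np.asarray(layer_min, dtype=float)
        self.layer_max = np.asarray(layer_max, dtype=float)
        self.scale_min = np.asarray(scale_min, dtype=float)
        self.scale_max = np.asarray(scale_max, dtype=float)
        self.reg_scale: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def labels(self) -> list[str]:
        return [d.label(self.layer_names) for d in self.defs]

    @property
    def kinds(self) -> np.ndarray:
        return np.array([d.kind for d in self.defs])

    def variable_of(self) -> list[tuple[int, ...]]:
        """Source layer indices per feature (two for products)."""
        return [d.layers for d in self.defs]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_background(
        cls,
        X_bg: np.ndarray,
        layer_names: list[str],
        fc: str,
        n_knots: int = 50,
    ) -> "FeatureSet":
        """Define features for the class code ``fc`` on background values."""
        X_bg = np.asarray(X_bg, dtype=float)
        if X_bg.ndim != 2 or X_bg.shape[1] != len(layer_names):
            raise ConfigurationError("X_bg must be (n_points, n_layers)")
        letters = _parse_fc(fc)
        nL = len(layer_names)
        lmin = X_bg.min(axis=0)
        lmax = X_bg.max(axis=0)
        defs: list[FeatureDef] = []
        if "L" in letters:
            defs += [FeatureDef("linear", (i,)) for i in range(nL)]
        if "Q" in letters:
            defs += [FeatureDef("quadratic", (i,)) for i in range(nL)]
        if "P" in letters:
            defs += [
                FeatureDef("product", (i, j)) for i in range(nL) for j in range(i + 1, nL)
            ]
        if "H" in letters or "T" in letters:
            qs = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
            for i in range(nL):
                knots = np.unique(np.quantile(X_bg[:, i], qs))
                for k in knots:
                    if "H" in letters:
                        if k < lmax[i]:
                            defs.append(FeatureDef("forward_hinge", (i,), float(k)))
                        if k > lmin[i]:
                            defs.append(FeatureDef("reverse_hinge", (i,), float(k)))
                    if "T" in letters:
                        defs.append(FeatureDef("threshold", (i,), float(k)))
        fs = cls(layer_names, defs, lmin, lmax, np.zeros(len(defs)), np.ones(len(defs)))
        raw = fs._raw(X_bg)
        fs.scale_min = raw.min(axis=0)
        fs.scale_max = raw.max(axis=0)
        return fs

    # -- evaluation --------------------------------------------------------

    def _raw(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.defs)))
        for j, d in enumerate(self.defs):
            i = d.layers[0]
            x = X[:, i]
            if d.kind == "linear":
                out[:, j] = x
            elif d.kind == "quadratic":
                out[:, j] = x * x
            elif d.kind == "product":
                out[:, j] = x * X[:, d.layers[1]]
            elif d.kind == "forward_hinge":
                denom = self.layer_max[i] - d.knot
                out[:, j] = np.maximum(0.0, (x - d.knot) / denom)
            elif d.kind == "reverse_hinge":
                denom = d.knot - self.layer_min[i]
                out[:, j] = np.maximum(0.0, (d.knot - x) / denom)
            else:  # threshold
                out[:, j] = (x > d.knot).astype(float)
        return out

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Design matrix on the [0, 1] training scale.

        ``clamp=True`` (projection) clips each feature to its training
        range before scaling, the standard MaxEnt extrapolation rule.
        """
        F = self._raw(X)
        span = self.scale_max - self.scale_min
        span = np.where(span > 0, span, 1.0)
        F = (F - self.scale_min) / span
        if clamp:
            np.clip(F, 0.0, 1.0, out=F)
        return F

    def reg_scale_for(self, F_presence: np.ndarray) -> np.ndarray:
        """Per-feature penalty weights for a presence design matrix.

        ``reg_scale_j = base(kind, m) * max(sd_j, SD_FLOOR) / sqrt(m)``
        with sd over presence rows of the scaled feature. The fit multiplies
        this by the regularization multiplier RM.
        """
        m = F_presence.shape[0]
        sd = F_presence.std(axis=0, ddof=0)
        base = np.array([default_reg_scale(d.kind, m) for d in self.defs])
        return base * np.maximum(sd, SD_FLOOR) / np.sqrt(m)

    def compute_reg_scale(self, F_presence: np.ndarray) -> np.ndarray:
        """Compute and store :meth:`reg_scale_for` of this presence sample."""
        self.reg_scale = self.reg_scale_for(F_presence)
        return self.reg_scale

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layer_names": self.layer_names,
            "defs": [asdict(d) for d in self.defs],
            "layer_min": self.layer_min.tolist(),
            "layer_max": self.layer_max.tolist(),
            "scale_min": self.scale_min.tolist(),
            "scale_max": self.scale_max.tolist(),
            "reg_scale": None if self.reg_scale is None else self.reg_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        defs = [
            FeatureDef(e["kind"], tuple(e["layers"]), e["knot"]) for e in d["defs"]
        ]
        fs = cls(
            d["layer_names"],
            defs,
            np.array(d["layer_min"]),
            np.array(d["layer_max"]),
            np.array(d["scale_min"]),
            np.array(d["scale_max"]),
        )
        if d.get("reg_scale") is not None:
            fs.reg_scale = np.array(d["reg_scale"])
        return fs


def build_features(
    X_bg: np.ndarray, layer_names: list[str], fc: str, n_knots: int = 50
) -> FeatureSet:
    """Functional wrapper over :meth:`FeatureSet.from_background`."""
    return FeatureSet.from_background(X_bg, layer_names, fc, n_knots=n_knots)
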