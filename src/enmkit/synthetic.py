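"""Synthetic climate-like scenarios with a known suitability truth.

Every pipeline stage in this package is exercised on generated data: a
stack of spatially autocorrelated, partially collinear "climate" layers
(Gaussian random fields smoothed to a chosen correlation length and mixed
to induce known inter-layer correlations), a true suitability surface
built from stated linear/quadratic/hinge responses, presences sampled
proportionally to that surface, and a "future" stack shifted by per-layer
deltas so that range-change and centroid analyses have a known answer.

The default scenario emulates the study conditions of a regional
presence-only analysis: five predictor layers on a 120x120 grid at
2.5 arc-min resolution, an 8-cell autocorrelation length, one strongly
collinear layer pair (r ~ 0.85) to exercise screening, 200 presences, and
a warming-type future shift on a temperature layer that carries a
latitudinal gradient, so warming moves the suitable band poleward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridHeader, Raster, RasterStack
from .occurrences import OccurrenceSet

__all__ = [
    "SyntheticScenario",
    "make_stack",
    "make_truth",
    "sample_occurrences",
    "make_future",
    "default_scenario",
]

CELLSIZE_2P5_ARCMIN = 2.5 / 60.0


def _grf(nrows: int, ncols: int, corr_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field via kernel smoothing of white noise."""
    z = rng.standard_normal((nrows, ncols))
    if corr_length > 0:
        z = gaussian_filter(z, sigma=corr_length, mode="reflect")
    return (z - z.mean()) / z.std()


def make_stack(
    n_layers: int,
    nrows: int = 120,
    ncols: int = 120,
    corr_length_cells: float = 8.0,
    mixing: np.ndarray | None = None,
    seed: int = 0,
    header: GridHeader | None = None,
    layer_names: list[str] | None = None,
    lat_gradient: dict[str, float] | None = None,
) -> RasterStack:
    """Generate a stack of standardized, autocorrelated, mixed layers.

    Independent random fields ``z`` are combined as ``x = M z`` where
    ``M`` is the mixing matrix (identity by default); with unit-norm rows
    the induced inter-layer correlation is ``M M^T``. Each mixed layer is
    re-standardized. ``lat_gradient`` then adds ``g * (lat - lat_mid)``
    to the named layers (units per degree), giving them a deterministic
    south-north trend on top of the field.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    if header is None:
        header = GridHeader(
            ncols=ncols, nrows=nrows, xll=100.0, yll=20.0, cellsize=CELLSIZE_2P5_ARCMIN
        )
    nrows, ncols = header.nrows, header.ncols
    if layer_names is None:
        layer_names = [f"env{i + 1}" for i in range(n_layers)]
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length mismatch")
    M = np.eye(n_layers) if mixing is None else np.asarray(mixing, dtype=float)
    if M.shape != (n_layers, n_layers) or not np.all(np.isfinite(M)):
        raise ValueError("mixing must be a finite (n_layers, n_layers) matrix")
    if np.any(np.linalg.norm(M, axis=1) == 0):
        raise ValueError("mixing has a zero row")
    rng = np.random.default_rng(seed)
    Z = np.stack([_grf(nrows, ncols, corr_length_cells, rng) for _ in range(n_layers)])
    X = np.tensordot(M, Z, axes=(1, 0))
    lat = header.lat_centers()
    lat_mid = float(lat.mean())
    layers: dict[str, Raster] = {}
    for i, name in enumerate(layer_names):
        v = X[i]
        v = (v - v.mean()) / v.std()
        if lat_gradient and name in lat_gradient:
            v = v + lat_gradient[name] * (lat[:, None] - lat_mid)
        layers[name] = Raster(header, v)
    return RasterStack(layers)


def make_truth(
    stack: RasterStack,
    intercept: float = 0.0,
    linear: dict[str, float] | None = None,
    quadratic: dict[str, tuple[float, float]] | None = None,
    hinge: dict[str, tuple[float, float]] | None = None,
) -> Raster:
    """True suitability surface: logistic transform of a stated predictor.

    ``linear[name] = b`` adds ``b*x``; ``quadratic[name] = (b, x0)`` adds
    ``b*(x - x0)^2`` (negative b gives an interior optimum at x0);
    ``hinge[name] = (b, knot)`` adds ``b*max(0, x - knot)``. With no terms
    the truth is uniformly 0.5.
    """
    h = stack.header
    eta = np.full((h.nrows, h.ncols), float(intercept))
    for name, b in (linear or {}).items():
        eta += b * stack[name].values
    for name, (b, x0) in (quadratic or {}).items():
        eta += b * (stack[name].values - x0) ** 2
    for name, (b, knot) in (hinge or {}).items():
        eta += b * np.maximum(0.0, stack[name].values - knot)
    truth = 1.0 / (1.0 + np.exp(-eta))
    return Raster(h, truth, stack.joint_mask())


def sample_occurrences(
    truth: Raster,
    n: int,
    bias: Raster | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw presence cells with probability proportional to the truth.

    Cells are drawn without replacement (at most one record per cell); an
    optional bias field multiplies the sampling weight, emulating uneven
    survey effort. Records sit at cell centers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sel = truth.mask & (truth.values > 0)
    if bias is not None:
        sel &= bias.mask
    rows, cols = np.nonzero(sel)
    if rows.size < n:
        raise ValueError(f"only {rows.size} candidate cells for {n} samples")
    w = truth.values[rows, cols].astype(float)
    if bias is not None:
        w = w * np.maximum(bias.values[rows, cols], 0.0)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=w)
    lon, lat = truth.header.rowcol_to_lonlat(rows[idx], cols[idx])
    names = [f"taxon_{i + 1:04d}" for i in range(n)]
    return OccurrenceSet(names, lon, lat)


def make_future(stack: RasterStack, shift: dict[str, float]) -> RasterStack:
    """Shifted copy of a stack: per-layer additive deltas, same header.

    On a layer with latitudinal gradient ``g`` per degree, a delta of
    ``+d`` moves the iso-lines (and any suitability band tied to them) by
    ``d/g`` degrees against the gradient — e.g. warming pushes a thermal
    band poleward.
    """
    unknown = [k for k in shift if k not in stack]
    if unknown:
        raise KeyError(f"shift names unknown layers: {unknown}")
    layers = {}
    for name in stack.names:
        r = stack[name]
        delta = shift.get(name, 0.0)
        layers[name] = Raster(r.header, r.values + delta, r.mask.copy())
    return RasterStack(layers)


@dataclass
class SyntheticScenario:
    """A generated study system: stack, truth, presences, future stack."""

    stack: RasterStack
    truth: Raster
    occurrences: OccurrenceSet
    future_stack: RasterStack
    future_truth: Raster
    seed: int
    config: dict = field(default_factory=dict)


# Mixing for the default 5-layer stack: unit-norm rows; layer 4 ("wet2")
# duplicates "wet" at r ~ 0.85 to exercise collinearity screening, layer 5
# is weakly tied to temperature.
_DEFAULT_MIXING = np.array(
    [
        [1.0, 0.0, 0.0, 0.0, 0.0],  # temp
        [0.0, 1.0, 0.0, 0.0, 0.0],  # seas
        [0.0, 0.0, 1.0, 0.0, 0.0],  # wet
        [0.0, 0.0, 0.85, np.sqrt(1 - 0.85**2), 0.0],  # wet2 ~ wet
        [0.4, 0.0, 0.0, 0.0, np.sqrt(1 - 0.4**2)],  # topo ~ temp (weak)
    ]
)

DEFAULT_LAYER_NAMES = ["temp", "seas", "wet", "wet2", "topo"]


def default_scenario(seed: int = 42, n_presence: int = 200) -> SyntheticScenario:
    """The package's reference synthetic study system.

    Five layers, 120x120 cells at 2.5 arc-min, correlation length 8 cells.
    ``temp`` carries a -1 unit/degree latitudinal gradient (colder
    northward); the truth has an interior temperature optimum and a
    positive precipitation response:

        eta = 1.0 - 1.2*(temp - 0)^2 + 0.8*wet - 0.5*seas

    The future stack warms ``temp`` by +0.5 units, which translates the
    suitable thermal band ~0.5 degrees poleward (north).
    """
    stack = make_stack(
        5,
        mixing=_DEFAULT_MIXING,
        seed=seed,
        layer_names=DEFAULT_LAYER_NAMES,
        lat_gradient={"temp": -1.0},
    )
    coef = {
        "intercept": 1.0,
        "linear": {"wet": 0.8, "seas": -0.5},
        "quadratic": {"temp": (-1.2, 0.0)},
    }
    truth = make_truth(stack, coef["intercept"], coef["linear"], coef["quadratic"])
    occ = sample_occurrences(truth, n_presence, seed=seed + 1)
    shift = {"temp": 0.5}
    future = make_future(stack, shift)
    future_truth = make_truth(future, coef["intercept"], coef["linear"], coef["quadratic"])
    return SyntheticScenario(
        stack=stack,
        truth=truth,
        occurrences=occ,
        future_stack=future,
        future_truth=future_truth,
        seed=seed,
        config={
            "n_layers": 5,
            "nrows": 120,
            "ncols": 120,
            "corr_length_cells": 8.0,
            "n_presence": n_presence,
            "coefficients": coef,
            "future_shift": shift,
            "lat_gradient": {"temp": -1.0},
        },
    )
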