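"""Spike-train encoding: predict binned spike counts from behavior.

Encoders: the boosted-tree model (:mod:`spikeboost.boost`), a model-based
tuning-curve predictor, and linear least-squares baselines on the raw angle
or its first six harmonics.  Goodness of fit is the deviance-based
pseudo-R2

    pR2 = 1 - [ (y log y - y) - (y log yhat - yhat) ]
            / [ (y log y - y) - (y log ybar - ybar) ]

evaluated with 8-fold cross-validation over contiguous time blocks, and
model complexity is selected on a (n_trees, depth) grid with
BIC = (|trees| + depth) log(n) - 2 log L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .boost import BoostParams, BoostedTrees
from .features import TWO_PI, harmonic_features

__all__ = [
    "CVResult",
    "GridResult",
    "pseudo_r2",
    "crossval_encode",
    "mb_predict",
    "linear_encoder",
    "bic_grid",
    "compare_encoders",
    "boosted_factory",
    "linear_factory",
    "tuning_curve_factory",
]

_FLOOR = 1e-8


def pseudo_r2(y, yhat, ybar) -> float:
    """Deviance pseudo-R2 for Poisson count predictions (0 log 0 = 0).

    1 for a perfect prediction, 0 for the constant mean-rate predictor
    ``ybar``; undefined (raises) when y is constant at ybar.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.any(yhat <= 0) or np.any(np.asarray(ybar) <= 0):
        raise ValueError("predictions and ybar must be > 0")
    if np.any(y < 0):
        raise ValueError("counts must be >= 0")

    def term(pred):
        return np.sum(np.where(y > 0, y * np.log(np.maximum(pred, 1e-300)), 0.0)
                      - pred)

    sat = term(y) if np.all(y > 0) else np.sum(
        np.where(y > 0, y * np.log(np.maximum(y, 1e-300)) - y, 0.0))
    num = sat - term(yhat)
    den = sat - term(np.full_like(y, float(ybar)))
    if den == 0:
        raise ValueError("pseudo-R2 undefined: y is constant at its mean")
    return float(1.0 - num / den)


@dataclass
class CVResult:
    """Per-fold pseudo-R2 scores for one encoder."""

    fold_scores: np.ndarray
    model: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))


def _fold_slices(n: int, k: int):
    """k contiguous, disjoint, exhaustive time blocks."""
    if n < k:
        raise ValueError("fewer samples than folds")
    bounds = np.linspace(0, n, k + 1).astype(int)
    return [(bounds[i], bounds[i + 1]) for i in range(k)]


def crossval_encode(X, y, model_factory, k: int = 8, model: str = "") -> CVResult:
    """8-fold cross-validated pseudo-R2 over contiguous time blocks.

    ``model_factory(X_train, y_train)`` must return an object with a
    ``predict(X_test) -> rates`` method.  Each fold's ybar is the mean of
    that fold's training targets.
    """
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] != np.asarray(y).size:
        X = X.T
    y = np.asarray(y, dtype=float)
    scores = []
    for lo, hi in _fold_slices(y.size, k):
        test = np.zeros(y.size, dtype=bool)
        test[lo:hi] = True
        fitted = model_factory(X[~test], y[~test])
        yhat = np.maximum(np.asarray(fitted.predict(X[test]), dtype=float), _FLOOR)
        ybar = max(float(y[~test].mean()), _FLOOR)
        scores.append(pseudo_r2(y[test], yhat, ybar))
    return CVResult(np.asarray(scores), model)


# ---------------------------------------------------------------------------
# encoders


def boosted_factory(params: BoostParams | None = None):
    """Factory for the boosted Poisson encoder (default 100 trees, depth 5)."""
    def make(X, y):
        return BoostedTrees(y, X, params=params or BoostParams()).fit()
    return make


class _LinearEncoder:
    """OLS on counts with intercept; predictions floored at 1e-8."""

    def __init__(self, X, y):
        A = np.column_stack([np.ones(len(y)), X])
        self.coef, *_ = np.linalg.lstsq(A, y, rcond=None)

    def predict(self, X):
        A = np.column_stack([np.ones(X.shape[0]), X])
        return np.maximum(A @ self.coef, _FLOOR)


def linear_encoder(X, y):
    """Fit the least-squares linear encoder; returns a fitted predictor."""
    return _LinearEncoder(np.atleast_2d(np.asarray(X, dtype=float)), np.asarray(y, dtype=float))


def linear_factory(harmonic_order: int | None = None):
    """Linear OLS encoder factory; if ``harmonic_order`` is given the single
    angle column is expanded into [cos k0, sin k0] features first."""
    def make(X, y):
        if harmonic_order:
            X = harmonic_features(np.asarray(X).ravel(), harmonic_order)
        return linear_encoder(X, y)

    if harmonic_order:
        class _Wrapped:
            def __init__(self, X, y):
                self.inner = make(X, y)

            def predict(self, X):
                return self.inner.predict(
                    harmonic_features(np.asarray(X).ravel(), harmonic_order))
        return _Wrapped
    return make


class _TuningCurveEncoder:
    """Model-based predictor: 60-bin tuning curve estimated on the training
    angles/counts, evaluated at the test angles (piecewise constant)."""

    def __init__(self, angles, y, n_bins: int = 60):
        self.n_bins = n_bins
        b = np.floor(np.mod(angles, TWO_PI) / (TWO_PI / n_bins)).astype(int) % n_bins
        spk = np.bincount(b, weights=y, minlength=n_bins)
        occ = np.bincount(b, minlength=n_bins).astype(float)
        self.expected = np.divide(spk, occ, out=np.zeros(n_bins), where=occ > 0)

    def predict(self, angles):
        b = np.floor(np.mod(np.asarray(angles).ravel(), TWO_PI)
                     / (TWO_PI / self.n_bins)).astype(int) % self.n_bins
        return np.maximum(self.expected[b], _FLOOR)


def tuning_curve_factory(n_bins: int = 60):
    def make(X, y):
        return _TuningCurveEncoder(np.asarray(X).ravel(), y, n_bins)
    return make


def mb_predict(train_session, test_angles, neuron: int, n_bins: int = 60,
               epoch=None, bin_width: float = 0.025) -> np.ndarray:
    """Model-based prediction: the neuron's tuning curve is estimated on the
    training session, then read out at each test angle and converted to an
    expected count per ``bin_width`` bin (floored at 1e-8)."""
    from .features import behavior_matrix, bin_spikes, tuning_curve

    curve = tuning_curve(train_session, neuron, n_bins, epoch, bin_width)
    b = np.floor(np.mod(np.asarray(test_angles), TWO_PI) / (TWO_PI / n_bins)).astype(int) % n_bins
    return np.maximum(curve.rate[b] * bin_width, _FLOOR)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class GridResult:
    """BIC grid over (n_trees, depth)."""

    tree_grid: np.ndarray
    depth_grid: np.ndarray
    bic: np.ndarray          # (len(tree_grid), len(depth_grid))
    mean_pr2: np.ndarray
    best: tuple = (0, 0)     # (n_trees, depth) at the BIC argmin

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, t in enumerate(self.tree_grid):
            for j, d in enumerate(self.depth_grid):
                rows.append({"n_trees": t, "depth": d, "bic": self.bic[i, j],
                             "mean_pr2": self.mean_pr2[i, j]})
        return pd.DataFrame(rows)


def bic_grid(X, y, tree_grid, depth_grid, k: int = 8,
             base_params: BoostParams | None = None) -> GridResult:
    """Grid search over (n_trees, depth) scored by
    BIC = (|trees| + depth) log(n) - 2 log L, with log L the Poisson
    log-likelihood of the cross-validated (held-out) predictions.

    Ties at the argmin go to the smallest n_trees, then smallest depth.
    """
    tree_grid = np.asarray(list(tree_grid), dtype=int)
    depth_grid = np.asarray(list(depth_grid), dtype=int)
    if tree_grid.size == 0 or depth_grid.size == 0:
        raise ValueError("empty grid")
    y = np.asarray(y, dtype=float)
    n = y.size
    base = base_params or BoostParams()
    bic = np.empty((tree_grid.size, depth_grid.size))
    pr2 = np.empty_like(bic)
    for i, n_trees in enumerate(tree_grid):
        for j, depth in enumerate(depth_grid):
            params = BoostParams(n_trees=int(n_trees), max_depth=int(depth),
                                 gamma=base.gamma, lam=base.lam, eta=base.eta,
                                 leaf_cap=base.leaf_cap, seed=base.seed)
            yhat = _cv_predictions(X, y, params, k)
            logl = float(np.sum(y * np.log(yhat) - yhat - gammaln(y + 1.0)))
            bic[i, j] = (n_trees + depth) * np.log(n) - 2.0 * logl
            ps = []
            for lo, hi in _fold_slices(n, k):
                test = np.zeros(n, dtype=bool)
                test[lo:hi] = True
                ybar = max(float(y[~test].mean()), _FLOOR)
                ps.append(pseudo_r2(y[test], yhat[test], ybar))
            pr2[i, j] = float(np.mean(ps))
    flat = np.argmin(bic)  # row-major: smallest tree count wins ties, then depth
    i, j = np.unravel_index(flat, bic.shape)
    return GridResult(tree_grid, depth_grid, bic, pr2,
                      (int(tree_grid[i]), int(depth_grid[j])))


def _cv_predictions(X, y, params: BoostParams, k: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] != y.size:
        X = X.T
    yhat = np.empty(y.size)
    for lo, hi in _fold_slices(y.size, k):
        test = np.zeros(y.size, dtype=bool)
        test[lo:hi] = True
        res = BoostedTrees(y[~test], X[~test], params=params).fit()
        yhat[test] = res.predict(X[test])
    return np.maximum(yhat, _FLOOR)


def compare_encoders(angles, y, k: int = 8,
                     xgb_params: BoostParams | None = None,
                     harmonic_order: int = 6) -> dict:
    """Cross-validated comparison of the four encoders on one neuron.

    ``angles`` is the per-bin head direction, ``y`` the (possibly smoothed)
    spike count per bin.  Returns {"xgb", "mb", "linear", "linear-harmonic"}
    -> CVResult, all sharing the same contiguous fold geometry.
    """
    angles = np.asarray(angles, dtype=float).reshape(-1, 1)
    out = {
        "xgb": crossval_encode(angles, y, boosted_factory(xgb_params), k, "xgb"),
        "mb": crossval_encode(angles, y, tuning_curve_factory(), k, "mb"),
        "linear": crossval_encode(angles, y, linear_factory(), k, "linear"),
        "linear-harmonic": crossval_encode(
            angles, y, linear_factory(harmonic_order), k, "linear-harmonic"),
    }
    return out
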