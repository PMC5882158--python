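"""Head-direction decoding from population spike counts.

Two decoders over 60 angular classes: the classical Bayesian decoder
(independent Poisson neurons, tuning-curve likelihood

    P(n | phi) = prod_i (tau f_i(phi))^{n_i} e^{-tau f_i(phi)} / n_i!

computed in log space with a uniform prior by default), and a multiclass
softmax boosted-tree decoder.  Decoding bins are 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .boost import BoostParams, BoostedTrees
from .features import TWO_PI, TuningCurve

__all__ = [
    "Posterior",
    "bayes_decode",
    "xgb_decode",
    "multiclass_logloss",
    "circular_error",
    "crossval_decode",
    "angle_to_class",
]

_RATE_FLOOR = 1e-3  # Hz; keeps log-likelihoods finite with observed spikes


@dataclass
class Posterior:
    """Per-time-bin probability over angular classes."""

    probs: np.ndarray        # (n_bins, n_classes), rows sum to 1
    bin_centers: np.ndarray  # angular class centers (rad)
    flagged: np.ndarray | None = None  # rows that fell back to uniform

    @property
    def decoded_angle(self) -> np.ndarray:
        return self.bin_centers[np.argmax(self.probs, axis=1)]

    @property
    def decoded_class(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)


def angle_to_class(angles, n_classes: int = 60) -> np.ndarray:
    """Map angles to the index of their angular bin in [0, n_classes)."""
    a = np.mod(np.asarray(angles, dtype=float), TWO_PI)
    return (np.floor(a / (TWO_PI / n_classes)).astype(int)) % n_classes


def _class_centers(n_classes: int) -> np.ndarray:
    return (np.arange(n_classes) + 0.5) * TWO_PI / n_classes


def _curve_rates(curves, n_classes: int) -> np.ndarray:
    """(n_classes, n_neurons) rate matrix from tuning curves (Hz, floored)."""
    cols = []
    for c in curves:
        if isinstance(c, TuningCurve):
            if c.n_bins != n_classes:
                raise ValueError("tuning curve bin count != n_classes")
            cols.append(c.rate)
        else:
            cols.append(np.asarray(c, dtype=float))
    F = np.column_stack(cols)
    return np.maximum(F, _RATE_FLOOR)


def bayes_decode(counts, curves, tau: float = 0.2, prior=None,
                 n_classes: int = 60) -> Posterior:
    """Bayesian population decoding of the head direction.

    counts: (n_bins, n_neurons) spike counts in ``tau``-second windows.
    curves: per-neuron TuningCurve (or rate vectors over the angular
    classes).  Likelihoods are evaluated in log space and normalized with
    the prior (uniform by default); rows whose likelihood underflows
    everywhere fall back to the prior and are flagged.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    F = _curve_rates(curves, n_classes)            # (K, N)
    if F.shape[1] != counts.shape[1]:
        raise ValueError("neuron count mismatch between counts and curves")
    logF = np.log(tau * F)                         # (K, N)
    # log P(n | phi) up to the n! term (constant per row)
    loglik = counts @ logF.T - (tau * F).sum(axis=1)[None, :]
    if prior is None:
        logprior = np.zeros(n_classes)
    else:
        prior = np.asarray(prior, dtype=float)
        logprior = np.log(np.maximum(prior / prior.sum(), 1e-300))
    logpost = loglik + logprior[None, :]
    bad = ~np.isfinite(logpost).any(axis=1)
    norm = logsumexp(logpost, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.exp(logpost - norm)
    if bad.any():
        probs[bad] = np.exp(logprior - logsumexp(logprior))
    return Posterior(probs, _class_centers(n_classes), flagged=bad if bad.any() else None)


_DECODER_PARAMS = dict(n_trees=30, max_depth=3)


def xgb_decode(counts, labels, test_counts=None, params: BoostParams | None = None,
               n_classes: int = 60) -> Posterior:
    """Multiclass boosted-tree decoding.

    Fits the softmax-objective model on (counts, labels) and returns the
    posterior over angular classes for ``test_counts`` (the training counts
    if omitted).  Classes absent from training are flagged.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels out of range")
    if params is None:
        params = BoostParams(objective="softmax", n_classes=n_classes,
                             **_DECODER_PARAMS)
    res = BoostedTrees(labels, np.asarray(counts), params=params).fit()
    X = counts if test_counts is None else test_counts
    probs = res.predict(np.asarray(X))
    probs = np.clip(probs, 1e-15, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)
    absent = np.setdiff1d(np.arange(n_classes), np.unique(labels))
    flagged = None
    if absent.size:
        flagged = np.zeros(probs.shape[0], dtype=bool)  # model-level flag
    return Posterior(probs, _class_centers(n_classes), flagged=flagged)


def multiclass_logloss(posterior: Posterior | np.ndarray, true_labels) -> float:
    """Mean multiclass log loss; 0 for a perfect one-hot posterior."""
    probs = posterior.probs if isinstance(posterior, Posterior) else np.asarray(posterior)
    labels = np.asarray(true_labels, dtype=int)
    if probs.shape[0] != labels.size:
        raise ValueError("shape mismatch")
    p = np.clip(probs[np.arange(labels.size), labels], 1e-15, 1.0)
    return float(-np.mean(np.log(p)))


def circular_error(decoded, true):
    """Absolute circular difference per bin, in [0, pi]."""
    d = np.abs(np.mod(np.asarray(decoded, dtype=float)
                      - np.asarray(true, dtype=float), TWO_PI))
    return np.minimum(d, TWO_PI - d)


@dataclass
class DecodeCV:
    """Cross-validated decoding performance."""

    errors: np.ndarray        # per-bin circular error (rad), concatenated
    logloss: float
    method: str = ""

    @property
    def median_error(self) -> float:
        return float(np.median(self.errors))


def crossval_decode(counts, angles, method: str = "bayes", tau: float = 0.2,
                    n_classes: int = 60, k: int = 8,
                    params: BoostParams | None = None) -> DecodeCV:
    """8-fold cross-validated decoding over contiguous time blocks.

    For the Bayesian decoder, each fold's tuning curves are estimated from
    that fold's training bins only (training spike count per class divided
    by training occupancy of the class).
    """
    counts = np.atleast_2d(np.asarray(counts))
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    labels = angle_to_class(angles, n_classes)
    bounds = np.linspace(0, n, k + 1).astype(int)
    errs, losses, weights = [], [], []
    for i in range(k):
        test = np.zeros(n, dtype=bool)
        test[bounds[i]:bounds[i + 1]] = True
        if method == "bayes":
            F = _rates_from_counts(counts[~test], labels[~test], tau, n_classes)
            post = bayes_decode(counts[test], list(F.T), tau, n_classes=n_classes)
        elif method == "xgb":
            post = xgb_decode(counts[~test], labels[~test], counts[test],
                              params=params, n_classes=n_classes)
        else:
            raise ValueError(f"unknown method {method!r}")
        errs.append(circular_error(post.decoded_angle, angles[test]))
        losses.append(multiclass_logloss(post, labels[test]))
        weights.append(test.sum())
    return DecodeCV(np.concatenate(errs),
                    float(np.average(losses, weights=weights)), method)


def _rates_from_counts(counts, labels, tau, n_classes) -> np.ndarray:
    """(n_classes, n_neurons) empirical rates from labelled count bins."""
    K = n_classes
    occ = np.bincount(labels, minlength=K).astype(float) * tau
    F = np.zeros((K, counts.shape[1]))
    for j in range(counts.shape[1]):
        spk = np.bincount(labels, weights=counts[:, j], minlength=K)
        np.divide(spk, occ, out=F[:, j], where=occ > 0)
    return np.maximum(F, _RATE_FLOOR)
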