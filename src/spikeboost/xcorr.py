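"""Linear baselines: cross-correlograms and profile statistics.

Pairwise spike-train cross-correlograms (default 5 ms bins, +-500 ms),
their centered standard-deviation profile across pairs, exponential-decay
fits, full width at half maximum, and PCA over collections of
correlograms.  These are the classical analyses against which the
tree-gain lag profiles are contrasted: correlogram widths track the
dynamics of the underlying behavioral signal, while the boosted-tree lag
gains track only the synaptic transmission delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Correlogram",
    "cross_correlogram",
    "std_profile",
    "exp_decay_fit",
    "fwhm",
    "center_of_mass",
    "lag_asymmetry",
    "pca_correlograms",
    "ExpFit",
    "PCAResult",
]


@dataclass
class Correlogram:
    """Values over a symmetric lag grid; positive lag = b after a."""

    lags: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    flagged: bool = False


def cross_correlogram(train_a, train_b, bin: float = 0.005,
                      max_lag: float = 0.5, normalize: str = "rate") -> Correlogram:
    """Histogram of b-spike times relative to each a-spike.

    normalize: "raw" counts, "rate" (Hz: counts / (n_a * bin)), or
    "zscore" (per-lag z-score against the correlogram's own mean/std).
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    n_half = int(round(max_lag / bin))
    if abs(n_half * bin - max_lag) > 1e-9:
        raise ValueError("max_lag must be a multiple of bin")
    lags = np.arange(-n_half, n_half + 1) * bin
    ta = np.sort(np.asarray(train_a, dtype=float))
    tb = np.sort(np.asarray(train_b, dtype=float))
    if ta.size == 0 or tb.size == 0:
        return Correlogram(lags, np.zeros(lags.size), normalize, flagged=True)
    half = bin / 2.0
    lo = np.searchsorted(tb, ta - max_lag - half, side="left")
    hi = np.searchsorted(tb, ta + max_lag + half, side="right")
    lengths = hi - lo
    total = int(lengths.sum())
    if total == 0:
        counts = np.zeros(lags.size)
    else:
        offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        flat = np.arange(total)
        idx_b = flat - np.repeat(offsets, lengths) + np.repeat(lo, lengths)
        diffs = tb[idx_b] - np.repeat(ta, lengths)
        edges = np.arange(-n_half, n_half + 2) * bin - half
        counts, _ = np.histogram(diffs, bins=edges)
        counts = counts.astype(float)
    if normalize == "raw":
        vals = counts
    elif normalize == "rate":
        vals = counts / (ta.size * bin)
    elif normalize == "zscore":
        sd = counts.std()
        vals = (counts - counts.mean()) / sd if sd > 0 else counts - counts.mean()
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return Correlogram(lags, vals, normalize)


def _stack(correlograms):
    lags = np.asarray(correlograms[0].lags)
    rows = []
    for c in correlograms:
        if c.lags.size != lags.size or not np.allclose(c.lags, lags):
            raise ValueError("correlograms are not on a shared lag grid")
        rows.append(c.values)
    return lags, np.vstack(rows)


def std_profile(correlograms) -> Correlogram:
    """Per-lag standard deviation across pairs after subtracting each
    correlogram's own mean (centering)."""
    if len(correlograms) < 2:
        raise ValueError("need at least 2 correlograms")
    lags, M = _stack(correlograms)
    M = M - M.mean(axis=1, keepdims=True)
    return Correlogram(lags, M.std(axis=0), "std")


@dataclass
class ExpFit:
    amplitude: float
    time_constant: float
    offset: float
    center: float
    success: bool
    residual: float


def exp_decay_fit(profile: Correlogram | np.ndarray, lags=None) -> ExpFit:
    """Least-squares fit of A exp(-|lag - lag0| / tau) + c to a profile."""
    if isinstance(profile, Correlogram):
        lags, vals = profile.lags, profile.values
    else:
        vals = np.asarray(profile, dtype=float)
        lags = np.asarray(lags, dtype=float)
    if vals.max() <= vals.min():
        return ExpFit(0.0, np.nan, float(vals.mean()), 0.0, False,
                      float(np.sum((vals - vals.mean()) ** 2)))

    def model(x, A, x0, tau, c):
        return A * np.exp(-np.abs(x - x0) / tau) + c

    p0 = [vals.max() - vals.min(), float(lags[np.argmax(vals)]),
          max((lags[-1] - lags[0]) / 10.0, 1e-3), float(vals.min())]
    try:
        popt, _ = curve_fit(model, lags, vals, p0=p0,
                            bounds=([0, lags[0], 1e-6, -np.inf],
                                    [np.inf, lags[-1], np.inf, np.inf]),
                            maxfev=20000)
        resid = float(np.sum((model(lags, *popt) - vals) ** 2))
        return ExpFit(float(popt[0]), float(popt[2]), float(popt[3]),
                      float(popt[1]), True, resid)
    except RuntimeError:
        return ExpFit(np.nan, np.nan, np.nan, np.nan, False,
                      float(np.sum((vals - vals.mean()) ** 2)))


def fwhm(profile: Correlogram | np.ndarray, lags=None) -> float:
    """Full width at half maximum above baseline (= profile minimum), with
    linear interpolation at the crossings.  NaN if the half level is never
    crossed on either side of the peak."""
    if isinstance(profile, Correlogram):
        lags, vals = profile.lags, profile.values
    else:
        vals = np.asarray(profile, dtype=float)
        lags = np.asarray(lags, dtype=float)
    baseline = vals.min()
    peak = vals.max()
    if peak <= baseline:
        return np.nan
    half = 0.5 * (peak + baseline)
    ip = int(np.argmax(vals))

    def crossing(direction):
        i = ip
        while 0 <= i + direction < vals.size:
            j = i + direction
            if vals[j] < half:
                # interpolate between i and j
                frac = (vals[i] - half) / (vals[i] - vals[j])
                return lags[i] + frac * (lags[j] - lags[i])
            i = j
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return np.nan
    return float(right - left)


def center_of_mass(profile: Correlogram | np.ndarray, lags=None) -> float:
    """Baseline-subtracted center of mass of a profile, in lag units."""
    if isinstance(profile, Correlogram):
        lags, vals = profile.lags, profile.values
    else:
        vals = np.asarray(profile, dtype=float)
        lags = np.asarray(lags, dtype=float)
    w = vals - vals.min()
    if w.sum() <= 0:
        return np.nan
    return float(np.sum(w * lags) / np.sum(w))


def lag_asymmetry(profile: Correlogram | np.ndarray, lags=None) -> float:
    """Signed asymmetry of a profile's mass about zero lag:
    (sum over negative lags - sum over positive lags) / total.

    Positive values mean the profile's center of mass sits at negative
    lags.  This is the robust readout of the integration-constant bias in
    correlogram variance profiles: a symmetric noise pedestal cancels,
    while a one-sided shoulder does not.
    """
    if isinstance(profile, Correlogram):
        lags, vals = profile.lags, profile.values
    else:
        vals = np.asarray(profile, dtype=float)
        lags = np.asarray(lags, dtype=float)
    total = vals.sum()
    if total <= 0:
        return np.nan
    return float((vals[lags < 0].sum() - vals[lags > 0].sum()) / total)


@dataclass
class PCAResult:
    scores: np.ndarray            # (n_correlograms, 2)
    explained_variance: np.ndarray
    group_means: dict
    group_covs: dict
    degenerate: bool = False


def pca_correlograms(correlograms, groups=None) -> PCAResult:
    """Project z-scored correlograms on their top-2 principal components,
    with a Gaussian (mean, covariance) fit per group."""
    if len(correlograms) < 3:
        raise ValueError("need at least 3 correlograms")
    _, M = _stack(correlograms)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    degenerate = bool(np.all(sd == 0))
    Z = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1][:2]
    comp = evecs[:, order]
    scores = Z @ comp
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(scores.shape[0])])
    means, covs = {}, {}
    if groups is not None:
        groups = np.asarray(groups)
        for gname in np.unique(groups):
            sel = scores[groups == gname]
            means[gname] = sel.mean(axis=0)
            covs[gname] = np.cov(sel, rowvar=False) if sel.shape[0] > 1 else np.zeros((2, 2))
    return PCAResult(scores, evals[order], means, covs, degenerate)
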