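"""Peer-prediction and lag-stacked transmission-delay inference.

A target neuron's binned spike count is predicted from the simultaneous
counts of an ensemble of feature neurons (within or between regions).  For
directed-delay inference the design is "lag-stacked": each feature neuron
contributes one column per time lag in [-T, +T] (raw, unsmoothed counts),
and the fitted trees' per-lag gain (number of splits x mean gain,
aggregated over neurons) forms a profile whose peak reads out the
transmission delay — a feature at lag -d predicts the target best when the
feature population drives the target d seconds later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boost import BoostParams, BoostedTrees, BoostedTreesResults
from .encoding import CVResult, boosted_factory, crossval_encode
from .features import BinnedCounts
from .xcorr import fwhm as _fwhm

__all__ = [
    "LagDesign",
    "GainProfile",
    "peer_design",
    "lag_design",
    "peer_score",
    "equalize_groups",
    "gain_profile",
    "split_stats_by_neuron",
    "INTERPRETATION_PARAMS",
    "SCORING_PARAMS",
]

# two regimes: few shallow trees for structure interpretation,
# many deeper trees for raw predictive scoring
INTERPRETATION_PARAMS = dict(n_trees=30, max_depth=2)
SCORING_PARAMS = dict(n_trees=100, max_depth=5)


@dataclass
class LagDesign:
    """Layout of a lag-stacked feature matrix."""

    lags: np.ndarray          # offsets in seconds, ascending, step = bin width
    neurons: np.ndarray       # feature neuron ids (column-major over lags)
    bin_width: float
    col_neuron: np.ndarray    # per-column feature neuron id
    col_lag: np.ndarray       # per-column lag (s)

    @property
    def n_columns(self) -> int:
        return self.col_neuron.size


def _values(binned: BinnedCounts, smoothed: bool):
    if smoothed and binned.smoothed is not None:
        return binned.smoothed
    return binned.counts


def peer_design(binned: BinnedCounts, target_neuron: int, feature_group,
                exclude_target: bool = True, smoothed: bool = True):
    """Synchronous peer-prediction design: y is the target's counts, X the
    counts of the feature group in the same bins.

    For intra-group prediction the target must be excluded from the pool
    (passing it with ``exclude_target=False`` is an error).
    """
    feature_group = list(feature_group)
    if target_neuron in feature_group:
        if not exclude_target:
            raise ValueError("target neuron is in the feature group; "
                             "set exclude_target=True")
        feature_group = [n for n in feature_group if n != target_neuron]
    if not feature_group:
        raise ValueError("empty feature group after excluding the target")
    vals = _values(binned, smoothed)
    X = vals[:, feature_group]
    y = vals[:, target_neuron]
    return X, y


def lag_design(binned: BinnedCounts, target_neuron: int, feature_group,
               max_lag: float, step: float | None = None,
               exclude_target: bool = True):
    """Lag-stacked design from raw, unsmoothed counts.

    Each feature neuron contributes one column per lag in
    ``-max_lag..+max_lag`` (step = bin width): the column at lag ``l``
    holds that neuron's count at ``t + l``.  Edge bins are dropped so all
    columns are fully defined.  Returns (X, y, LagDesign) with X keeping
    integer dtype.
    """
    step = binned.bin_width if step is None else step
    if abs(step - binned.bin_width) > 1e-9:
        raise ValueError("step must equal the bin width")
    n_half = int(round(max_lag / step))
    if abs(n_half * step - max_lag) > 1e-9:
        raise ValueError("max_lag must be a multiple of step")
    feature_group = [n for n in feature_group if not (exclude_target and n == target_neuron)]
    if target_neuron in feature_group:
        raise ValueError("target neuron is in the feature group")
    if not feature_group:
        raise ValueError("empty feature group")
    counts = binned.counts
    T = counts.shape[0]
    if T <= 2 * n_half + 1:
        raise ValueError("max_lag too large for the session")
    lag_bins = np.arange(-n_half, n_half + 1)
    valid = slice(n_half, T - n_half)
    cols, col_neuron, col_lag = [], [], []
    for n in feature_group:
        for lb in lag_bins:
            cols.append(counts[n_half + lb: T - n_half + lb, n])
            col_neuron.append(n)
            col_lag.append(lb * step)
    X = np.column_stack(cols)
    y = counts[valid, target_neuron]
    design = LagDesign(lag_bins * step, np.asarray(feature_group),
                       step, np.asarray(col_neuron), np.asarray(col_lag))
    return X, y, design


def peer_score(X, y, params: BoostParams | None = None, k: int = 8) -> CVResult:
    """8-fold cross-validated pseudo-R2 of the boosted encoder on a peer
    design (default scoring regime: 100 trees, depth 5)."""
    if params is None:
        params = BoostParams(**SCORING_PARAMS)
    return crossval_encode(X, y, boosted_factory(params), k, "peer-xgb")


def equalize_groups(groups, seed: int = 0):
    """Trim every group to the smallest group's size by seeded uniform
    subsampling without replacement.  Accepts a dict name -> ids or a list
    of id sequences, returned in the same form."""
    rng = np.random.default_rng(seed)
    items = list(groups.items()) if isinstance(groups, dict) else list(enumerate(groups))
    sizes = [len(v) for _, v in items]
    if min(sizes) < 1:
        raise ValueError("every group needs at least 1 neuron")
    m = min(sizes)
    out = {}
    for key, ids in items:
        ids = np.asarray(list(ids))
        if ids.size > m:
            ids = np.sort(rng.choice(ids, size=m, replace=False))
        out[key] = ids
    return out if isinstance(groups, dict) else [out[i] for i in range(len(items))]


@dataclass
class GainProfile:
    """Per-lag total gain (n_splits x mean gain summed over neurons)."""

    lags: np.ndarray
    gain: np.ndarray
    n_splits: np.ndarray
    flagged: bool = False

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.gain))])

    @property
    def fwhm(self) -> float:
        return _fwhm(self.gain, self.lags)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag": self.lags, "gain": self.gain,
                             "n_splits": self.n_splits})

    def plot(self, ax=None, **kwargs):
        """Gain vs lag (ms), peak marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags * 1000, self.gain, marker="o", **kwargs)
        ax.axvline(self.peak_lag * 1000, ls="--", color="k", alpha=0.5)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("gain (n_splits x mean gain)")
        return ax


def gain_profile(results: BoostedTreesResults, design: LagDesign) -> GainProfile:
    """Aggregate the fitted model's per-feature gain over neurons, per lag.

    The model should have been fitted on the lag design with the
    interpretation regime (30 trees, depth 2).  An all-zero profile has no
    defined peak and is flagged.
    """
    gs = results.gain_summary()
    total = gs["total_gain"].to_numpy()
    nsp = gs["n_splits"].to_numpy()
    if total.size != design.n_columns:
        raise ValueError("model was not fitted on this design")
    lags = design.lags
    gain = np.zeros(lags.size)
    splits = np.zeros(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        sel = np.isclose(design.col_lag, lag)
        gain[i] = total[sel].sum()
        splits[i] = nsp[sel].sum()
    return GainProfile(lags, gain, splits, flagged=bool(gain.max() == 0))


def fit_gain_profile(binned: BinnedCounts, target_neuron: int, feature_group,
                     max_lag: float = 0.2,
                     params: BoostParams | None = None) -> GainProfile:
    """Convenience: build the lag design, fit the interpretation-regime
    model, and return its gain profile."""
    X, y, design = lag_design(binned, target_neuron, feature_group, max_lag)
    if params is None:
        params = BoostParams(**INTERPRETATION_PARAMS)
    res = BoostedTrees(y, X, params=params).fit()
    return gain_profile(res, design)


def split_stats_by_neuron(results: BoostedTreesResults, feature_neurons,
                          curves, target_curve, mean_rates=None):
    """Per-feature-neuron split statistics for a synchronous peer model.

    Returns a DataFrame with the neuron id, number of splits, total gain,
    circular distance between the neuron's preferred direction and the
    target's (in [0, pi]), and its mean firing rate.
    """
    import pandas as pd

    gs = results.gain_summary()
    feature_neurons = np.asarray(list(feature_neurons))
    if len(gs) != feature_neurons.size:
        raise ValueError("one column per feature neuron expected")
    pd_target = target_curve.preferred_direction
    dist, rates = [], []
    for i, n in enumerate(feature_neurons):
        p = curves[i].preferred_direction
        d = abs((p - pd_target + np.pi) % (2 * np.pi) - np.pi)
        dist.append(d)
        if mean_rates is not None:
            rates.append(mean_rates[i])
        else:
            c = curves[i]
            occ = np.asarray(c.occupancy, dtype=float)
            rates.append(float(np.average(c.rate, weights=occ)
                               if occ.sum() > 0 else c.rate.mean()))
    return pd.DataFrame({
        "neuron": feature_neurons,
        "n_splits": gs["n_splits"].to_numpy(),
        "total_gain": gs["total_gain"].to_numpy(),
        "angular_distance": dist,
        "mean_rate": rates,
    })
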