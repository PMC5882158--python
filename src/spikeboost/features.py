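"""Sessions, spike binning, tuning curves and Fisher information.

A :class:`Session` bundles per-neuron spike times with behavioral tracking
(head direction angle, x/y position) and named brain-state epochs
(wake / rem / nonrem).  Analyses operate on spike counts binned at 25 ms
(decoding uses 200 ms) and optionally smoothed with a 125 ms Gaussian
kernel; head-direction tuning curves use 60 angular bins over [0, 2pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Session",
    "BinnedCounts",
    "TuningCurve",
    "bin_spikes",
    "smooth_counts",
    "tuning_curve",
    "fisher_information",
    "harmonic_features",
    "behavior_matrix",
]

TWO_PI = 2.0 * np.pi


@dataclass
class Session:
    """Spike trains + tracking + epochs for one recording (or simulation).

    spike_times: per-neuron arrays of spike times (s), non-decreasing.
    tracking_times / angle / x / y: behavioral samples; angle in [0, 2pi).
    epochs: state name -> (n, 2) array of [start, end) intervals (s).
    regions: per-neuron anatomical label (e.g. "ADn", "PoSub").
    ground_truth: optional dict with simulator-provided truth (preferred
    directions, weights, trajectory) for validation work.
    """

    spike_times: list
    tracking_times: np.ndarray
    angle: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    epochs: dict = field(default_factory=dict)
    regions: list = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = [np.sort(np.asarray(st, dtype=float)) for st in self.spike_times]
        self.tracking_times = np.asarray(self.tracking_times, dtype=float)
        self.angle = np.mod(np.asarray(self.angle, dtype=float), TWO_PI)
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if not self.regions:
            self.regions = ["other"] * len(self.spike_times)
        self.epochs = {k: np.atleast_2d(np.asarray(v, dtype=float))
                       for k, v in self.epochs.items()}
        if not self.epochs:
            t0 = float(self.tracking_times[0]) if self.tracking_times.size else 0.0
            t1 = float(self.tracking_times[-1]) if self.tracking_times.size else 0.0
            self.epochs = {"wake": np.array([[t0, t1]])}

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def neurons_in(self, region: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.regions) if r == region],
                        dtype=int)

    def epoch_intervals(self, epoch) -> np.ndarray:
        if epoch is None:
            return next(iter(self.epochs.values()))
        if isinstance(epoch, str):
            if epoch not in self.epochs:
                raise KeyError(f"unknown epoch {epoch!r}")
            return self.epochs[epoch]
        return np.atleast_2d(np.asarray(epoch, dtype=float))


@dataclass
class BinnedCounts:
    """Time-binned spike counts, bins x neurons, with half-open bins."""

    bin_edges: list          # one edge array per epoch interval
    centers: np.ndarray      # absolute bin-center times, concatenated
    counts: np.ndarray       # (n_bins, n_neurons) integer counts
    bin_width: float
    smoothed: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def rates(self) -> np.ndarray:
        """Smoothed firing rate in Hz (falls back to raw counts / width)."""
        base = self.counts if self.smoothed is None else self.smoothed
        return base / self.bin_width


@dataclass
class TuningCurve:
    """60-bin angular firing-rate map: rate (Hz) and occupancy (s) per bin."""

    bin_centers: np.ndarray
    rate: np.ndarray
    occupancy: np.ndarray
    zero_occupancy: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def preferred_direction(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.rate))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"bin_center": self.bin_centers, "rate": self.rate,
                             "occupancy": self.occupancy})

    def plot(self, ax=None, **kwargs):
        """Polar plot of the tuning curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        th = np.append(self.bin_centers, self.bin_centers[0])
        r = np.append(self.rate, self.rate[0])
        ax.plot(th, r, **kwargs)
        return ax


def bin_spikes(session: Session, bin_width: float = 0.025, epoch=None,
               neurons=None) -> BinnedCounts:
    """Bin spike trains in half-open ``[edge, edge + bin_width)`` bins.

    Bins are laid out per epoch interval (only whole bins inside each
    interval are kept) and concatenated.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    intervals = session.epoch_intervals(epoch)
    if neurons is None:
        neurons = np.arange(session.n_neurons)
    neurons = np.asarray(neurons, dtype=int)
    edges_list, centers_list, count_blocks = [], [], []
    for start, end in intervals:
        n_bins = int(np.floor((end - start) / bin_width + 1e-9))
        if n_bins < 1:
            continue
        edges = start + np.arange(n_bins + 1) * bin_width
        block = np.zeros((n_bins, neurons.size), dtype=np.int64)
        for j, n in enumerate(neurons):
            st = session.spike_times[n]
            st = st[(st >= start) & (st < edges[-1])]
            if st.size:
                ix = np.floor((st - start) / bin_width).astype(np.int64)
                ix = ix[(ix >= 0) & (ix < n_bins)]
                block[:, j] = np.bincount(ix, minlength=n_bins)
        edges_list.append(edges)
        centers_list.append(edges[:-1] + bin_width / 2.0)
        count_blocks.append(block)
    if not count_blocks:
        raise ValueError("empty epoch: no whole bin fits in any interval")
    return BinnedCounts(edges_list, np.concatenate(centers_list),
                        np.vstack(count_blocks), bin_width)


def smooth_counts(binned: BinnedCounts, kernel_width: float = 0.125) -> np.ndarray:
    """Gaussian smoothing of binned counts (sigma = kernel_width seconds,
    reflected boundaries); the result is also stored on ``binned.smoothed``.

    kernel_width = 0 returns the raw counts unchanged.
    """
    if kernel_width < 0:
        raise ValueError("kernel_width must be >= 0")
    counts = binned.counts.astype(float)
    if kernel_width == 0:
        binned.smoothed = counts
        return counts
    sigma = kernel_width / binned.bin_width
    out = gaussian_filter1d(counts, sigma, axis=0, mode="reflect")
    binned.smoothed = out
    return out


def tuning_curve(session: Session, neuron: int, n_bins: int = 60, epoch=None,
                 bin_width: float = 0.025) -> TuningCurve:
    """Head-direction tuning curve: spike counts per angular bin divided by
    the total time spent in that bin, using time bins of ``bin_width``.

    Angular bins are ``[2 pi i / n_bins, 2 pi (i+1) / n_bins)``.  Bins never
    visited get rate 0 and are flagged in ``zero_occupancy``.
    """
    binned = bin_spikes(session, bin_width, epoch, neurons=[neuron])
    counts = binned.counts[:, 0].astype(float)
    ang, valid = _interp_angle(session, binned.centers)
    counts = counts[valid]
    ang = ang[valid]
    if ang.size == 0:
        raise ValueError("no tracked angle samples in epoch")
    ang_bin = np.floor(ang / (TWO_PI / n_bins)).astype(int) % n_bins
    spk = np.bincount(ang_bin, weights=counts, minlength=n_bins)
    occ_bins = np.bincount(ang_bin, minlength=n_bins).astype(float)
    occupancy = occ_bins * bin_width
    rate = np.divide(spk, occupancy, out=np.zeros(n_bins), where=occupancy > 0)
    centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
    return TuningCurve(centers, rate, occupancy, zero_occupancy=occupancy == 0)


def fisher_information(curve: TuningCurve) -> np.ndarray:
    """Per-bin Fisher information (df/dphi)^2 / f from a tuning curve.

    The slope at each bin is the least-squares line over the three
    successive bins centred there (circularly wrapped), in per-radian
    units; bins with zero rate report 0.
    """
    f = np.asarray(curve.rate, dtype=float)
    n = f.size
    if n < 3:
        raise ValueError("need at least 3 bins")
    delta = TWO_PI / n
    # LS slope on 3 equally spaced points is (f[i+1] - f[i-1]) / (2 delta)
    slope = (np.roll(f, -1) - np.roll(f, 1)) / (2.0 * delta)
    fi = np.zeros(n)
    np.divide(slope**2, f, out=fi, where=f > 0)
    return fi


def harmonic_features(angles, order: int = 6) -> np.ndarray:
    """Trigonometric expansion [cos k0, sin k0, ..., cos k_order, sin k_order]."""
    th = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("non-finite angles")
    cols = []
    for k in range(1, order + 1):
        cols.append(np.cos(k * th))
        cols.append(np.sin(k * th))
    return np.column_stack(cols)


def _interp_angle(session: Session, times: np.ndarray, max_gap: float = 0.5):
    """Circularly interpolate the tracked angle at ``times``.

    Returns (angle, valid) where ``valid`` flags times bracketed by tracking
    samples no more than ``max_gap`` apart (NaN tracking samples count as
    gaps).
    """
    tt = session.tracking_times
    ang = session.angle
    ok = np.isfinite(ang)
    tt, ang = tt[ok], ang[ok]
    if tt.size < 2:
        raise ValueError("not enough tracking samples")
    unwrapped = np.unwrap(ang)
    out = np.mod(np.interp(times, tt, unwrapped), TWO_PI)
    j = np.searchsorted(tt, times)
    jl = np.clip(j - 1, 0, tt.size - 1)
    jr = np.clip(j, 0, tt.size - 1)
    gap = tt[jr] - tt[jl]
    valid = (times >= tt[0]) & (times <= tt[-1]) & (gap <= max_gap)
    return out, valid


def behavior_matrix(session: Session, features=("angle",), epoch=None,
                    bin_width: float = 0.025, max_gap: float = 0.5):
    """Behavioral features interpolated at the spike-bin centers.

    Returns ``(X, valid)``: X has one column per requested feature in
    {"angle", "x", "y"} aligned row-for-row with :func:`bin_spikes` output;
    ``valid`` flags rows whose tracking gap is within ``max_gap`` seconds.
    The angle is interpolated circularly (via unwrapping), x/y linearly.
    """
    binned = bin_spikes(session, bin_width, epoch, neurons=[0] if session.n_neurons else None)
    times = binned.centers
    cols = []
    valid = np.ones(times.size, dtype=bool)
    for name in features:
        if name == "angle":
            a, v = _interp_angle(session, times, max_gap)
            cols.append(a)
            valid &= v
        elif name in ("x", "y"):
            series = session.x if name == "x" else session.y
            if series is None:
                raise ValueError(f"session has no {name} tracking")
            ok = np.isfinite(series)
            cols.append(np.interp(times, session.tracking_times[ok], series[ok]))
        else:
            raise ValueError(f"unknown behavioral feature {name!r}")
    return np.column_stack(cols), valid
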