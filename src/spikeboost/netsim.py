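"""Ground-truth head-direction network simulator.

A synthetic angular trajectory drives two layers of von Mises-tuned Poisson
neurons, T(ADn) and T(PoSub); a layer of leaky integrate-and-fire neurons,
I(PoSub), receives one-to-one input from its mirror T(PoSub) neuron (weight
0.9) and full connectivity from T(ADn) with angular-distance weights

    w_ij = alpha * exp(beta * (cos(phi_i - phi_j) - 1)),  alpha=0.1, beta=10.

Membrane dynamics are dv/dt = -v/tau with tau = 50 ms, threshold 1, reset 0,
no refractory period; synaptic events are delivered after a configurable
transmission delay.  The trajectory is a wrapped random walk whose angular
velocity follows an Ornstein-Uhlenbeck process, so the "angular speed" of
the animal can be scaled to emulate the accelerated head-direction dynamics
of non-REM sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .features import TWO_PI, Session, TuningCurve

__all__ = [
    "SimConfig",
    "SimOutput",
    "VonMisesTuning",
    "synth_trajectory",
    "vm_tuning",
    "poisson_layer",
    "connect_weights",
    "lif_layer",
    "simulate_session",
    "simulate_hd_cells",
    "default_concentration",
]


def default_concentration(fwhm_deg: float = 60.0) -> float:
    """Von Mises concentration giving the requested tuning width at half
    peak (default ~60 degrees, typical of head-direction cells)."""
    half = np.deg2rad(fwhm_deg / 2.0)
    return float(np.log(2.0) / (1.0 - np.cos(half)))


@dataclass
class SimConfig:
    """Simulation parameters (durations in seconds, rates in Hz)."""

    duration: float = 1200.0       # 20-min exploration session
    dt: float = 0.001
    n_adn: int = 10                # 10 + 10 as in the network validation
    n_posub: int = 10
    tau_m: float = 0.05            # LIF membrane constant
    v_thresh: float = 1.0
    v_reset: float = 0.0
    w_one_to_one: float = 0.9      # mirror synapse weight
    alpha: float = 0.1             # ADn->PoSub weight scale
    beta: float = 10.0             # ADn->PoSub angular concentration
    delay: float = 0.0             # ADn->PoSub transmission delay (s)
    mirror_delay: float = 0.0
    speed_factor: float = 1.0
    peak_rate: float = 30.0        # tuning-curve peak of the Poisson units
    baseline_rate: float = 1.0     # background firing of the Poisson units
    concentration: float = field(default_factory=default_concentration)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt > 0.001 + 1e-12:
            raise ValueError("dt must be <= 1 ms")
        if self.delay < 0 or self.mirror_delay < 0:
            raise ValueError("delays must be >= 0")
        if self.speed_factor < 0:
            raise ValueError("speed_factor must be >= 0")
        if self.dt > self.tau_m / 10:
            raise ValueError("dt must be <= tau_m / 10")


class VonMisesTuning:
    """Angular tuning curve with a background rate:

    f(theta) = baseline + (peak - baseline) * exp(kappa (cos(theta - pref) - 1))

    The baseline (default 1 Hz) emulates the nonzero background firing of
    recorded head-direction cells; the rate at the preferred direction is
    exactly ``peak_rate``.
    """

    def __init__(self, preferred_direction: float, peak_rate: float,
                 concentration: float, baseline_rate: float = 1.0):
        if peak_rate <= 0:
            raise ValueError("peak_rate must be > 0")
        if not (0 <= baseline_rate < peak_rate):
            raise ValueError("need 0 <= baseline_rate < peak_rate")
        self.preferred_direction = float(np.mod(preferred_direction, TWO_PI))
        self.peak_rate = float(peak_rate)
        self.concentration = float(concentration)
        self.baseline_rate = float(baseline_rate)

    def rate(self, theta) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        return self.baseline_rate + (self.peak_rate - self.baseline_rate) * np.exp(
            self.concentration * (np.cos(th - self.preferred_direction) - 1.0))

    def as_tuning_curve(self, n_bins: int = 60) -> TuningCurve:
        centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
        return TuningCurve(centers, self.rate(centers), np.ones(n_bins))


def vm_tuning(preferred_direction: float, peak_rate: float,
              concentration: float | None = None,
              baseline_rate: float = 1.0) -> VonMisesTuning:
    """Build a von Mises tuning curve (default concentration gives ~60 deg
    full width at half peak)."""
    if concentration is None:
        concentration = default_concentration()
    return VonMisesTuning(preferred_direction, peak_rate, concentration,
                          baseline_rate)


def synth_trajectory(duration: float, dt: float = 0.001,
                     speed_factor: float = 1.0, seed: int = 0,
                     relaxation: float = 1.0, speed_std: float = 1.0) -> np.ndarray:
    """Wrapped angular random walk with Ornstein-Uhlenbeck velocity.

    The angular velocity relaxes toward 0 with time constant ``relaxation``
    (1 s) and has stationary standard deviation ``speed_std`` (1 rad/s)
    before scaling by ``speed_factor``.  Uses the exact OU discretization,
    so the statistics do not depend on dt.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    phi = np.exp(-dt / relaxation)
    noise = rng.standard_normal(n) * speed_std * np.sqrt(1.0 - phi * phi)
    omega = lfilter([1.0], [1.0, -phi], noise)
    omega *= speed_factor
    theta = np.mod(np.cumsum(omega * dt), TWO_PI)
    return theta


def poisson_layer(curves, theta: np.ndarray, dt: float, seed: int = 0) -> np.ndarray:
    """Independent Poisson (Bernoulli-thinned) spiking driven by the
    trajectory: P(spike in step t) = f(theta_t) * dt.

    Returns a (n_steps, n_neurons) uint8 spike raster.  Requires
    rate * dt < 1; dt * max rate should stay below ~0.2 for the thinning
    approximation to be Poisson-like.
    """
    rng = np.random.default_rng(seed)
    n = theta.size
    spikes = np.zeros((n, len(curves)), dtype=np.uint8)
    for j, curve in enumerate(curves):
        if hasattr(curve, "rate") and callable(curve.rate):
            r = curve.rate(theta)
        else:
            c = curve  # TuningCurve: piecewise-constant lookup
            b = np.floor(np.mod(theta, TWO_PI) / (TWO_PI / c.n_bins)).astype(int) % c.n_bins
            r = c.rate[b]
        p = r * dt
        if np.any(p >= 1.0):
            raise ValueError("rate * dt >= 1: decrease dt")
        spikes[:, j] = rng.random(n) < p
    return spikes


def connect_weights(pref_adn, pref_posub, alpha: float = 0.1,
                    beta: float = 10.0) -> np.ndarray:
    """(n_adn, n_posub) synaptic weights, exponential in the cosine of the
    preferred-direction difference; maximal (= alpha) at zero distance."""
    a = np.mod(np.asarray(pref_adn, dtype=float), TWO_PI)[:, None]
    b = np.mod(np.asarray(pref_posub, dtype=float), TWO_PI)[None, :]
    return alpha * np.exp(beta * (np.cos(a - b) - 1.0))


@njit(cache=True)
def _lif_run(drive, decay, v_thresh, v_reset, v0, record_v):  # pragma: no cover
    T, M = drive.shape
    v = np.empty(M)
    for j in range(M):
        v[j] = v0
    spikes = np.zeros((T, M), dtype=np.uint8)
    traces = np.zeros((T if record_v else 1, M))
    for t in range(T):
        for j in range(M):
            vj = v[j] * decay + drive[t, j]
            if vj >= v_thresh:
                spikes[t, j] = 1
                vj = v_reset
            v[j] = vj
            if record_v:
                traces[t, j] = vj
    return spikes, traces


def _delayed(arr: np.ndarray, steps: int) -> np.ndarray:
    if steps <= 0:
        return arr
    out = np.zeros_like(arr)
    out[steps:] = arr[:-steps]
    return out


def lif_layer(input_spikes, weights, delay: float, config: SimConfig,
              record_v: bool = False, v0: float = 0.0, extra_drive=None):
    """Leaky integrate-and-fire layer driven by weighted, delayed spikes.

    Between events the membrane decays exactly (v <- v e^{-dt/tau}); a
    presynaptic spike at step t contributes its weight at t + delay.
    Returns (spike raster (T, M) uint8, voltage traces or None).
    """
    S = np.asarray(input_spikes, dtype=np.float64)
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    drive = _delayed(S @ W, int(round(delay / config.dt)))
    if extra_drive is not None:
        drive = drive + extra_drive
    decay = np.exp(-config.dt / config.tau_m)
    spikes, traces = _lif_run(np.ascontiguousarray(drive), decay,
                              config.v_thresh, config.v_reset, v0, record_v)
    return spikes, (traces if record_v else None)


@dataclass
class SimOutput:
    """Everything the simulator produced, plus the ground truth."""

    config: SimConfig
    theta: np.ndarray             # trajectory at config.dt
    spikes_adn: np.ndarray        # (T, n_adn) uint8
    spikes_mirror: np.ndarray     # (T, n_posub) uint8, T(PoSub)
    spikes_lif: np.ndarray        # (T, n_posub) uint8, I(PoSub)
    pref_adn: np.ndarray
    pref_posub: np.ndarray
    weights: np.ndarray           # (n_adn, n_posub)
    v_traces: np.ndarray | None = None

    def spike_times(self, raster: np.ndarray) -> list:
        dt = self.config.dt
        return [(np.nonzero(raster[:, j])[0] + 0.5) * dt
                for j in range(raster.shape[1])]

    def to_session(self, include_mirror: bool = False,
                   tracking_dt: float = 0.025) -> Session:
        """Package the simulation as a Session: T(ADn) Poisson units labelled
        ADn, I(PoSub) LIF units labelled PoSub (optionally also the mirror
        Poisson layer), tracking resampled at ``tracking_dt``."""
        dt = self.config.dt
        stride = max(int(round(tracking_dt / dt)), 1)
        tt = (np.arange(self.theta.size) * dt)[::stride]
        spikes = self.spike_times(self.spikes_adn) + self.spike_times(self.spikes_lif)
        regions = ["ADn"] * self.config.n_adn + ["PoSub"] * self.config.n_posub
        if include_mirror:
            spikes += self.spike_times(self.spikes_mirror)
            regions += ["PoSubMirror"] * self.config.n_posub
        return Session(
            spike_times=spikes,
            tracking_times=tt,
            angle=self.theta[::stride],
            epochs={"wake": [[0.0, self.theta.size * dt]]},
            regions=regions,
            ground_truth={
                "pref_adn": self.pref_adn,
                "pref_posub": self.pref_posub,
                "weights": self.weights,
                "delay": self.config.delay,
                "speed_factor": self.config.speed_factor,
            },
        )


def simulate_session(config: SimConfig | None = None, record_v: bool = False) -> SimOutput:
    """Run the full two-layer network simulation.

    Preferred directions are evenly spaced on [0, 2pi) in both layers; the
    mirror T(PoSub) input reaches I(PoSub) after ``config.mirror_delay``
    (default 0) and the T(ADn) input after ``config.delay``.
    """
    cfg = config or SimConfig()
    theta = synth_trajectory(cfg.duration, cfg.dt, cfg.speed_factor, cfg.seed)
    pref_adn = (np.arange(cfg.n_adn) + 0.5) * TWO_PI / max(cfg.n_adn, 1)
    pref_posub = (np.arange(cfg.n_posub) + 0.5) * TWO_PI / max(cfg.n_posub, 1)
    curves_adn = [vm_tuning(p, cfg.peak_rate, cfg.concentration, cfg.baseline_rate)
                  for p in pref_adn]
    curves_mirror = [vm_tuning(p, cfg.peak_rate, cfg.concentration, cfg.baseline_rate)
                     for p in pref_posub]
    spikes_adn = (poisson_layer(curves_adn, theta, cfg.dt, seed=cfg.seed + 1)
                  if cfg.n_adn else np.zeros((theta.size, 0), dtype=np.uint8))
    spikes_mirror = poisson_layer(curves_mirror, theta, cfg.dt, seed=cfg.seed + 2)
    mirror_drive = _delayed(spikes_mirror.astype(float) * cfg.w_one_to_one,
                            int(round(cfg.mirror_delay / cfg.dt)))
    if cfg.n_adn:
        W = connect_weights(pref_adn, pref_posub, cfg.alpha, cfg.beta)
        spikes_lif, v = lif_layer(spikes_adn, W, cfg.delay, cfg,
                                  record_v=record_v, extra_drive=mirror_drive)
    else:
        W = np.zeros((0, cfg.n_posub))
        spikes_lif, v = lif_layer(np.zeros((theta.size, 1)),
                                  np.zeros((1, cfg.n_posub)), 0.0, cfg,
                                  record_v=record_v, extra_drive=mirror_drive)
    return SimOutput(cfg, theta, spikes_adn, spikes_mirror, spikes_lif,
                     pref_adn, pref_posub, W, v_traces=v)


def simulate_hd_cells(n_cells: int = 20, duration: float = 1200.0,
                      dt: float = 0.001, peak_rate: float = 30.0,
                      baseline_rate: float = 1.0,
                      concentration: float | None = None,
                      speed_factor: float = 1.0, seed: int = 0,
                      region: str = "ADn") -> Session:
    """Poisson-only surrogate: von Mises HD cells with evenly spaced
    preferred directions driven by a synthetic trajectory.  This is the
    standard fixture for encoder/decoder validation."""
    if concentration is None:
        concentration = default_concentration()
    theta = synth_trajectory(duration, dt, speed_factor, seed)
    prefs = (np.arange(n_cells) + 0.5) * TWO_PI / n_cells
    curves = [vm_tuning(p, peak_rate, concentration, baseline_rate) for p in prefs]
    spikes = poisson_layer(curves, theta, dt, seed=seed + 1)
    dtimes = [(np.nonzero(spikes[:, j])[0] + 0.5) * dt for j in range(n_cells)]
    stride = max(int(round(0.025 / dt)), 1)
    return Session(
        spike_times=dtimes,
        tracking_times=(np.arange(theta.size) * dt)[::stride],
        angle=theta[::stride],
        epochs={"wake": [[0.0, duration]]},
        regions=[region] * n_cells,
        ground_truth={"preferred_directions": prefs, "peak_rate": peak_rate,
                      "concentration": concentration},
    )
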