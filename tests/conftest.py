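"""Shared fixtures: simulated sessions are expensive, so the standard
20-minute ensembles are built once per test session."""

from __future__ import annotations

import numpy as np
import pytest

from spikeboost.features import behavior_matrix, bin_spikes, smooth_counts
from spikeboost.netsim import SimConfig, simulate_hd_cells, simulate_session


@pytest.fixture(scope="session")
def hd20():
    """20 simulated von Mises HD cells, 20 min, with 25 ms binned/smoothed
    counts and the aligned angle regressor."""
    session = simulate_hd_cells(n_cells=20, duration=1200.0, seed=7)
    binned = bin_spikes(session, 0.025)
    smooth_counts(binned)
    angles, valid = behavior_matrix(session, ("angle",), bin_width=0.025)
    return {
        "session": session,
        "binned": binned,
        "angles": angles[valid, 0],
        "y": binned.smoothed[valid],
        "valid": valid,
    }


@pytest.fixture(scope="session")
def net_sim():
    """Cached factory for network simulations keyed by (delay, speed, seed,
    duration)."""
    cache = {}

    def run(delay=0.0, speed=1.0, seed=11, duration=600.0):
        key = (delay, speed, seed, duration)
        if key not in cache:
            cfg = SimConfig(duration=duration, delay=delay,
                            speed_factor=speed, seed=seed)
            cache[key] = simulate_session(cfg)
        return cache[key]

    return run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
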