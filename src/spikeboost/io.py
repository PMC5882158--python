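"""Session I/O.

The generic session layout is a directory of plain CSV files for
auditability:

    manifest.csv   neuron_id, region
    spikes.csv     neuron_id, time        (seconds, session-relative)
    tracking.csv   time, angle, x, y     (angle in radians, [0, 2pi))
    epochs.csv     state, start, end     (wake / rem / nonrem)

An optional reader for Neurosuite-format recordings (.res.N spike samples
at 20 kHz, .clu.N cluster labels with the count on the first line, and a
.whl two-LED tracking file at 39 Hz) covers the deposited thalamo-cortical
head-direction dataset's dialect; clusters 0 and 1 (noise and multi-unit
conventions) are dropped.
"""

from __future__ import annotations

import glob
import os
import warnings

import numpy as np
import pandas as pd

from .features import TWO_PI, Session

__all__ = ["read_session", "write_session", "read_neurosuite"]


def write_session(session: Session, path: str) -> None:
    """Write a Session to the CSV directory layout."""
    os.makedirs(path, exist_ok=True)
    pd.DataFrame({
        "neuron_id": np.arange(session.n_neurons),
        "region": session.regions,
    }).to_csv(os.path.join(path, "manifest.csv"), index=False)
    ids = np.concatenate([np.full(len(st), i, dtype=int)
                          for i, st in enumerate(session.spike_times)]) \
        if session.n_neurons else np.array([], dtype=int)
    times = np.concatenate(session.spike_times) if session.n_neurons else np.array([])
    pd.DataFrame({"neuron_id": ids, "time": times}).to_csv(
        os.path.join(path, "spikes.csv"), index=False)
    tr = {"time": session.tracking_times, "angle": session.angle}
    tr["x"] = session.x if session.x is not None else np.full(session.angle.size, np.nan)
    tr["y"] = session.y if session.y is not None else np.full(session.angle.size, np.nan)
    pd.DataFrame(tr).to_csv(os.path.join(path, "tracking.csv"), index=False)
    rows = []
    for state, iv in session.epochs.items():
        for start, end in iv:
            rows.append({"state": state, "start": start, "end": end})
    pd.DataFrame(rows).to_csv(os.path.join(path, "epochs.csv"), index=False)


def read_session(path: str) -> Session:
    """Read a Session from the CSV directory layout, with validation.

    Unsorted spikes are sorted with a warning; out-of-range angles are
    wrapped with a warning; missing tracking is an error.  Neurons listed
    in the manifest but absent from spikes.csv are kept with zero spikes.
    """
    manifest_path = os.path.join(path, "manifest.csv")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"no manifest.csv in {path}")
    manifest = pd.read_csv(manifest_path)
    tracking_path = os.path.join(path, "tracking.csv")
    if not os.path.exists(tracking_path):
        raise FileNotFoundError(f"no tracking.csv in {path}")
    tracking = pd.read_csv(tracking_path)
    spikes = pd.read_csv(os.path.join(path, "spikes.csv"))
    n = len(manifest)
    spike_times = []
    for nid in manifest["neuron_id"]:
        st = spikes.loc[spikes["neuron_id"] == nid, "time"].to_numpy(dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            warnings.warn(f"neuron {nid}: unsorted spike times, sorting")
            st = np.sort(st)
        spike_times.append(st)
    ang = tracking["angle"].to_numpy(dtype=float)
    finite = ang[np.isfinite(ang)]
    if finite.size and (finite.min() < 0 or finite.max() >= TWO_PI):
        warnings.warn("angle out of [0, 2pi): wrapping")
    epochs = {}
    ep_path = os.path.join(path, "epochs.csv")
    if os.path.exists(ep_path):
        ep = pd.read_csv(ep_path)
        for state, grp in ep.groupby("state"):
            iv = grp[["start", "end"]].to_numpy(dtype=float)
            iv = iv[np.argsort(iv[:, 0])]
            if np.any(iv[1:, 0] < iv[:-1, 1] - 1e-9):
                raise ValueError(f"overlapping {state} epochs")
            epochs[state] = iv
    return Session(
        spike_times=spike_times,
        tracking_times=tracking["time"].to_numpy(dtype=float),
        angle=ang,
        x=tracking["x"].to_numpy(dtype=float) if "x" in tracking else None,
        y=tracking["y"].to_numpy(dtype=float) if "y" in tracking else None,
        epochs=epochs,
        regions=list(manifest["region"].astype(str)),
    )


def read_neurosuite(session_dir: str, sampling_rate: float = 20000.0,
                    tracking_rate: float = 39.0) -> Session:
    """Read a Neurosuite session directory (.res.N / .clu.N / .whl).

    Spike samples are divided by ``sampling_rate`` to get seconds; cluster
    ids 0 and 1 are dropped.  The .whl file holds x1,y1,x2,y2 LED positions
    per frame with -1 sentinels for lost tracking; the head direction is
    atan2(y1 - y2, x1 - x2) with the first LED anterior.
    """
    res_files = sorted(glob.glob(os.path.join(session_dir, "*.res.*")),
                       key=lambda p: int(p.rsplit(".", 1)[1]))
    spike_times, regions = [], []
    for res_path in res_files:
        shank = res_path.rsplit(".", 1)[1]
        clu_path = res_path.replace(f".res.{shank}", f".clu.{shank}")
        if not os.path.exists(clu_path):
            raise FileNotFoundError(f"missing {clu_path}")
        res = np.loadtxt(res_path, dtype=np.int64, ndmin=1)
        clu = np.loadtxt(clu_path, dtype=np.int64, ndmin=1)
        n_clusters = int(clu[0])
        clu = clu[1:]
        if clu.size != res.size:
            raise ValueError(f"{clu_path}: cluster/sample count mismatch")
        for c in range(2, n_clusters):
            st = res[clu == c] / sampling_rate
            spike_times.append(np.sort(st))
            regions.append("other")
    whl = glob.glob(os.path.join(session_dir, "*.whl"))
    if not whl:
        raise FileNotFoundError("no .whl tracking file")
    led = np.loadtxt(whl[0], ndmin=2)
    led = np.where(led == -1, np.nan, led)
    x1, y1, x2, y2 = led[:, 0], led[:, 1], led[:, 2], led[:, 3]
    angle = np.mod(np.arctan2(y1 - y2, x1 - x2), TWO_PI)
    angle = np.where(np.isfinite(x1) & np.isfinite(x2), angle, np.nan)
    times = np.arange(led.shape[0]) / tracking_rate
    return Session(
        spike_times=spike_times,
        tracking_times=times,
        angle=np.where(np.isfinite(angle), angle, np.nan),
        x=(x1 + x2) / 2.0,
        y=(y1 + y2) / 2.0,
        regions=regions,
    )
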