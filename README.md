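# spikeboost

Gradient boosted trees for spike-train analysis in the head-direction (HD)
system: non-linear **encoding** of spike counts from behavior, Bayesian and
boosted-tree **decoding** of head direction from population activity, and
**peer-prediction with lag-stacked features** whose tree structure reads out
directed transmission delays between neuronal populations — all validated
against a built-in Poisson / integrate-and-fire network simulator with known
ground truth.

It is written for systems neuroscientists who want an interpretable
machine-learning encoder: unlike a generic boosting library, every tree in
the model exposes its split thresholds and gains, so the *structure* of the
fit — where the trees split the feature space, and how much each split
improves the objective — becomes the analysis.

## The model

Spike counts `y_i` in 25 ms bins are modelled as Poisson with intensity
`λ(x_i)`; the log-intensity is a sum of regression trees fitted by
second-order gradient boosting. With per-sample derivatives of the Poisson
deviance `g = e^ŷ − y`, `h = e^ŷ`, a leaf carrying samples `I_j` takes the
weight

    w*_j = − G_j / (H_j + λ̄),   G_j = Σ_{i∈I_j} g_i,  H_j = Σ_{i∈I_j} h_i

and a split of a node into (L, R) is scored by the gain

    Gain = ½ [ G_L²/(H_L+λ̄) + G_R²/(H_R+λ̄) − (G_L+G_R)²/(H_L+H_R+λ̄) ] − γ

with defaults γ = 0.4, λ̄ = 0. Split finding is *exact* greedy over the
midpoints of consecutive unique feature values, so the trees can be checked
against brute-force enumeration. Three analyses are built on this core:

- **Encoding** — predict a neuron's binned spike train from the head
  direction (and optionally x/y position); performance is the deviance
  pseudo-R² under 8-fold cross-validation over contiguous time blocks, and
  complexity is selected by `BIC = (|trees| + depth)·log n − 2·log L`.
  Split density along the angle axis tracks the tuning curve's Fisher
  information `(df/dφ)²/f`.
- **Decoding** — reconstruct the HD from population spike counts in 200 ms
  bins, via the classical Bayesian population decoder (independent Poisson
  likelihoods over 60 angular classes) or a multiclass softmax boosted-tree
  classifier.
- **Peer-prediction / delay inference** — predict one neuron's counts from
  time-shifted copies of other neurons' counts (lags −T…+T); aggregating
  `n_splits × mean gain` per lag yields a gain profile whose peak sits at
  minus the transmission delay, invariant to the speed of the underlying
  behavioral signal (unlike cross-correlogram widths).

The simulator (`spikeboost.netsim`) provides the ground truth: a wrapped
angular random walk with Ornstein–Uhlenbeck velocity drives von Mises-tuned
Poisson layers T(ADn) and T(PoSub); a leaky integrate-and-fire layer
I(PoSub) (`dv/dt = −v/τ`, τ = 50 ms, threshold 1, reset 0) receives its
mirror T(PoSub) input with weight 0.9 and full T(ADn) connectivity with
weights `w_ij = α·exp(β(cos(φ_i−φ_j)−1))`, α = 0.1, β = 10, after a
configurable synaptic delay.

## Worked example

```python
import numpy as np
from spikeboost import (SimConfig, simulate_session, bin_spikes, smooth_counts,
                        behavior_matrix, compare_encoders, fit_gain_profile)

# 5 minutes of the two-layer network with a 25 ms synaptic delay
cfg = SimConfig(duration=300.0, delay=0.025, seed=42)
session = simulate_session(cfg).to_session()

binned = bin_spikes(session, bin_width=0.025)
smooth_counts(binned)
angles, valid = behavior_matrix(session, ("angle",), bin_width=0.025)

# encode one thalamic cell from the head direction
neuron = session.neurons_in("ADn")[0]
scores = compare_encoders(angles[valid, 0], binned.smoothed[valid, neuron])
for name, cv in scores.items():
    print(f"{name:<16} mean pR2 = {cv.mean:+.3f}")

# read the transmission delay out of the trees
total = None
adn = list(session.neurons_in("ADn"))
for target in session.neurons_in("PoSub"):
    prof = fit_gain_profile(binned, int(target), adn, max_lag=0.2)
    total = prof.gain if total is None else total + prof.gain
peak = prof.lags[int(np.argmax(total))]
print(f"gain-profile peak lag: {peak * 1000:+.0f} ms")
```

Output:

```
xgb              mean pR2 = +0.801
mb               mean pR2 = +0.798
linear           mean pR2 = -0.035
linear-harmonic  mean pR2 = +0.804
gain-profile peak lag: -25 ms
```

The boosted encoder (`xgb`), the model-based tuning-curve predictor (`mb`)
and the 6th-order harmonic linear model agree; raw-angle linear regression
fails because spike counts are not a linear function of an angle. The
lag-gain profile peaks at −25 ms: PoSub spiking is best explained by ADn
activity 25 ms earlier — exactly the injected synaptic delay.

A command-line interface mirrors the library
(`spikeboost simulate | encode | decode | peer | lag-profile | correlogram |
fixtures`); run `spikeboost --help`.

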