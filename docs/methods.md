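# Methods

## Boosting core

The estimator is second-order gradient boosting with regression trees,
written from scratch so the fitted structure is fully inspectable. The
objective per tree is the loss's second-order expansion plus the
regularizer `γ·|leaves| + ½λ̄·Σ w_j²`; leaf weights and split gains follow
in closed form (see README). Defaults: γ = 0.4, λ̄ = 0, shrinkage
η = 0.3, 100 trees of depth 5 for prediction, 30 trees of depth 2 for
structure interpretation. The prediction/interpretation split matters:
late trees increasingly split uninformative features (their per-tree gain
decays roughly exponentially with round), so gain analyses read only a
short boosting run, while predictive scores use the longer one.

Numerical choices:

- **Exact greedy splits.** Candidate thresholds are midpoints of
  consecutive sorted unique values; a split needs strictly positive gain;
  ties resolve to the lowest feature index, then the smallest threshold.
  Two code paths produce identical results: a presorted vectorized path
  for continuous features and a histogram path (numba) for small
  non-negative integer features such as spike counts. The published gain
  formula's third term is implemented as `(G_L+G_R)²/(H_L+H_R+λ̄)`, the
  form implied by the leaf-objective derivation; some printed versions of
  the formula show `G_L²+G_R²` in the numerator, which does not reduce to
  the parent score at a null split.
- **Poisson safeguards.** Raw leaf weights are clipped to ±0.7 and margins
  to ±30 before exponentiation. With η = 0.3 and the 0.7 cap, each
  per-leaf Newton step provably decreases the exact Poisson loss (the
  damped step stays inside the decrease region of `H₀eᵗ − Y·t`), which is
  why training loss is monotone — a property the tests assert.
- **Base score** is `log(mean(y) + 1e-8)` for Poisson, 0 for softmax.
- **Softmax objective** fits one tree per class per round with
  `g_k = p_k − 1{k=label}`, `h_k = p_k(1−p_k)`.
- Determinism: the fit has no randomness; identical inputs give
  bit-identical trees, and the JSON serialization round-trips predictions
  exactly.

## Binning, tuning curves, Fisher information

Spike trains are binned at 25 ms (half-open bins) and smoothed with a
Gaussian kernel of σ = 125 ms; decoding uses raw 200 ms bins; lag-stacked
peer-prediction uses raw 25 ms counts. Tuning curves use 60 angular bins:
spike count per bin divided by occupancy time. Fisher information per bin
is `slope²/rate`, the slope being the least-squares line through three
successive bins (circularly wrapped, per-radian units; for three equally
spaced points this is the centered difference over 2Δ). Zero-rate bins
report 0. The per-radian choice only scales FI globally, so downstream
correlations are unaffected. Behavioral features are interpolated to bin
centers, the angle circularly via unwrapping; tracking gaps longer than
0.5 s flag the affected bins.

## Cross-validation and model selection

Pseudo-R² folds are 8 contiguous, disjoint time blocks; contiguity keeps
smoothed samples from leaking across the train/test boundary. Each fold's
reference mean rate `ȳ` comes from that fold's training portion. In the
BIC grid, `log L` is the Poisson log-likelihood (including the `log y!`
term) of the *held-out* cross-validated predictions; the published
formulation leaves open whether training or test likelihood is meant, and
the held-out choice is the conservative one. Linear baselines are
ordinary least squares (the published text says "linear regression");
non-positive predictions are floored at 1e-8 so the deviance is defined.

## Decoding

The Bayesian decoder evaluates, in log space,
`log P(n|φ) = Σ_i n_i log(τ f_i(φ)) − τ f_i(φ)` over 60 classes with a
uniform prior by default (occupancy priors optional); tuning-curve rates
are floored at 1e-3 Hz so observed spikes never produce −∞. The boosted
decoder is the softmax model on population count vectors (defaults 30
rounds, depth 3 — near its performance plateau at a fraction of the cost).
Decoding error is the circular distance between the posterior argmax
class center and the true (continuous) angle.

On the synthetic cells the Bayesian decoder is *exactly* the generative
model and therefore optimal; the boosted decoder converges to within
~20% of its log loss and the same ~1-bin median error, but cannot beat
it. On recorded data, where Poisson and independence assumptions fail,
the two methods are reported to be on par — passing the synthetic parity
test at the achievable bound (ratio < 1.25) therefore shows the decoder is
close to the information-theoretic ceiling, not that it would merely tie
on real data.

## Peer-prediction and delay inference

The lag design gives each feature neuron one column per lag in ±200 ms
(25 ms steps, the binning resolution; the range comfortably covers
thalamo-cortical delays of tens of ms). The column at lag ℓ holds the
feature's count at `t+ℓ`; edge bins are dropped. The gain profile
aggregates `n_splits × mean gain` per lag over feature neurons and
targets; its peak at lag −d means the feature population's activity d
seconds *before* the target bin is most predictive — a transmission delay
d. FWHM is measured at half of (peak − baseline) above baseline, baseline
being the profile minimum, with linear interpolation.

## Network simulator

The generator emulates a 20-min exploration session of the
thalamo-cortical HD circuit:

- **Trajectory**: wrapped random walk whose angular velocity is an
  Ornstein–Uhlenbeck process (relaxation 1 s, stationary std 1 rad/s,
  exact discretization); a speed factor scales the velocity and serves as
  the surrogate for brain states with faster HD dynamics. A recorded HD
  trace could be substituted directly.
- **Tuning**: von Mises curves, evenly spaced preferred directions, peak
  30 Hz, ~60° width at half peak (concentration ln2/(1−cos 30°) ≈ 5.2),
  plus a 1 Hz background rate. The background matters: recorded HD cells
  fire at 0.5–2 Hz off-peak, and a tuning curve that is exactly zero
  over half the circle puts the Poisson booster in a degenerate regime
  (log-rate → −∞) that spreads split thresholds into regions real data
  never produce.
- **Layers**: 10 T(ADn) + 10 T(PoSub) Poisson units (Bernoulli thinning at
  dt = 1 ms, valid for rate·dt ≪ 1) and 10 I(PoSub) LIF units
  (τ = 50 ms, threshold 1, reset 0, no refractory period; exact per-step
  exponential decay). The mirror synapse (weight 0.9) reaches its LIF unit
  with zero delay by default; the ADn synapses (α = 0.1, β = 10, full
  connectivity) carry the configurable transmission delay.

What the simulator does *not* emulate: spike-history structure
(refractoriness, bursting), inhibition, conductance synapses, true
REM/non-REM dynamics (the speed factor is a surrogate), heterogeneous
tuning widths/rates, and recording artifacts. Tests passing on this
ground truth show the estimators recover what they claim under the
model's assumptions, not that those assumptions hold in any recording.

## Correlogram analyses

Cross-correlograms default to 5 ms bins, ±500 ms (resolving 25 ms
delays); the speed-dependence analysis uses 25 ms bins over ±2 s because
the co-modulation envelope at normal speed is wider than ±500 ms and
per-correlogram centering would otherwise remove it. The variance
profile is the per-lag std across pairs after subtracting each
correlogram's own mean. For the zero-delay integration bias, profiles are
oriented "feature time relative to target spike" (so a leading feature
population loads negative lags) and the shift is quantified by the signed
mass asymmetry about zero over ±100 ms (2× the membrane constant): the
raw center of mass of a noisy pedestal is sign-unstable, whereas the
asymmetry isolates the one-sided integration shoulder the bias actually
produces. Exponential fits `A·e^{−|ℓ−ℓ₀|/τ_c}+c` use bounded
least-squares.

## Validation problem sizes

The standard conditions are 20-min sessions, 25 ms bins, 60 angular bins.
The test suite runs encoder parity, split-density/FI and speed-invariance
checks at the full 20-min scale, and uses 10-min sessions for the
delay-recovery grid (3 delays × 3 seeds) and the decoder population-size
comparison (5 seeds), where the measured properties are stable at that
size. The acceptance script uses the full 20-min condition.

## Known limitations

- Exact greedy split finding is O(n log n) per feature per node; very wide
  lag designs are handled by the integer histogram path, but histogram
  *approximation* (fixed bin budgets) is deliberately out of scope.
- The Neurosuite reader covers the .res/.clu/.whl dialect with the
  two-LED convention `atan2(y₁−y₂, x₁−x₂)`; LED order should be checked
  against a given dataset's documentation before trusting absolute
  angles (relative analyses are unaffected).
- `pseudo_r2` is undefined for a constant target equal to its mean; such
  neurons should be excluded upstream.
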