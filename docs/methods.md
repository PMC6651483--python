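# Methods

## Overview

The package detects *divergent movement patterns*: 8-second fragments of
multi-sensor actigraphy that a sequence forecaster trained on a control
population fails to predict. The analysis chain is
preprocessing → segmentation → forecasting → similarity scoring → group
inference, with a synthetic-cohort generator providing ground-truthed
inputs for validation. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Preprocessing

**Gravity estimation.** The gravity vector in the sensor frame is the
centred moving average of the raw tri-axial signal over `N + 1` samples,
default `N = 20` (a 2.1 s window at 10 Hz). The window length trades
gravity-tracking lag against movement leakage: it must be long relative to
the voluntary-movement band (most power above ~0.5 Hz is attenuated) and
short relative to orientation changes. Boundary windows shrink rather than
pad — no invented samples. `N` is configurable and must be even.

**Vertical projection.** We report the signed component of movement
acceleration along the *unit* gravity direction, `a_v = a_m · ĝ′`, in g
units, rather than the coefficient `a_m · g′ / ‖g′‖²`. The two differ by
the factor `‖g′‖ ≈ 1`; the unit-vector form keeps thresholds and intensity
bins in physical g units. A gravity estimate with `‖g′‖ < 1e-6` raises an
error naming the sample (it would make the projection direction
meaningless); with real gravity always present this indicates corrupt
input, not a recoverable condition.

**Shake synchronization.** Recordings begin with a deliberate simultaneous
high-amplitude shake of all four sensors. Detection: find the first sample
with `|a_v| ≥ th1`, then the first later index whose forward window of
`n_sync + 1` samples has mean `|a_v| ≤ th2` *and contains no sample at or
above th1*. The burst-free condition matters: with a short averaging
window, a window straddling the burst tail can already satisfy the mean
condition one sample early. Defaults `th1 = 2 g`, `th2 = 0.5 g`,
`n_sync = 10` sit between the synthetic rest amplitude (≤ ~0.5 g) and the
3 g burst; only the inequalities `th1 > th2 > 0` are structural, so all
three are configurable. `|a_v|` (absolute value of the scalar) is used
throughout the scan — a signed mean over an alternating burst would be
near zero and end the burst immediately. Channels are trimmed to their own
detected post-burst index and truncated to the common minimum length;
indexing is 0-based with half-open ranges, the nominal rate is metadata.

## Segmentation and intensity

Windows are non-overlapping 80-sample blocks (8 s), split 60/20 into
forecaster input and target; the trailing remainder is discarded. The
movement intensity of a window is the sample SD (ddof = 1) of all 320
pooled values — the four channels concatenated into one flat sample, the
literal "combined" reading; a per-channel-SD-mean alternative would differ
only where channels have very unequal offsets. Intensity bins are
half-open `[lo, hi)` with default edges `0, 0.2, 0.4, 0.6, 0.8, 1.0, ∞` in
g; edges below 0.2 g and the treatment above 1 g are not pinned down by
the reference analysis, so the top bin is open-ended.

## Forecaster

A stacked LSTM with 50 memory units in layer 1 (input size 4) and 20 in
layer 2, followed by an affine map from layer 2's *final* hidden state to
the 80 predicted values (time-major layout, `t * 4 + channel`). Feeding
the dense head from the final state rather than the whole hidden sequence
was an open choice; the final state is the smaller, conventional reading
("the number of memory cells in the second layer is adapted to the length
of the sequence to be reconstructed"), and the full-sequence variant, like
a 3-layer/50-unit architecture, remains available through
`hidden_sizes` / code-level configuration. Initial `h, c` are zero per
window: windows are shuffled during training, so no cross-window state is
meaningful.

Training minimises MSE with mini-batch Adam — hand-written
backpropagation through time, no framework. Hyperparameters are not
constrained by the study design and are fixed as defaults: learning rate
1e-3, batch 64, max 30 epochs, early stopping with patience 5 on a 10%
held-out validation split, Glorot-uniform initialisation with forget bias
1. Tiny corpora (a few dozen windows) need more optimisation steps than
the defaults provide; the tests that train on single motifs use smaller
batches and more epochs for that reason. The returned parameters are the
best-validation snapshot and are guaranteed not to have a worse training
MSE than the seeded initialisation. Inputs are not rescaled: vertical
acceleration is already O(1) in g, and leaving the scale alone keeps
Pearson thresholds comparable across configurations. All training is
seeded and single-threaded-deterministic; two runs with the same seed and
data produce bit-identical parameters.

## Scoring and inference

A fragment's similarity is the Pearson correlation between the flattened
80-value prediction and observation (a per-channel-mean mode exists as
config). Vectors with variance below 1e-12 score r = 0: an uninformative
constant prediction must not count as a match. Consequently true rest
windows — near-constant targets — are flagged non-similar in *every*
group; they land in the lowest intensity bin and inflate both groups
equally, which is why the per-bin comparisons, not the overall count, are
the sensitive readout. The similarity threshold is `th = 0.5`, sweepable
over a grid without re-running the model (counts are monotonically
non-decreasing in th by construction).

Group comparisons use the pooled-variance two-sample t-test, one-sided for
"case mean > control mean" with `df = n_a + n_b − 2`. Sidedness and the
pooled (vs Welch) variance were open; the pooled one-sided form is the one
that reproduces the reference analysis's printed p-values (0.055, 0.152)
from its printed count summaries, which we verified against scipy's
independent implementation before fixing it as the default — Welch is
available and differs here by < 0.001. Zero pooled variance with equal
means returns p = 0.5 (the null convention); with unequal means the
comparison is flagged degenerate. Bins where both groups have zero count
variance are flagged `undefined`, never dropped. No multiple-testing
correction is applied across bins, matching the reference analysis; the
report states the number of comparisons. AUC is the pairwise-comparison
(Mann–Whitney) statistic with ties at 1/2; the operating point is the
smallest count threshold maximising Youden's J, reporting
(cases above / n, controls above / n).

## Synthetic cohorts: what they emulate

The generator reproduces the *structural* assumptions of the analysis, not
biomechanics:

* **Band-limited motifs.** Movement templates are zero-mean random Fourier
  series on a 2.1 s fundamental (harmonics 1–4, i.e. 0.476–1.905 Hz),
  respecting the ≤ 2 Hz concentration of voluntary limb movement. Motifs
  are 4-channel, normalised to unit pooled SD, tiled periodically within
  an "event" of 6–12 periods and tapered with a one-period raised cosine.
  The 2.1 s period equals the default gravity-filter window, so in the
  drift-free noise-free limit the moving average of the movement content
  is *exactly* zero in event interiors and preprocessing recovers the
  planted vertical acceleration to machine precision — the basis of the
  exact round-trip checks. `GroundTruth.steady_mask` marks the
  filter-transient neighbourhoods (event edges, tapers, the shake) where
  this cancellation cannot hold.
* **Intensity structure.** Each motif event is scaled to a target combined
  SD drawn uniformly from 0.05–1.15 g; rest periods (fraction 0.3, 8–16 s)
  contain only sensor noise (white, SD 0.02 g). Fragment SD is linear in
  the motif scale.
* **Orientation.** Each sensor observes the world (gravity +1 g up,
  vertical motif acceleration, independent horizontal movement at 30% of
  the vertical amplitude) through a random initial rotation composed with
  a slow random walk (default 0.005 rad/s per-step scale). The walk is
  Brownian motion in the rotation-vector tangent space — equivalent to a
  sequential SO(3) walk at these magnitudes and fully vectorisable.
* **Synchronization.** A 3 s, 3 g alternating-sign vertical burst precedes
  the content, offset per sensor by 0/5/10/15 samples (device clock
  offsets); motif peaks are capped at 2.2× their SD so the burst always
  dominates.
* **Planted divergence.** Atypical participants have each motif event
  whose target SD falls in the divergence band (default 0.4–1.0 g)
  replaced, with probability δ (default 0.8), by a motif from a disjoint
  dictionary. The random stream is consumed identically in both groups, so
  δ = 0 collapses the groups sample-for-sample. Default dictionaries hold
  6 motifs each.

The scaled-down study conditions used throughout the tests and the
acceptance script are 9 participants per group and 600 s of signal each
(vs 24 h in a real deployment) — large enough for the planted effect to be
comfortably detectable while keeping a 20-replicate power study on one CPU
in minutes.

**What passing does not show.** The generator's realism is asserted only
at the level of band limit, intensity distribution, and burst structure.
Real recordings contain non-stationary, non-periodic movement, non-wear
episodes, sensor repositioning, and inter-individual variability that the
motif model does not attempt; power and calibration measured here
establish that the pipeline recovers the effect *it is designed to
detect*, not that the effect size in any clinical population matches.

## Numerical choices and degenerate inputs

* Sigmoid is computed in the numerically stable split form; hidden states
  are tanh-bounded by construction.
* The forecaster's equation fidelity is checked against an independently
  coded naive evaluation of the five gate equations to 1e-10.
* Sample SD uses ddof = 1 everywhere counts or intensities are summarised
  (at n = 320 the distinction is negligible but fixed for
  reproducibility).
* Traces shorter than the filter window, fragments shorter than 80
  samples, empty training sets after bin filtering, missing per-bin
  models, and channels without a detectable burst all raise typed errors
  naming the offending sensor/bin/index.
* Per-participant seeds are spawned from the cohort seed via
  `SeedSequence`; every stochastic component (dictionaries, schedules,
  orientations, noise, training shuffles, initialisation) is reproducible
  from the single cohort/config seed.

## Known limitations

* The architecture constants (60-step input, 20-step output, 4 channels)
  assume the 10 Hz / 8 s study design; other rates require retuning the
  window constants, not just the metadata.
* Per-intensity-bin training requires every bin that occurs during scoring
  to be populated in training — with short synthetic recordings the
  sparse top bin often is not, so per-bin mode is practical only with
  coarser bins or longer recordings.
* The t-test treats per-participant counts as approximately normal;
  with n = 9 per group this follows the reference analysis rather than a
  robustness ideal (a rank test would be the conservative alternative).
* Rest fragments are structurally non-similar under the degenerate-
  variance rule; analyses focused on the lowest intensity bin should
  interpret counts there accordingly.
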