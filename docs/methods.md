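# Methods

This note records the models, parameter choices and numerical decisions
behind `fmgait`, and what the synthetic-cohort results do and do not show.

## Signal model and phase definitions

A force-myography ankle band reports the pressure exerted by the muscles
around the ankle on an array of force-sensing resistors while the wearer
walks. Within one gait cycle the envelope of these channels rises from
heel strike (Initial-Contact) through Mid-Stance and Pre-Swing, peaks
shortly before toe-off, collapses as the foot unloads, and stays near the
sensor baseline through Swing. The four phases are delimited by heel
strike, opposite toe-off, heel-off and toe-off; labels use codes 1–4 in
that order, and all intervals are half-open `[start, next_start)` so a
transition sample belongs to the phase that begins there.

## Feature extraction

Fourteen time-domain scalars per channel per window (`features.py`),
computed on 125 ms windows advancing 8 ms (62- and 4-sample lengths at
500 Hz; lengths are `round(ms · fs / 1000)` and the window count is
`floor((n − w)/s) + 1` with no edge padding). A window's timestamp is its
center, so a window is labeled by the phase in effect at its midpoint.
Choices worth noting:

* **MAV** is the mean absolute deviation about the window mean (the
  sum of absolute values divided by `n` is already available as SAV/n).
* **db7** is the mean of the detail coefficients of a single-level
  Daubechies-7 DWT with symmetric extension; the level is configurable
  and deeper levels cascade on the approximation coefficients.
* **Log detector** floors `|x|` at machine epsilon before the logarithm,
  since force-sensor baselines can be exactly zero.
* **Parabolic fit** contributes its quadratic *and* linear coefficients;
  with the linear-fit slope this completes the count of 14 and the
  112-column default feature vector (8 channels × 14).
* Fits use the sample index as the time variable; after min-max
  normalization the choice of time unit is immaterial.
* The slope-sign-change count uses a strict threshold, default 0.

Windows shorter than 3 samples are rejected. The vectorized extractor is
verified against the scalar per-window reference implementation in the
test suite.

Normalization is training-referenced min-max scaling per column. Columns
constant in training map to 0 (a constant feature carries no
information); test values outside the training range are deliberately not
clipped. Reversal of window time leaves all features unchanged except
the two fit slopes (which negate/flip) and the db7 detail mean — the
Daubechies filter is asymmetric, so exact reversal invariance does not
hold for it.

## Classification

A four-class linear discriminant with pooled within-class covariance
`Σ = Σ_c Σ_{i∈c}(x_i−μ_c)(x_i−μ_c)ᵀ/(n−C)` and Moore–Penrose
pseudoinverse (`lda.py`). With 112 strongly correlated features the
pooled covariance is routinely rank-deficient; the pseudoinverse keeps
the discriminant well-defined without shrinkage. Priors default to
empirical class frequencies (so the long Swing phase is favored on
ambiguous windows) and are configurable. Ties break toward the lower
phase code for reproducibility. Predictions are verified against a
brute-force shared-covariance Gaussian log-likelihood oracle and, on
full-rank problems, against scikit-learn's LDA.

## Supervisory transition rules

`events.apply_rules` converts the classified stream's raw run-length
transitions into a strictly cyclic 1→2→3→4→1 event list. The machine
keeps the latest accepted `(time, phase)`; a transition to the valid
successor is accepted; anything else opens a *recovery period* that ends
at the first event returning to the accepted phase or reaching its
successor. The period is then judged by its duration:

* shorter than `short_fraction` (default 0.5) of the interrupted phase's
  average duration → discarded as a classifier blip;
* longer than `long_multiple` (default 1.0) of the average cycle →
  promoted to one full synthesized cycle, keeping the period's observed
  phase starts where they fit the expected order and splitting the
  preceding phase at its temporal midpoint for each missed transition;
* intermediate → relabeled as the single expected successor phase
  starting at the period's start (minimal intervention).

Two refinements the bare order-checking rule set needs in practice:

* **Recovery closure on return.** A recovery period also closes when the
  stream returns to the accepted phase itself. Without this, a short
  excursion (e.g. a two-sample blip of phase 3 inside a phase-1 run)
  would hold the recovery open until the next genuine successor
  transition and be misjudged as long.
* **Flicker arbitration.** Around a genuine boundary the classifier may
  oscillate between the accepted phase and its successor in bursts each
  shorter than the blip threshold. An in-order transition is therefore
  not accepted blindly: the machine scans the alternating bursts and
  sides with whichever of the two phases the stream settles into (first
  run lasting at least the blip threshold, or departure to a third
  phase). Premature successor blips are dropped; a genuine transition
  followed by brief backward flicker is kept at its first onset.

Phase and cycle duration averages come from the training reference
events of the same walking speed (complete 1-2-3-4-1 cycles only, at
least two required), not from online adaptation. The first event of a
stream is accepted unconditionally; a trailing recovery that never
closes cannot be judged and is discarded. The corrected output is
idempotent under re-application and is the identity on clean periodic
input.

## Evaluation

* **Sample accuracy**: correct windows / total windows × 100.
* **Confusion matrix**: row-normalized percent per reference phase; a
  reference phase absent from the track yields an undefined (NaN) row
  rather than zeros.
* **Event matching**: greedy chronological one-to-one matching of
  same-phase transitions within 33% of the mean reference cycle
  duration (configurable). Greedy matching on time-sorted same-phase
  lists attains maximum cardinality; the suite checks it against an
  exhaustive assignment oracle. Unmatched predictions are insertions,
  unmatched references deletions.
* **Scoring region**: the first event of either stream is a state
  marker, not a detected transition, and is excluded; unmatched events
  within one matching window of the classified span's edges are not
  counted as insertions/deletions because their counterpart may lie
  before the first or after the last classifiable window center.
* **Temporal error**: signed error is `ref − pred` (positive when the
  prediction leads); relative error divides the absolute error by the
  trial's mean stride duration.
* **ICC(A,k)**: two-way absolute-agreement average-measure intraclass
  correlation from the standard ANOVA decomposition, with the F-based
  95% interval (single-measure bounds stepped up by Spearman–Brown).
  Zero between-target variance makes the coefficient undefined (NaN);
  perfect agreement degenerates the interval to a point.
* **Cross-trial validation**: leave-one-trial-out within a
  subject × speed group; normalizer, discriminant and rule durations are
  fit on the training trials only.

## Synthetic cohort

`simulate.py` generates the walking protocol: per subject, five 60 s
trials at each of three slow treadmill speeds, sampled at 500 Hz on
8 channels. Defaults and their rationale:

* cycle duration 2.60 s (slow walking at 1–2 km/h), per-speed defaults
  3.0 / 2.6 / 2.2 s — the two outer values are interpolations around the
  pooled figure, as only the pooled stride duration is established;
* phase fractions 0.12 / 0.28 / 0.20 / 0.40 (stance ≈ 60% of the cycle,
  standard gait proportions);
* lognormal cycle durations with CV 0.05 (positive support, mild skew);
* per-channel envelopes: monotone piecewise-cubic (PCHIP) through knots
  at the phase boundaries, peak at ~90% of Pre-Swing, collapse within
  the first 10% of Swing; channels differ by uniform gains (0.8–1.2),
  small random peak offsets and knot perturbations;
* additive white Gaussian noise (SD 0.05 of the unit peak), sinusoidal
  baseline drift (< 0.5 Hz, amplitude 0.05) and per-cycle amplitude
  jitter (SD 0.03);
* each trial starts at a uniformly random position within a cycle, as a
  real acquisition would, with a state-marker event at `t = 0` carrying
  the in-progress phase;
* every trial derives from an independent child stream of one seed, so
  the whole cohort is reproducible bit-for-bit.

What the generator does *not* emulate: subject-specific or pathological
gait, muscle-physiological waveform detail, sensor nonlinearity and
hysteresis, band migration within a trial, or cross-talk between
sensors. End-to-end results on this cohort therefore demonstrate that
the pipeline recovers phases and transition times under the documented
signal morphology with realistic noise — a parameter-recovery check —
not that it attains any particular accuracy on human data.

On the default nine-subject cohort the leave-one-trial-out pipeline
reaches ~94% sample accuracy with zero insertions and sub-2% relative
temporal error (recomputed by `scripts/acceptance.py` and asserted, at
its thresholds, in `tests/test_acceptance.py`). The synthetic
inter-rater ICC uses two annotators reading each reference time with
independent one-frame (8 ms at 125 fps) Gaussian noise; because
transition times spread over a 60 s trial while rater noise is
milliseconds, the coefficient is necessarily very close to 1.

## Problem sizes and runtime

The acceptance script simulates the full 135-trial protocol
(4,050,000 raw samples) and validates all 135 folds in well under a
minute on one CPU; the test suite's end-to-end checks use the same
cohort. A 60 s trial yields 7,485 feature windows under the window-count
formula above (~125 Hz output; the nominal figure of 7.5 k windows per
trial rounds this).

## Known limitations

* The supervisory rules are causal in structure but the implementation
  processes complete trials; no bounded-latency streaming mode.
* The intermediate-recovery policy (relabel as successor) is the least
  constrained design point; other policies (e.g. proportional splitting)
  are plausible and would change behaviour only on mid-length recoveries.
* Event matching requires phase identity; a detector that systematically
  confuses two phases would register insertion/deletion pairs rather
  than label errors.
* `read_recording` infers the sampling rate from the time column and
  requires uniform sampling; irregularly sampled input is rejected, not
  resampled.
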