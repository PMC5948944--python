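# fmgait

Gait-phase detection from **force myography (FMG)**: a band of
force-sensing resistors strapped above the ankle senses the pressure
changes of the underlying muscles during walking, and this package turns
that multichannel force signal into the four gait phases of each stride —
Initial-Contact (1), Mid-Stance (2), Pre-Swing (3) and Swing (4) — together
with the precise times of the phase transitions.

It is aimed at wearable-sensing and gait-analysis researchers who want a
tested, scriptable reference pipeline for slow-walking phase detection
(the regime where inertial-sensor methods degrade), and who need every
stage — feature extraction, classification, event correction, evaluation —
available as a library function.

## Method

Given an `n_samples × n_channels` recording at sampling rate `f_s`
(defaults: 8 channels, 500 Hz):

1. **Windowed features.** A 125 ms sliding window advancing 8 ms extracts
   14 time-domain features per channel (RMS, SAV, MAV, VAR, WL, SSC, SSI,
   db7 wavelet detail mean, DASDV, AAC, log detector, linear-fit slope and
   the two leading parabolic-fit coefficients), giving a 125 Hz stream of
   112-dimensional feature vectors.
2. **Normalization.** Training-referenced min-max scaling,
   `x_norm = (x − min(X_train)) / (max(X_train) − min(X_train))`.
3. **Pseudolinear LDA.** Each window is classified into a phase by a
   linear discriminant with pooled within-class covariance `Σ` inverted in
   the Moore–Penrose sense (`Σ⁺`), scoring
   `xᵀΣ⁺μ_c − ½μ_cᵀΣ⁺μ_c + ln π_c` — the pseudoinverse makes the rule
   well-defined when the 112 correlated features render `Σ` singular.
4. **Supervisory rules.** A state machine repairs the label stream so
   transitions follow 1→2→3→4→1: out-of-order excursions shorter than half
   the average duration of the interrupted phase are discarded; stretches
   longer than an average gait cycle are promoted to a full synthesized
   cycle; intermediate ones are relabeled as the expected successor phase.
5. **Evaluation.** Sample-based accuracy, a row-normalized confusion
   matrix, phase insertions/deletions under time-window event matching
   (window = 33% of the mean reference cycle), signed/absolute/relative
   temporal errors, ICC(A,k) inter-rater agreement, and a
   leave-one-trial-out cross-validation harness.

No public FMG gait dataset accompanies the method, so the package bundles
a synthetic trial generator (`fmgait.simulate`) that reproduces the
signal's documented morphology — amplitude rising from Initial-Contact
through a late Pre-Swing peak, collapsing at toe-off, flat through Swing —
with per-channel gains, cycle-duration jitter, sensor noise and baseline
drift, plus exact ground-truth events.

## Worked example

```python
import fmgait as fg

# three synthetic 60 s treadmill speeds x 5 trials for one subject
cohort = fg.simulate_protocol(n_subjects=1, n_trials=5, seed=1)

run_cfg = fg.RunConfig()                     # 125 ms window, 8 ms step
groups = {}
for rec, events in cohort:
    groups.setdefault(rec.speed_label, []).append(
        fg.trial_from_recording(rec, events, run_cfg))

reports = []
for speed, trials in groups.items():
    reports.extend(fg.cross_trial_validation(trials))
print(fg.mean_report(reports))
```

prints (exact values depend on the seed):

```
{'mean_sample_accuracy_pct': 94.4929859719439, 'sd_sample_accuracy_pct': 1.2426717093420565,
 'n_insertions': 0, 'n_deletions': 0, 'n_correct_phases': 1402,
 'mean_abs_error_ms': 34.81563347766645, 'mean_rel_error_pct': 1.3374586201107412}
```

Reading: across the 15 leave-one-trial-out folds, 94.5% of the 125 Hz
feature samples received the correct phase; every one of the 1,402 scored
phase segments was detected (no spurious or missed segments); and the
detected transition times deviate from ground truth by 35 ms on average,
i.e. 1.3% of a stride.

The same pipeline is scriptable from a shell:

```
fmgait simulate trials/ --seed 1 --trials 5
fmgait pipeline --simulate --seed 1 -o run/
fmgait features trials/S1_speed1_T1_rec.csv -o features.csv
```

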