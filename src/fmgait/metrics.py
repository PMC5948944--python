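"""Evaluation statistics for gait-phase detection.

Sample-based accuracy (percent of feature samples whose predicted phase
matches the reference), a row-normalized 4x4 confusion matrix, phase-based
accuracy via time-window matching of transition events (unmatched
predictions are *insertions*, unmatched references are *deletions*),
signed/absolute/relative temporal errors of matched transitions, the
intraclass correlation ICC(A,k) for inter-rater timestamp agreement, and a
leave-one-trial-out cross-validation harness tying the pipeline together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import events as ev
from . import features as ft
from . import lda as ld
from .io import EventList, LabelTrack, PHASES, RunConfig, labels_from_events


class MetricError(ValueError):
    pass


@dataclass
class MatchingConfig:
    """Events match when same-phase start times differ by at most
    ``match_window_fraction`` of the average reference cycle duration."""

    match_window_fraction: float = 0.33

    def __post_init__(self) -> None:
        if not (0 < self.match_window_fraction <= 1):
            raise ValueError("match_window_fraction must lie in (0, 1]")


@dataclass
class EvaluationReport:
    sample_accuracy: float                     # percent
    confusion: np.ndarray                      # 4x4, rows percent (NaN if absent)
    n_insertions: int
    n_deletions: int
    n_correct_phases: int
    signed_errors: dict = field(default_factory=dict)   # phase -> seconds array
    mean_abs_error_s: float = float("nan")
    mean_rel_error_pct: float = float("nan")
    subject_id: str = ""
    trial_id: str = ""
    speed_label: str = ""

    def per_phase_table(self) -> pd.DataFrame:
        rows = []
        for p in PHASES:
            e = np.asarray(self.signed_errors.get(p, []), dtype=float)
            rows.append({
                "phase": p,
                "n_matched": e.size,
                "mean_signed_s": e.mean() if e.size else np.nan,
                "mean_abs_s": np.abs(e).mean() if e.size else np.nan,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample-based metrics
# ---------------------------------------------------------------------------

def sample_accuracy(pred, ref) -> float:
    """Percent of samples whose predicted phase equals the reference."""
    p = pred.labels if isinstance(pred, LabelTrack) else np.asarray(pred)
    r = ref.labels if isinstance(ref, LabelTrack) else np.asarray(ref)
    if p.shape != r.shape:
        raise MetricError(f"length mismatch: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise MetricError("empty label tracks")
    return float(np.count_nonzero(p == r) / p.size * 100.0)


def confusion(pred, ref) -> np.ndarray:
    """Row-normalized confusion matrix in percent.

    Row r, column c: percent of reference-phase-r samples predicted as
    phase c.  Rows of reference phases absent from ``ref`` are NaN.
    """
    p = pred.labels if isinstance(pred, LabelTrack) else np.asarray(pred)
    r = ref.labels if isinstance(ref, LabelTrack) else np.asarray(ref)
    if p.shape != r.shape:
        raise MetricError(f"length mismatch: {p.shape} vs {r.shape}")
    out = np.full((4, 4), np.nan)
    for i, phase_r in enumerate(PHASES):
        mask = r == phase_r
        if not mask.any():
            continue
        for j, phase_p in enumerate(PHASES):
            out[i, j] = np.count_nonzero(p[mask] == phase_p) / mask.sum() * 100.0
    return out


# ---------------------------------------------------------------------------
# Phase-based (event) metrics
# ---------------------------------------------------------------------------

def mean_cycle_duration(reference: EventList) -> float:
    """Average stride duration from intervals between consecutive
    same-phase reference events."""
    gaps = []
    for p in PHASES:
        t = reference.times[reference.phases == p]
        if t.size >= 2:
            gaps.extend(np.diff(t).tolist())
    if not gaps:
        raise MetricError("reference events span fewer than two cycles")
    return float(np.mean(gaps))


def match_events(pred: EventList, ref: EventList,
                 cfg: MatchingConfig = MatchingConfig(),
                 window_override: float | None = None):
    """Greedy chronological one-to-one matching of same-phase events.

    The tolerance is ``match_window_fraction`` of the average reference
    cycle duration unless ``window_override`` gives it in seconds.
    Returns ``(pairs, insertions, deletions)`` where ``pairs`` is a list
    of ``(pred_index, ref_index)``, insertions are unmatched predicted
    event indices and deletions unmatched reference event indices.
    """
    if len(ref) == 0:
        raise MetricError("reference event list is empty")
    window = (window_override if window_override is not None
              else cfg.match_window_fraction * mean_cycle_duration(ref))
    pairs: list[tuple[int, int]] = []
    used_ref: set[int] = set()
    for ip in range(len(pred)):
        tp, pp = pred.times[ip], pred.phases[ip]
        best = None
        for ir in range(len(ref)):
            if ir in used_ref or ref.phases[ir] != pp:
                continue
            if abs(ref.times[ir] - tp) <= window:
                best = ir
                break                      # earliest unmatched candidate
        if best is not None:
            used_ref.add(best)
            pairs.append((ip, best))
    insertions = [i for i in range(len(pred)) if i not in {p for p, _ in pairs}]
    deletions = [i for i in range(len(ref)) if i not in used_ref]
    return pairs, insertions, deletions


def temporal_errors(pred: EventList, ref: EventList, pairs,
                    mean_stride_s: float) -> dict:
    """Per-phase signed errors (seconds) of matched transition pairs.

    Signed error is ``ref_time - pred_time``: positive when the predicted
    event precedes the reference.  Relative error is the absolute error
    over the mean stride duration, in percent.
    """
    per_phase: dict[int, list[float]] = {p: [] for p in PHASES}
    for ip, ir in pairs:
        per_phase[int(ref.phases[ir])].append(
            float(ref.times[ir] - pred.times[ip]))
    out = {p: np.asarray(v) for p, v in per_phase.items() if v}
    return out


def summarize_errors(signed_errors: dict, mean_stride_s: float):
    """(mean absolute error [s], mean relative error [%]) over all phases."""
    allv = np.concatenate([v for v in signed_errors.values()]) \
        if signed_errors else np.empty(0)
    if allv.size == 0:
        return float("nan"), float("nan")
    mean_abs = float(np.abs(allv).mean())
    return mean_abs, mean_abs / mean_stride_s * 100.0


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

def icc_a_k(ratings, alpha: float = 0.05):
    """ICC, absolute agreement, average of k raters, two-way model.

    ``ratings`` is an ``n_targets x k`` matrix with no missing cells.
    Returns ``(icc, (ci_lower, ci_upper))``; the interval uses the
    standard F-based construction.  With zero between-target variance the
    coefficient is undefined and NaN is returned.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 3 or Y.shape[1] < 2:
        raise MetricError("ratings must be at least 3 targets x 2 raters")
    if not np.all(np.isfinite(Y)):
        raise MetricError("ratings contain missing cells")
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        return float("nan"), (float("nan"), float("nan"))
    icc = (msr - mse) / (msr + (msc - mse) / n)

    # CI: single-measure ICC(A,1) bounds, then Spearman-Brown step-up to k
    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse <= 0 or icc1 >= 1:      # perfect agreement: interval degenerates
        return float(icc), (float(icc), float(icc))
    a = k * icc1 / (n * (1 - icc1))
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr)
    step = lambda r: k * r / (1 + (k - 1) * r)
    return float(icc), (float(step(lo1)), float(step(hi1)))


# ---------------------------------------------------------------------------
# Cross-trial validation
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    """Everything the harness needs about one recorded trial."""

    features: ft.FeatureMatrix
    labels: LabelTrack                 # per-window reference labels
    ref_events: EventList
    subject_id: str = ""
    trial_id: str = ""
    speed_label: str = ""


def trial_from_recording(rec, ref_events: EventList,
                         run_cfg: RunConfig) -> Trial:
    """Window a recording and rasterize its reference events onto the
    window centers, packaging both for the validation harness."""
    F = ft.sliding_features(rec, run_cfg)
    labels = labels_from_events(ref_events, F.window_centers)
    return Trial(F, labels, ref_events, subject_id=rec.subject_id,
                 trial_id=rec.trial_id, speed_label=rec.speed_label)


def _drop_stream_start(events: EventList) -> EventList:
    """The first event of a transition list marks the stream's initial
    state, not a detected transition; it is excluded from event scoring."""
    return EventList(events.times[1:], events.phases[1:])


def evaluate_trial(pred_labels: LabelTrack, trial: Trial,
                   rule_cfg: ev.RuleConfig,
                   match_cfg: MatchingConfig = MatchingConfig()) -> EvaluationReport:
    """Full per-trial evaluation of predicted window labels.

    Event scoring excludes the stream-start marker of both the predicted
    and the reference list (neither is a detected transition).  Unmatched
    events within one matching window of the classified span's edges are
    not counted as insertions or deletions: their counterpart may fall in
    the region no windowed detector observes.
    """
    acc = sample_accuracy(pred_labels, trial.labels)
    conf = confusion(pred_labels, trial.labels)
    corrected = ev.apply_rules(ev.raw_transitions(pred_labels), rule_cfg)
    pred_ev = _drop_stream_start(corrected)
    ref_ev = _drop_stream_start(trial.ref_events)
    stride = mean_cycle_duration(ref_ev)
    window = match_cfg.match_window_fraction * stride
    pairs, ins, dels = match_events(pred_ev, ref_ev, match_cfg,
                                    window_override=window)
    t_lo = pred_labels.timestamps[0] + window
    t_hi = pred_labels.timestamps[-1] - window
    ins = [i for i in ins if t_lo <= pred_ev.times[i] <= t_hi]
    dels = [i for i in dels if t_lo <= ref_ev.times[i] <= t_hi]
    errs = temporal_errors(pred_ev, ref_ev, pairs, stride)
    mean_abs, mean_rel = summarize_errors(errs, stride)
    return EvaluationReport(acc, conf, len(ins), len(dels), len(pairs),
                            errs, mean_abs, mean_rel,
                            subject_id=trial.subject_id,
                            trial_id=trial.trial_id,
                            speed_label=trial.speed_label)


def cross_trial_validation(trials, priors=None,
                           short_fraction: float = 0.5,
                           long_multiple: float = 1.0,
                           match_cfg: MatchingConfig = MatchingConfig()):
    """Leave-one-trial-out validation over same-speed trials.

    For each fold the min-max normalizer, the discriminant, and the rule
    durations are fit on the training trials only; the held-out trial is
    evaluated end to end.  Returns the per-fold reports.
    """
    if len(trials) < 2:
        raise MetricError("cross-trial validation needs at least 2 trials")
    reports = []
    for i, test in enumerate(trials):
        train = [t for j, t in enumerate(trials) if j != i]
        X_train = np.vstack([t.features.values for t in train])
        y_train = np.concatenate([t.labels.labels for t in train])
        stats = ft.fit_normalizer(X_train)
        model = ld.fit(ft.normalize(X_train, stats), y_train, priors=priors,
                       norm_stats=stats)
        # durations pooled over training trials (each trial separately,
        # then averaged, to avoid stitching across trial boundaries)
        cfgs = [ev.estimate_durations(t.ref_events, short_fraction,
                                      long_multiple) for t in train]
        rule_cfg = ev.RuleConfig(
            np.mean([c.avg_phase_duration for c in cfgs], axis=0),
            float(np.mean([c.avg_cycle_duration for c in cfgs])),
            short_fraction=short_fraction, long_multiple=long_multiple)
        pred = ld.predict(model, ft.normalize(test.features.values, stats))
        pred_track = LabelTrack(pred, test.labels.timestamps)
        reports.append(evaluate_trial(pred_track, test, rule_cfg, match_cfg))
    return reports


def mean_report(reports) -> dict:
    """Aggregate fold reports into cohort-level summary numbers."""
    accs = np.array([r.sample_accuracy for r in reports])
    abss = np.array([r.mean_abs_error_s for r in reports])
    rels = np.array([r.mean_rel_error_pct for r in reports])
    return {
        "mean_sample_accuracy_pct": float(np.nanmean(accs)),
        "sd_sample_accuracy_pct": float(np.nanstd(accs, ddof=1)) if accs.size > 1 else 0.0,
        "n_insertions": int(sum(r.n_insertions for r in reports)),
        "n_deletions": int(sum(r.n_deletions for r in reports)),
        "n_correct_phases": int(sum(r.n_correct_phases for r in reports)),
        "mean_abs_error_ms": float(np.nanmean(abss) * 1000.0),
        "mean_rel_error_pct": float(np.nanmean(rels)),
    }
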