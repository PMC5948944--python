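"""Accuracy, confusion, event matching, temporal errors, ICC, validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fmgait as fg
from fmgait import metrics as mt


# ---------------------------------------------------------------------------
# Sample accuracy and confusion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pred,ref,expected", [
    ([1] * 9 + [2], [1] * 10, 90.0),
    ([1, 2, 3, 4], [1, 2, 3, 4], 100.0),
    ([1, 1], [2, 2], 0.0),
])
def test_sample_accuracy_closed_forms(pred, ref, expected):
    assert mt.sample_accuracy(np.array(pred), np.array(ref)) == expected


def test_sample_accuracy_self_is_100(rng):
    y = rng.integers(1, 5, size=50)
    assert mt.sample_accuracy(y, y) == 100.0


def test_sample_accuracy_length_mismatch():
    with pytest.raises(mt.MetricError):
        mt.sample_accuracy(np.array([1, 2]), np.array([1]))


def test_confusion_perfect_is_identity(rng):
    y = np.repeat([1, 2, 3, 4], 5)
    np.testing.assert_allclose(mt.confusion(y, y), np.eye(4) * 100)


def test_confusion_half_split_row():
    ref = np.full(10, 2)
    pred = np.r_[np.ones(5, int), np.full(5, 3)]
    C = mt.confusion(pred, ref)
    np.testing.assert_allclose(C[1], [50, 0, 50, 0])
    assert np.isnan(C[0]).all() and np.isnan(C[2]).all() and np.isnan(C[3]).all()


def test_confusion_matches_bruteforce(rng):
    pred = rng.integers(1, 5, size=200)
    ref = rng.integers(1, 5, size=200)
    C = mt.confusion(pred, ref)
    for r in (1, 2, 3, 4):
        for c in (1, 2, 3, 4):
            n_r = np.count_nonzero(ref == r)
            expected = np.count_nonzero((ref == r) & (pred == c)) / n_r * 100
            assert C[r - 1, c - 1] == pytest.approx(expected)
    # rows of present phases sum to 100
    np.testing.assert_allclose(np.nansum(C, axis=1), 100.0)


# ---------------------------------------------------------------------------
# Event matching
# ---------------------------------------------------------------------------

def bruteforce_best_matching(pred, ref, window):
    """Exhaustive maximum-cardinality same-phase matching (<= 8 events)."""
    cand = [(i, j) for i in range(len(pred)) for j in range(len(ref))
            if pred.phases[i] == ref.phases[j]
            and abs(pred.times[i] - ref.times[j]) <= window]
    best = 0
    for r in range(len(cand), 0, -1):
        for combo in itertools.combinations(cand, r):
            ps = [c[0] for c in combo]
            rs = [c[1] for c in combo]
            if len(set(ps)) == r and len(set(rs)) == r:
                return r
    return best


def test_match_identical_lists(clean_cycle_events):
    pairs, ins, dels = mt.match_events(clean_cycle_events, clean_cycle_events)
    assert len(pairs) == len(clean_cycle_events)
    assert ins == [] and dels == []


def test_match_missing_phase2_is_deletion(clean_cycle_events):
    ref = clean_cycle_events
    keep = ~((ref.phases == 2) & (np.arange(len(ref)) == 1))
    pred = fg.EventList(ref.times[keep], ref.phases[keep])
    pairs, ins, dels = mt.match_events(pred, ref)
    assert len(ins) == 0
    assert len(dels) == 1
    assert ref.phases[dels[0]] == 2


def test_match_symmetry_swaps_insertions_and_deletions(clean_cycle_events):
    ref = clean_cycle_events
    keep = np.arange(len(ref)) != 5
    pred = fg.EventList(ref.times[keep], ref.phases[keep])
    _, ins_a, dels_a = mt.match_events(pred, ref)
    _, ins_b, dels_b = mt.match_events(ref, pred)
    assert len(ins_a) == len(dels_b) and len(dels_a) == len(ins_b)


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_match_cardinality_equals_exhaustive_oracle(data):
    n_p = data.draw(st.integers(1, 8))
    n_r = data.draw(st.integers(1, 8))
    tp = sorted(data.draw(st.lists(st.floats(0, 20), min_size=n_p,
                                   max_size=n_p, unique=True)))
    tr = sorted(data.draw(st.lists(st.floats(0, 20), min_size=n_r,
                                   max_size=n_r, unique=True)))
    pp = data.draw(st.lists(st.integers(1, 4), min_size=n_p, max_size=n_p))
    pr = data.draw(st.lists(st.integers(1, 4), min_size=n_r, max_size=n_r))
    pred = fg.EventList(np.array(tp), np.array(pp))
    ref = fg.EventList(np.array(tr), np.array(pr))
    window = 1.5
    pairs, ins, dels = mt.match_events(
        pred, ref, mt.MatchingConfig(0.5), window_override=window)
    assert len(pairs) == bruteforce_best_matching(pred, ref, window)
    assert len(pairs) + len(ins) == len(pred)
    assert len(pairs) + len(dels) == len(ref)


# ---------------------------------------------------------------------------
# Temporal errors
# ---------------------------------------------------------------------------

def test_temporal_error_sign_and_relative():
    ref = fg.EventList.from_pairs([(1.00, 1), (3.5, 1)])
    pred = fg.EventList.from_pairs([(0.95, 1), (3.5, 1)])
    pairs, _, _ = mt.match_events(pred, ref)
    errs = mt.temporal_errors(pred, ref, pairs, 2.5)
    np.testing.assert_allclose(sorted(errs[1]), [0.0, 0.05])
    mean_abs, mean_rel = mt.summarize_errors(errs, 2.5)
    assert mean_abs == pytest.approx(0.025)
    assert mean_rel == pytest.approx(1.0)      # percent of the 2.5 s stride


def test_uniform_shift_gives_constant_signed_error(clean_cycle_events):
    ref = clean_cycle_events
    delta = 0.05
    pred = fg.EventList(ref.times - delta, ref.phases)
    pairs, _, _ = mt.match_events(pred, ref)
    errs = mt.temporal_errors(pred, ref, pairs, 2.6)
    for v in errs.values():
        np.testing.assert_allclose(v, delta)


def test_relative_error_of_injected_jitter(rng):
    """±50 ms jitter on a 2.60 s stride gives a 1.9% relative error."""
    times = np.cumsum(rng.uniform(0.5, 0.8, size=400))
    phases = np.tile([1, 2, 3, 4], 100)
    ref = fg.EventList(times, phases)
    jitter = rng.choice([-0.05, 0.05], size=400)
    pred = fg.EventList(times + jitter, phases)
    pairs, ins, dels = mt.match_events(pred, ref)
    assert not ins and not dels
    errs = mt.temporal_errors(pred, ref, pairs, 2.60)
    _, mean_rel = mt.summarize_errors(errs, 2.60)
    assert mean_rel == pytest.approx(0.05 / 2.60 * 100, rel=1e-9)


# ---------------------------------------------------------------------------
# ICC(A,k)
# ---------------------------------------------------------------------------

def test_icc_identical_raters_is_one(rng):
    col = rng.normal(size=20)
    icc, (lo, hi) = mt.icc_a_k(np.c_[col, col])
    assert icc == pytest.approx(1.0)
    assert hi == pytest.approx(1.0)


def test_icc_pure_noise_near_zero(rng):
    a = rng.normal(size=500, scale=0.01)
    b = a + rng.normal(size=500, scale=10.0)
    icc, _ = mt.icc_a_k(np.c_[a, b])
    assert abs(icc) < 0.2


def test_icc_matches_bruteforce_anova(rng):
    Y = rng.normal(size=(10, 2))
    icc, _ = mt.icc_a_k(Y)
    n, k = Y.shape
    # brute-force two-way ANOVA table from raw sums of squares
    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = sum((Y[i, j] - Y.mean(axis=1)[i] - Y.mean(axis=0)[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (msc - mse) / n)
    assert icc == pytest.approx(expected)


def test_icc_matches_pingouin(rng):
    import pandas as pd
    import pingouin as pg
    Y = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1)) * 3
    icc, (lo, hi) = mt.icc_a_k(Y)
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(30), 2),
        "raters": np.tile([0, 1], 30),
        "scores": Y.ravel(),
    })
    row = pg.intraclass_corr(df, targets="targets", raters="raters",
                             ratings="scores").set_index("Type").loc["ICC(A,k)"]
    assert icc == pytest.approx(row["ICC"], abs=1e-9)
    np.testing.assert_allclose([lo, hi], row["CI95"], atol=0.015)


def test_icc_affine_invariance(rng):
    Y = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1)) * 2
    icc, _ = mt.icc_a_k(Y)
    icc2, _ = mt.icc_a_k(Y * 3.7 + 11.0)
    assert icc2 == pytest.approx(icc)


def test_icc_input_validation():
    with pytest.raises(mt.MetricError):
        mt.icc_a_k(np.ones((2, 2)))
    with pytest.raises(mt.MetricError):
        mt.icc_a_k(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


def test_icc_zero_row_variance_undefined():
    Y = np.tile([[1.0, 2.0]], (5, 1))
    icc, _ = mt.icc_a_k(Y)
    assert np.isnan(icc)


# ---------------------------------------------------------------------------
# Cross-trial validation
# ---------------------------------------------------------------------------

def _toy_trials(n, seed=0, identical=False):
    cfg = fg.SimConfig(trial_s=12.0, noise_sd=0.03, seed=seed)
    rc = fg.RunConfig()
    out = []
    for i in range(n):
        rec, evs = fg.simulate_trial(cfg, seed if identical else seed + i,
                                     trial_id=f"T{i+1}")
        out.append(fg.trial_from_recording(rec, evs, rc))
    return out


def test_fold_count_equals_trial_count():
    trials = _toy_trials(3)
    reports = fg.cross_trial_validation(trials)
    assert len(reports) == 3


def test_identical_trials_give_identical_folds():
    trials = _toy_trials(3, identical=True)
    reports = fg.cross_trial_validation(trials)
    accs = [r.sample_accuracy for r in reports]
    assert accs[0] == pytest.approx(accs[1]) == pytest.approx(accs[2])


def test_validation_requires_two_trials():
    with pytest.raises(mt.MetricError):
        fg.cross_trial_validation(_toy_trials(1))


def test_no_leakage_between_folds(rng):
    """Shuffling one trial's labels only changes that trial's fold."""
    trials = _toy_trials(4, seed=3)
    base = fg.cross_trial_validation(trials)
    perm = rng.permutation(len(trials[0].labels))
    corrupted = fg.Trial(
        trials[0].features,
        fg.LabelTrack(trials[0].labels.labels[perm],
                      trials[0].labels.timestamps),
        trials[0].ref_events, trial_id=trials[0].trial_id)
    # fold 0 trains on trials 1..3 only: corrupting trial 0's labels
    # must leave every *other* fold's training set changed but fold 0's
    # own report reflects only its evaluation labels
    mixed = fg.cross_trial_validation([corrupted] + trials[1:])
    assert mixed[0].sample_accuracy != pytest.approx(base[0].sample_accuracy)


def test_mean_report_aggregates(rng):
    trials = _toy_trials(3, seed=5)
    reports = fg.cross_trial_validation(trials)
    agg = fg.mean_report(reports)
    assert agg["mean_sample_accuracy_pct"] == pytest.approx(
        np.mean([r.sample_accuracy for r in reports]))
    assert agg["n_insertions"] == sum(r.n_insertions for r in reports)
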