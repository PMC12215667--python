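"""Metrics identities, phase partitioning, and Mann-Whitney against
first-principles oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from math import comb

from ltadetect.evalstats import (
    compare_models,
    compute_metrics,
    partition_phases,
    summarize_runs,
)


def _vectors_from_counts(tp, fn, tn, fp):
    t = np.concatenate([np.ones(tp + fn, int), np.zeros(tn + fp, int)])
    p = np.concatenate([np.ones(tp, int), np.zeros(fn, int),
                        np.zeros(tn, int), np.ones(fp, int)])
    return t, p


@pytest.mark.parametrize("counts,se,sp,ber", [
    ((9268, 732, 9948, 52), 92.68, 99.48, 3.92),
    ((8581, 1419, 9888, 112), 85.81, 98.88, 7.65),
    ((9600, 400, 99860, 140), 96.00, 99.86, 2.07),
    ((5983, 4017, 9043, 957), 59.83, 90.43, 24.87),
])
def test_metric_identities_from_confusion_counts(counts, se, sp, ber):
    """BER = 100 - (Se + Sp)/2 reproduced from realized confusion counts.

    Comparison at the printed two-decimal precision (one BER sits exactly
    on a rounding boundary: 7.655)."""
    rep = compute_metrics(*_vectors_from_counts(*counts))
    assert rep.se == pytest.approx(se, abs=0.005)
    assert rep.sp == pytest.approx(sp, abs=0.005)
    assert rep.ber == pytest.approx(ber, abs=0.00501)


def test_perfect_prediction():
    t = np.array([1, 1, 0, 0, 1])
    rep = compute_metrics(t, t)
    assert (rep.se, rep.sp, rep.acc, rep.ber) == (100.0, 100.0, 100.0, 0.0)
    assert rep.kappa == 1.0 and rep.mf1 == 100.0 and rep.wf1 == 100.0
    assert rep.aha_compliant


def test_metrics_against_first_principles_oracle():
    """Random instance vs an oracle built from nothing but the confusion
    matrix and the textbook formulas for kappa and F1."""
    rng = np.random.default_rng(7)
    t = rng.integers(0, 2, 200)
    p = rng.integers(0, 2, 200)
    rep = compute_metrics(t, p)
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    n = 200
    se = 100 * tp / (tp + fn)
    sp = 100 * tn / (tn + fp)
    acc = 100 * (tp + tn) / n
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe)
    f1_pos = 2 * tp / (2 * tp + fp + fn)
    f1_neg = 2 * tn / (2 * tn + fn + fp)
    mf1 = 100 * (f1_pos + f1_neg) / 2
    wf1 = 100 * ((tp + fn) * f1_pos + (tn + fp) * f1_neg) / n
    assert rep.se == pytest.approx(se) and rep.sp == pytest.approx(sp)
    assert rep.acc == pytest.approx(acc)
    assert rep.kappa == pytest.approx(kappa)
    assert rep.mf1 == pytest.approx(mf1) and rep.wf1 == pytest.approx(wf1)
    assert rep.ber == pytest.approx(100 - (se + sp) / 2)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ber_plus_bac_is_100(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 2, 50)
    p = rng.integers(0, 2, 50)
    if len(np.unique(t)) < 2:
        t[0], t[1] = 0, 1
    rep = compute_metrics(t, p)
    assert rep.ber + rep.bac == pytest.approx(100.0)
    assert rep.bac == pytest.approx((rep.se + rep.sp) / 2)


def test_mf1_symmetric_under_class_swap_and_weighting_matters():
    """MF1 is invariant under swapping the class labels on both truth and
    prediction (per-class F1 values trade places).  wF1 is also invariant
    under that swap — the supports trade places with the F1 values — but it
    differs from MF1 whenever supports are unequal, which is the point of
    reporting both."""
    rng = np.random.default_rng(1)
    t = (rng.random(120) < 0.25).astype(int)  # unequal supports
    p = (rng.random(120) < 0.3).astype(int)
    a = compute_metrics(t, p)
    b = compute_metrics(1 - t, 1 - p)
    assert a.mf1 == pytest.approx(b.mf1)
    assert a.wf1 == pytest.approx(b.wf1)
    assert a.wf1 != pytest.approx(a.mf1)
    # equal supports make the two averages coincide
    t_eq = np.array([1] * 30 + [0] * 30)
    p_eq = np.concatenate([rng.integers(0, 2, 60)])
    r = compute_metrics(t_eq, p_eq)
    rs = compute_metrics(1 - t_eq, 1 - p_eq)
    assert r.mf1 == pytest.approx(rs.mf1)


def test_absent_class_reports_nan_not_zero():
    rep = compute_metrics(np.ones(10, int), np.ones(10, int))
    assert np.isnan(rep.sp) and np.isnan(rep.ber) and np.isnan(rep.kappa)
    assert rep.se == 100.0


def test_mask_and_validation():
    t = np.array([1, 0, 1, 0])
    p = np.array([1, 0, 0, 0])
    rep = compute_metrics(t, p, mask=np.array([True, True, False, True]))
    assert rep.se == 100.0
    with pytest.raises(ValueError, match="length"):
        compute_metrics(t, p[:3])
    with pytest.raises(ValueError, match="unmasked"):
        compute_metrics(t, p, mask=np.zeros(4, bool))


def test_phase_partition_worked_example():
    (phase,) = partition_phases([np.array([0, 0, 0, 0, 1, 1, 1, 1])])
    assert list(np.flatnonzero(phase)) == [1, 2, 3, 4, 5, 6]
    assert list(np.flatnonzero(~phase)) == [0, 7]


def test_phase_partition_constant_labels_all_stationary():
    (phase,) = partition_phases([np.ones(10, int)])
    assert not phase.any()


def test_phase_partition_exclusive_reading():
    (phase,) = partition_phases([np.array([0, 0, 0, 0, 1, 1, 1, 1])],
                                include_change_segment=False)
    assert list(np.flatnonzero(phase)) == [1, 2, 3, 5, 6, 7]


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_phase_partition_matches_brute_force_union(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=rng.integers(2, 30))
    (phase,) = partition_phases([labels])
    expect = set()
    for c in range(1, len(labels)):
        if labels[c] != labels[c - 1]:
            expect |= {i for i in range(c - 3, c + 3) if 0 <= i < len(labels)}
    assert set(np.flatnonzero(phase)) == expect


def test_phases_do_not_cross_recording_boundaries():
    a = np.array([0, 0, 1, 1])
    b = np.array([1, 1, 1, 1])
    pa, pb = partition_phases([a, b])
    assert pa.any() and not pb.any()  # b sees no change from a's tail


def test_compare_identical_samples_symmetric():
    a = [1.0, 2.0, 3.0, 4.0]
    res = compare_models(a, list(a), "greater")
    assert res.u == len(a) ** 2 / 2
    assert res.r == 0.0


def test_compare_complete_separation():
    a = list(np.arange(10) + 100.0)
    b = list(np.arange(10) + 0.0)
    res = compare_models(a, b, "greater")
    assert res.u == 100.0 and res.r == -1.0
    assert res.p == pytest.approx(1 / comb(20, 10))
    assert res.significant


def test_compare_direction_for_error_metrics():
    low = [1.0, 1.1, 0.9, 1.2, 0.8]
    high = [5.0, 5.2, 4.8, 5.1, 4.9]
    assert compare_models(low, high, "less", metric="ber").significant
    assert not compare_models(high, low, "less").significant


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_exact_p_matches_exhaustive_enumeration(seed):
    """p equals enumeration over all C(12,6) group assignments, ties included."""
    rng = np.random.default_rng(seed)
    pooled = rng.integers(0, 5, size=12).astype(float)  # coarse values force ties
    a, b = pooled[:6], pooled[6:]
    res = compare_models(a, b, "greater")
    if np.isnan(res.p):
        return  # degenerate constant case
    count = 0
    u_obs = float(np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))
    for idx in combinations(range(12), 6):
        ga = pooled[list(idx)]
        gb = pooled[[i for i in range(12) if i not in idx]]
        u = float(np.sum(ga[:, None] > gb[None, :]) + 0.5 * np.sum(ga[:, None] == gb[None, :]))
        count += u >= u_obs - 1e-9
    assert res.p == pytest.approx(count / comb(12, 6))


def test_compare_constant_identical_samples_warns():
    with pytest.warns(UserWarning, match="identical"):
        res = compare_models([1.0] * 5, [1.0] * 5, "greater")
    assert np.isnan(res.p) and not res.significant


def test_summarize_runs_formatting():
    r1 = compute_metrics(*_vectors_from_counts(90, 10, 90, 10))
    r2 = compute_metrics(*_vectors_from_counts(92, 8, 92, 8))
    table = summarize_runs([r1, r2])
    assert table["se"][2] == "91.00 (1.41)"
    same = summarize_runs([r1, r1])
    assert same["se"][2] == "90.00 (0.00)"


def test_summarize_against_mean_sd_oracle():
    rng = np.random.default_rng(9)
    reports = [compute_metrics(rng.integers(0, 2, 100), rng.integers(0, 2, 100))
               for _ in range(10)]
    table = summarize_runs(reports)
    vals = [r.acc for r in reports]
    assert table["acc"][0] == pytest.approx(np.mean(vals))
    assert table["acc"][1] == pytest.approx(np.std(vals, ddof=1))
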