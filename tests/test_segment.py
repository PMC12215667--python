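"""Sequence construction, label majority rule, splits, batch balancing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltadetect.ecg_io import EcgRecord, RhythmAnnotationTrack
from ltadetect.rhythms import LTA_CODES, RhythmCode
from ltadetect.segment import (
    SEQUENCE_LEN,
    RecordExcluded,
    plan_balanced_batches,
    segment_recording,
    split_subjects,
    truncate_pt_recording,
)


def _rec(n, subject="s"):
    return EcgRecord(subject, np.zeros(n), 200)


def _track(*entries):
    return RhythmAnnotationTrack([(o, c) for o, c in entries])


def test_all_sinus_record_gives_other_labels():
    seqs = segment_recording(_rec(3584), _track((0, RhythmCode.SINUS)))
    assert len(seqs) == 2
    assert sum(s.segment_labels.sum() for s in seqs) == 0
    assert all(s.segment_mask.all() for s in seqs)
    assert [s.start_sample for s in seqs] == [0, 1792]


def test_majority_rule_mixed_segment():
    # 154 samples of VF + 102 of sinus within one segment -> LTA wins
    track = _track((0, RhythmCode.VF), (154, RhythmCode.SINUS))
    seqs = segment_recording(_rec(1792), track)
    assert seqs[0].segment_labels[0] == 1


def test_majority_tie_resolves_to_lta():
    track = _track((0, RhythmCode.VF), (128, RhythmCode.SINUS))
    seqs = segment_recording(_rec(1792), track)
    assert seqs[0].segment_labels[0] == 1


def test_noise_segments_masked_not_deleted():
    # noise covering segments 3-4 of a single sequence
    track = _track((0, RhythmCode.SINUS), (3 * 256, RhythmCode.NOISE),
                   (5 * 256, RhythmCode.SINUS))
    seqs = segment_recording(_rec(1792), track)
    assert len(seqs) == 1
    assert list(seqs[0].segment_mask) == [True, True, True, False, False, True, True]
    assert len(seqs[0].segment_labels) == 7


def test_short_record_warns_and_yields_nothing():
    with pytest.warns(UserWarning, match="samples"):
        assert segment_recording(_rec(1000), _track((0, RhythmCode.SINUS))) == []


def test_trailing_remainder_dropped():
    seqs = segment_recording(_rec(1792 + 700), _track((0, RhythmCode.SINUS)))
    assert len(seqs) == 1


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_segment_labels_match_per_sample_vote_oracle(seed):
    """Brute force: label every sample from the annotation track, then take
    per-segment majority (LTA >= Other > Noise-only) — must agree with the
    implementation on random tracks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 4)) * SEQUENCE_LEN
    codes = list(RhythmCode)
    onsets = np.unique(rng.integers(0, n, size=rng.integers(1, 8)))
    if onsets[0] != 0:
        onsets = np.concatenate([[0], onsets])
    entries = [(int(o), codes[rng.integers(len(codes))]) for o in onsets]
    track = RhythmAnnotationTrack(entries)
    # oracle: per-sample class codes
    per_sample = np.empty(n, dtype=object)
    for i, (o, c) in enumerate(entries):
        stop = entries[i + 1][0] if i + 1 < len(entries) else n
        per_sample[o:stop] = c
    seqs = segment_recording(_rec(n), track)
    for s, seq in enumerate(seqs):
        for k in range(7):
            chunk = per_sample[s * SEQUENCE_LEN + k * 256 : s * SEQUENCE_LEN + (k + 1) * 256]
            lta = sum(1 for c in chunk if c in LTA_CODES)
            noise = sum(1 for c in chunk if c is RhythmCode.NOISE)
            other = len(chunk) - lta - noise
            if noise > max(lta, other):
                assert not seq.segment_mask[k]
            else:
                assert seq.segment_mask[k]
                assert seq.segment_labels[k] == (1 if lta >= other else 0)


def test_pt_truncation_and_exclusions():
    s = truncate_pt_recording(_rec(2000), frozenset({"SR"}))
    assert len(s.waveform) == 1792 and s.label_set == frozenset({"SR"})
    with pytest.raises(RecordExcluded) as e:
        truncate_pt_recording(_rec(1000), frozenset({"SR"}))  # 5 s record
    assert e.value.reason == "short_record"
    with pytest.raises(RecordExcluded) as e:
        truncate_pt_recording(_rec(2000), frozenset())
    assert e.value.reason == "no_rhythm_label"


def test_split_sizes_and_disjointness():
    subjects = {f"s{i:03d}": frozenset() for i in range(100)}
    assign = split_subjects(subjects, seed=0)
    counts = {k: sum(1 for v in assign.values() if v == k) for k in
              ("train", "validation", "test")}
    assert counts == {"train": 64, "validation": 16, "test": 20}
    assert set(assign) == set(subjects)  # each subject exactly once


def test_split_stratifies_two_label_groups():
    subjects = {f"a{i}": frozenset({"lta"}) for i in range(50)}
    subjects |= {f"b{i}": frozenset({"plain"}) for i in range(50)}
    assign = split_subjects(subjects, seed=1)
    for lab in ("a", "b"):
        n_test = sum(1 for s, v in assign.items() if s.startswith(lab) and v == "test")
        assert abs(n_test - 10) <= 1  # 20 % of 50, +-1 subject


def test_split_determinism_and_singleton_stratum():
    subjects = {f"s{i}": frozenset({"x"}) for i in range(9)}
    subjects["solo"] = frozenset({"rare"})
    with pytest.warns(UserWarning, match="single-subject"):
        a = split_subjects(subjects, seed=3)
    with pytest.warns(UserWarning):
        b = split_subjects(subjects, seed=3)
    assert a == b
    assert a["solo"] == "train"


def _seqs_with_pools(n_lta, n_other):
    from ltadetect.segment import SequenceSample

    out = []
    for i in range(n_lta + n_other):
        labels = np.zeros(7, dtype=int)
        if i < n_lta:
            labels[0] = 1
        out.append(SequenceSample(np.zeros(SEQUENCE_LEN), f"s{i}", "r", 0,
                                  segment_labels=labels))
    return out


def test_oversample_epoch_pool_is_balanced():
    plan = plan_balanced_batches(_seqs_with_pools(30, 300), batch_size=32, seed=0)
    pool = plan.epoch_pool(0)
    assert len(pool) == 180  # 90 LTA (30 x3) + 90 Other
    lta_count = np.sum(pool < 30)
    assert lta_count == 90
    # every LTA-pool sequence appears exactly 3x
    counts = np.bincount(pool[pool < 30], minlength=30)
    assert np.all(counts == 3)


def test_none_mode_keeps_original_multiplicities():
    plan = plan_balanced_batches(_seqs_with_pools(30, 300), 32, mode="none", seed=0)
    pool = plan.epoch_pool(0)
    assert sorted(pool) == list(range(330))


def test_plans_deterministic_per_epoch_and_fresh_across_epochs():
    seqs = _seqs_with_pools(10, 100)
    p1 = plan_balanced_batches(seqs, 16, seed=5)
    p2 = plan_balanced_batches(seqs, 16, seed=5)
    assert all(np.array_equal(a, b) for a, b in
               zip(p1.epoch_batches(0), p2.epoch_batches(0)))
    other0 = set(p1.epoch_pool(0)[p1.epoch_pool(0) >= 10])
    other1 = set(p1.epoch_pool(1)[p1.epoch_pool(1) >= 10])
    assert other0 != other1  # fresh undersample draw each epoch


def test_weighted_loss_mode_exposes_inverse_frequency_weights():
    plan = plan_balanced_batches(_seqs_with_pools(10, 90), 16, mode="weighted_loss", seed=0)
    w_other, w_lta = plan.class_weights
    assert w_lta > w_other
    n_lta, n_other = 10, 90 * 7 + 10 * 6
    assert np.isclose(w_lta / w_other, n_other / n_lta)


def test_batch_plan_validation():
    seqs = _seqs_with_pools(5, 5)
    with pytest.raises(ValueError, match="batch_size"):
        plan_balanced_batches(seqs, 1)
    with pytest.raises(ValueError, match="class"):
        plan_balanced_batches(_seqs_with_pools(0, 10), 4)
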