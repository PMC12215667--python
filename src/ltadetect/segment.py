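"""Sequence construction, exclusion rules, subject splits, batch balancing.

The model consumes fixed 1792-sample sequences (7 segments of 256 samples
at 200 Hz, about 8.96 s).  FT-style recordings are cut into consecutive
non-overlapping sequences with one {LTA, Other} label per 256-sample
segment (majority rhythm within the segment; Noise-majority segments are
masked out of loss and metrics, keeping the fixed input length).  PT-style
10 s recordings are truncated to one sequence with a whole-sequence
multi-label target.

Splits are subject-wise 64/16/20 via multi-label iterative stratification;
training batches can be balanced by the 3x-oversample/undersample scheme or
by inverse-frequency loss weights.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ecg_io import EcgRecord, RhythmAnnotationTrack
from .rhythms import LTA_CODES, RhythmCode

__all__ = [
    "SEGMENT_LEN",
    "SEGMENTS_PER_SEQUENCE",
    "SEQUENCE_LEN",
    "SequenceSample",
    "RecordExcluded",
    "segment_recording",
    "truncate_pt_recording",
    "split_subjects",
    "BatchPlan",
    "plan_balanced_batches",
]

SEGMENT_LEN = 256
SEGMENTS_PER_SEQUENCE = 7
SEQUENCE_LEN = SEGMENT_LEN * SEGMENTS_PER_SEQUENCE  # 1792

LTA, OTHER = 1, 0


@dataclass
class SequenceSample:
    """One 1792-sample model input with its training target.

    ``segment_labels``/``segment_mask`` are set for FT-style samples (7
    binary labels, mask False where the segment is Noise-majority);
    ``label_set`` is set for PT-style samples.
    """

    waveform: np.ndarray
    subject_id: str
    source_recording: str
    start_sample: int
    segment_labels: np.ndarray | None = None  # (7,) int, 1 = LTA
    segment_mask: np.ndarray | None = None  # (7,) bool, True = use in loss/metrics
    label_set: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if len(self.waveform) != SEQUENCE_LEN:
            raise ValueError(f"waveform must have {SEQUENCE_LEN} samples")
        if self.segment_labels is not None:
            if len(self.segment_labels) != SEGMENTS_PER_SEQUENCE:
                raise ValueError("need exactly 7 segment labels")
            if self.segment_mask is None:
                self.segment_mask = np.ones(SEGMENTS_PER_SEQUENCE, dtype=bool)

    @property
    def is_lta_pool(self) -> bool:
        """Sequence-level class used for batch balancing: any valid LTA segment."""
        if self.segment_labels is None:
            return False
        return bool(np.any((self.segment_labels == LTA) & self.segment_mask))


class RecordExcluded(Exception):
    """A recording rejected by an exclusion rule; ``reason`` says which."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _segment_label(code_counts: Counter) -> tuple[int, bool]:
    """Majority class of one segment -> (label, valid).

    Counts are per mapped class {LTA, OTHER, NOISE}.  Ties between LTA and
    Other resolve to LTA (safety-first for a life-threatening-event
    detector); Noise wins only a strict majority.
    """
    lta = sum(n for c, n in code_counts.items() if c in LTA_CODES)
    noise = code_counts.get(RhythmCode.NOISE, 0)
    other = sum(code_counts.values()) - lta - noise
    if noise > max(lta, other):
        return OTHER, False
    return (LTA, True) if lta >= other else (OTHER, True)


def segment_recording(
    record: EcgRecord, track: RhythmAnnotationTrack
) -> list[SequenceSample]:
    """Cut an FT-style recording into labeled non-overlapping sequences.

    The trailing remainder shorter than one sequence is dropped; a record
    shorter than one sequence yields zero sequences with a warning.
    """
    if record.fs != 200:
        raise ValueError("segmenter expects a 200 Hz record (resample first)")
    x = np.asarray(record.signal, dtype=float)
    n_seq = len(x) // SEQUENCE_LEN
    if n_seq == 0:
        warnings.warn(
            f"record {record.subject_id}: {len(x)} samples < one sequence", stacklevel=2
        )
        return []
    # per-sample rhythm codes over the retained region
    spans = track.spans(n_seq * SEQUENCE_LEN)
    out: list[SequenceSample] = []
    for s in range(n_seq):
        start = s * SEQUENCE_LEN
        labels = np.zeros(SEGMENTS_PER_SEQUENCE, dtype=int)
        mask = np.ones(SEGMENTS_PER_SEQUENCE, dtype=bool)
        for k in range(SEGMENTS_PER_SEQUENCE):
            a, b = start + k * SEGMENT_LEN, start + (k + 1) * SEGMENT_LEN
            counts: Counter = Counter()
            for lo, hi, code in spans:
                ov = min(hi, b) - max(lo, a)
                if ov > 0:
                    counts[code] += ov
            labels[k], mask[k] = _segment_label(counts)
        out.append(
            SequenceSample(
                x[start : start + SEQUENCE_LEN],
                subject_id=record.subject_id,
                source_recording=record.subject_id,
                start_sample=start,
                segment_labels=labels,
                segment_mask=mask,
            )
        )
    return out


def truncate_pt_recording(record: EcgRecord, label_set: frozenset[str]) -> SequenceSample:
    """Keep the first 1792 samples of a PT-style 200 Hz recording.

    Raises :class:`RecordExcluded` for 5 s records (``short_record``) and
    for empty label sets (``no_rhythm_label``).
    """
    if record.fs != 200:
        raise ValueError("expects a 200 Hz record (resample first)")
    if not label_set:
        raise RecordExcluded("no_rhythm_label")
    if len(record.signal) < SEQUENCE_LEN:
        raise RecordExcluded("short_record")
    return SequenceSample(
        np.asarray(record.signal[:SEQUENCE_LEN], dtype=float),
        subject_id=record.subject_id,
        source_recording=record.subject_id,
        start_sample=0,
        label_set=frozenset(label_set),
    )


# ---------------------------------------------------------------------------
# subject-wise multi-label stratified split


def _iterative_stratify(
    subjects: list[str],
    labels: dict[str, frozenset[str]],
    fractions: tuple[float, ...],
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multi-label iterative stratification into len(fractions) folds.

    Greedy per-label assignment: repeatedly take the label with the fewest
    remaining unassigned subjects and deal its subjects to the fold whose
    per-label desire is largest (ties broken by total remaining desire,
    then by seeded draw).  Label-free subjects are dealt at the end by
    total desire.
    """
    remaining = set(subjects)
    desired_total = np.array([f * len(subjects) for f in fractions])
    label_counts: Counter = Counter()
    for s in subjects:
        label_counts.update(labels.get(s, frozenset()))
    desired_label = {
        lab: np.array([f * c for f in fractions]) for lab, c in label_counts.items()
    }
    assign: dict[str, int] = {}

    def place(subj: str, fold: int) -> None:
        assign[subj] = fold
        remaining.discard(subj)
        desired_total[fold] -= 1
        for lab in labels.get(subj, frozenset()):
            desired_label[lab][fold] -= 1

    while True:
        live = {
            lab: sum(1 for s in remaining if lab in labels.get(s, frozenset()))
            for lab in desired_label
        }
        live = {lab: n for lab, n in live.items() if n > 0}
        if not live:
            break
        lab = min(sorted(live), key=lambda k: live[k])
        for subj in sorted(s for s in remaining if lab in labels.get(s, frozenset())):
            d = desired_label[lab]
            best = np.flatnonzero(d == d.max())
            if len(best) > 1:
                t = desired_total[best]
                best = best[np.flatnonzero(t == t.max())]
            fold = int(rng.choice(best)) if len(best) > 1 else int(best[0])
            place(subj, fold)
    for subj in sorted(remaining):
        best = np.flatnonzero(desired_total == desired_total.max())
        fold = int(rng.choice(best)) if len(best) > 1 else int(best[0])
        place(subj, fold)
    return assign


def split_subjects(
    subject_labels: dict[str, frozenset[str] | set[str]],
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
) -> dict[str, str]:
    """Subject-wise stratified train/validation/test split.

    20 % of subjects go to test, then 20 % of the remainder to validation
    (64/16/20 overall).  A label carried by a single subject pins that
    subject to train with a warning.  Deterministic under ``seed``.
    """
    subjects = sorted(subject_labels)
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects to split 64/16/20")
    labels = {s: frozenset(subject_labels[s]) for s in subjects}
    pinned: set[str] = set()
    singleton = {lab for lab, c in Counter(l for s in subjects for l in labels[s]).items() if c == 1}
    for s in subjects:
        if labels[s] & singleton:
            pinned.add(s)
    if pinned:
        warnings.warn(
            f"{len(pinned)} subject(s) carry a single-subject label; pinned to train",
            stacklevel=2,
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    free = [s for s in subjects if s not in pinned]
    tr_f, va_f, te_f = fractions
    first = _iterative_stratify(free, labels, (tr_f + va_f, te_f), rng)
    devel = [s for s in free if first[s] == 0]
    second = _iterative_stratify(devel, labels, (tr_f / (tr_f + va_f), va_f / (tr_f + va_f)), rng)
    out = {}
    for s in subjects:
        if s in pinned:
            out[s] = "train"
        elif first[s] == 1:
            out[s] = "test"
        else:
            out[s] = "train" if second[s] == 0 else "validation"
    return out


# ---------------------------------------------------------------------------
# batch balancing


@dataclass
class BatchPlan:
    """Deterministic per-epoch batch generator over training sequences.

    ``oversample_3x_undersample`` replicates every LTA-pool sequence three
    times per epoch and draws a fresh equally sized subsample of the Other
    pool each epoch; ``weighted_loss`` keeps the data as-is and exposes
    inverse-frequency class weights; ``none`` is a plain shuffle.
    """

    n_sequences: int
    batch_size: int
    mode: str
    seed: int
    lta_indices: np.ndarray = field(repr=False, default=None)
    other_indices: np.ndarray = field(repr=False, default=None)
    class_weights: tuple[float, float] | None = None  # (other, lta)

    def epoch_pool(self, epoch: int) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((self.seed, epoch))))
        if self.mode == "oversample_3x_undersample":
            lta = np.repeat(self.lta_indices, 3)
            k = len(lta)
            replace = k > len(self.other_indices)
            other = rng.choice(self.other_indices, size=k, replace=replace)
            pool = np.concatenate([lta, other])
        else:
            pool = np.arange(self.n_sequences)
        rng.shuffle(pool)
        return pool

    def epoch_batches(self, epoch: int) -> list[np.ndarray]:
        pool = self.epoch_pool(epoch)
        return [pool[i : i + self.batch_size] for i in range(0, len(pool), self.batch_size)]


def plan_balanced_batches(
    sequences: list[SequenceSample],
    batch_size: int,
    mode: str = "oversample_3x_undersample",
    seed: int = 0,
) -> BatchPlan:
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    if mode not in ("oversample_3x_undersample", "weighted_loss", "none"):
        raise ValueError(f"unknown balancing mode {mode!r}")
    is_lta = np.array([s.is_lta_pool for s in sequences], dtype=bool)
    lta_idx, other_idx = np.flatnonzero(is_lta), np.flatnonzero(~is_lta)
    weights = None
    if mode == "oversample_3x_undersample":
        if len(lta_idx) == 0 or len(other_idx) == 0:
            raise ValueError("both classes must be present in the training set")
    elif mode == "weighted_loss":
        # per-segment inverse-frequency weights over valid segments
        n_lta = n_other = 0
        for s in sequences:
            if s.segment_labels is None:
                continue
            n_lta += int(np.sum((s.segment_labels == LTA) & s.segment_mask))
            n_other += int(np.sum((s.segment_labels == OTHER) & s.segment_mask))
        if n_lta == 0 or n_other == 0:
            raise ValueError("both classes must be present in the training set")
        tot = n_lta + n_other
        weights = (tot / (2.0 * n_other), tot / (2.0 * n_lta))
    return BatchPlan(len(sequences), batch_size, mode, seed, lta_idx, other_idx, weights)
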