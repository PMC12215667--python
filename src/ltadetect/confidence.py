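"""Sliding-window majority-vote confidence and pre-alert decision logic.

The detector emits one label per 256-sample segment, and its 1792-sample
input window can start at any segment boundary.  Sliding the input window
over a recording with a 256-sample step therefore gives every interior
segment up to 7 independent predictions — one from each covering window.
The final label is the majority vote and the confidence is the fraction of
covering windows that voted for it, so full-coverage confidences take the
values {4/7, 5/7, 6/7, 7/7} (e.g. 5 LTA votes out of 7 -> LTA at 71.4 %).

Edge segments are covered by fewer than 7 windows; their confidence uses
the actual number of covering windows as denominator, and even-split ties
resolve to LTA (safety-first), flagged on the prediction.

A confidence threshold turns the stream into alert decisions: a confident
LTA triggers an alert immediately, a low-confidence LTA opens a pre-alert
that escalates if any of the next ``h`` segments is a confident LTA and is
cleared otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecgnet import ECGNet

__all__ = [
    "SEGMENT_LEN",
    "WINDOW_SEGMENTS",
    "VoteTrace",
    "ConfidentPrediction",
    "AlertDecision",
    "sliding_votes",
    "vote",
    "decide_alert",
]

SEGMENT_LEN = 256
WINDOW_SEGMENTS = 7
WINDOW_LEN = SEGMENT_LEN * WINDOW_SEGMENTS

LTA, OTHER = 1, 0


@dataclass
class VoteTrace:
    """All predictions covering one segment (at most 7)."""

    segment_index: int
    votes: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.votes)


@dataclass
class ConfidentPrediction:
    """Majority label with its vote-fraction confidence."""

    segment_index: int
    label: int  # 1 = LTA
    confidence: float  # (majority votes) / n_windows
    n_windows: int
    tie_broken: bool = False


@dataclass
class AlertDecision:
    segment_index: int
    state: str  # none | pre_alert | alert
    confidence: float
    resolution: str | None = None  # for pre_alert: escalated | cleared | pending


def sliding_votes(model: ECGNet, recording: np.ndarray) -> list[VoteTrace]:
    """Collect per-segment votes from every 1792-sample window at 256 stride.

    ``recording`` is a standardized waveform at 200 Hz; a trailing partial
    segment is ignored.  All windows are evaluated in one batched forward
    pass (inference mode is per-sample independent, so this is exactly
    window-by-window application).
    """
    x = np.asarray(recording, dtype=np.float32).ravel()
    if len(x) < WINDOW_LEN:
        raise ValueError(
            f"recording of {len(x)} samples is too short for one window ({WINDOW_LEN})"
        )
    n_segments = len(x) // SEGMENT_LEN
    n_windows = n_segments - WINDOW_SEGMENTS + 1
    windows = np.stack(
        [x[w * SEGMENT_LEN : w * SEGMENT_LEN + WINDOW_LEN] for w in range(n_windows)]
    )
    logits = model.forward(windows, training=False)  # (n_windows, 7, 2)
    pred = np.argmax(logits, axis=-1)
    traces = [VoteTrace(s) for s in range(n_segments)]
    for w in range(n_windows):
        for j in range(WINDOW_SEGMENTS):
            traces[w + j].votes.append(int(pred[w, j]))
    return traces


def vote(trace: VoteTrace) -> ConfidentPrediction:
    """Majority label and confidence = majority count / covering windows."""
    if trace.n_windows < 1:
        raise ValueError("vote trace has no covering windows")
    n_lta = sum(1 for v in trace.votes if v == LTA)
    n_other = trace.n_windows - n_lta
    tie = n_lta == n_other
    label = LTA if n_lta >= n_other else OTHER  # ties -> LTA (safety-first)
    majority = n_lta if label == LTA else n_other
    return ConfidentPrediction(
        trace.segment_index, label, majority / trace.n_windows, trace.n_windows, tie
    )


def decide_alert(
    predictions: list[ConfidentPrediction],
    tau: float = 6 / 7,
    confirmation_horizon: int = 4,
) -> list[AlertDecision]:
    """Turn a confidence stream into none/pre-alert/alert decisions.

    LTA with confidence >= ``tau`` is an immediate alert.  LTA below
    ``tau`` opens a pre-alert, escalated if any of the next
    ``confirmation_horizon`` segments is a confident LTA, cleared
    otherwise (``pending`` if the stream ends inside the horizon).
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must lie in (0.5, 1]")
    if confirmation_horizon < 1:
        raise ValueError("confirmation horizon must be >= 1")
    decisions = []
    for i, p in enumerate(predictions):
        if p.label == LTA and p.confidence >= tau:
            decisions.append(AlertDecision(p.segment_index, "alert", p.confidence))
        elif p.label == LTA:
            upcoming = predictions[i + 1 : i + 1 + confirmation_horizon]
            if any(q.label == LTA and q.confidence >= tau for q in upcoming):
                resolution = "escalated"
            elif len(upcoming) < confirmation_horizon:
                resolution = "pending"
            else:
                resolution = "cleared"
            decisions.append(
                AlertDecision(p.segment_index, "pre_alert", p.confidence, resolution)
            )
        else:
            decisions.append(AlertDecision(p.segment_index, "none", p.confidence))
    return decisions
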