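"""Preprocessing chains for the two cohort styles.

Both chains operate at the model rate of 200 Hz:

* **PT chain** — 4th-order Butterworth band-pass, 0.5-40 Hz.
* **FT chain** (Amann-style, the AED monitor bandwidth) — mean subtraction,
  5-sample moving average, 1 Hz high-pass for drift suppression, 30 Hz
  low-pass Butterworth, in that order.

IIR filters default to zero-phase (forward-backward) application for the
offline training path; a causal mode is provided for streaming use.  The
pipeline order is: resample -> convert units -> filter -> segment ->
standardize, with standardization statistics fitted on training sequences
only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal as sps

from .ecg_io import EcgRecord

__all__ = [
    "FilterSpec",
    "NormalizationStats",
    "resample_to_200hz",
    "pt_filter",
    "amann_filter",
    "fit_standardizer",
    "apply_standardizer",
    "MODEL_FS",
]

MODEL_FS = 200
_ALLOWED_FS = (200, 250, 360, 500)


@dataclass(frozen=True)
class FilterSpec:
    """Serializable description of one filtering stage."""

    kind: str  # butterworth_bandpass | butterworth_lowpass | highpass | moving_average
    order: int
    cutoff_hz: tuple[float, ...]
    application: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_for(self, fs: float) -> None:
        if any(c >= fs / 2 for c in self.cutoff_hz):
            raise ValueError(f"cutoffs {self.cutoff_hz} must be < Nyquist ({fs / 2} Hz)")


#: The two chains as configuration (overridable defaults; the high-pass
#: order and the 30 Hz low-pass order are reconstruction choices).
PT_CHAIN = (FilterSpec("butterworth_bandpass", 4, (0.5, 40.0)),)
FT_CHAIN = (
    FilterSpec("moving_average", 5, ()),
    FilterSpec("highpass", 1, (1.0,)),
    FilterSpec("butterworth_lowpass", 4, (30.0,)),
)


def resample_to_200hz(record: EcgRecord) -> EcgRecord:
    """Polyphase rational-ratio resampling to 200 Hz with anti-aliasing.

    Output length is ``round(n * 200 / fs_in)``; content below 40 Hz is
    preserved.  Upsampling from below 200 Hz is rejected (source sets are
    all at >= 200 Hz).
    """
    if record.fs < 200:
        raise ValueError(f"fs {record.fs} < 200 Hz: upsampling not supported")
    if record.fs not in _ALLOWED_FS:
        raise ValueError(f"fs must be one of {_ALLOWED_FS}, got {record.fs}")
    if record.fs == MODEL_FS:
        return record
    g = gcd(MODEL_FS, record.fs)
    up, down = MODEL_FS // g, record.fs // g
    y = sps.resample_poly(np.asarray(record.signal, dtype=float), up, down)
    target = int(round(len(record.signal) * MODEL_FS / record.fs))
    y = y[:target]
    return EcgRecord(record.subject_id, y, MODEL_FS, record.units, record.lead_name)


def _require_model_fs(fs: int) -> None:
    if fs != MODEL_FS:
        raise ValueError(f"filter chain requires fs = {MODEL_FS} Hz, got {fs}")


def pt_filter(x: np.ndarray, fs: int = MODEL_FS, zero_phase: bool = True) -> np.ndarray:
    """PT chain: 0.5-40 Hz band-pass, 4th-order Butterworth."""
    _require_model_fs(fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(4, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)


def amann_filter(x: np.ndarray, fs: int = MODEL_FS, zero_phase: bool = True) -> np.ndarray:
    """FT chain: mean subtraction, 5-sample boxcar, 1 Hz HP, 30 Hz LP.

    The boxcar is centered with reflection padding so length is preserved.
    """
    _require_model_fs(fs)
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("Amann chain needs at least 5 samples")
    y = x - x.mean()
    padded = np.pad(y, 2, mode="reflect")
    y = np.convolve(padded, np.full(5, 0.2), mode="valid")
    sos_hp = sps.butter(1, 1.0, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(4, 30.0, btype="lowpass", fs=fs, output="sos")
    if zero_phase:
        y = sps.sosfiltfilt(sos_hp, y)
        y = sps.sosfiltfilt(sos_lp, y)
    else:
        y = sps.sosfilt(sos_hp, y)
        y = sps.sosfilt(sos_lp, y)
    return y


@dataclass(frozen=True)
class NormalizationStats:
    """Pooled mean/sd in µV, fitted on the training split only."""

    mean: float
    sd: float
    fitted_on: str = "train"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be > 0 (constant training data?)")


def fit_standardizer(training_sequences: list[np.ndarray] | np.ndarray,
                     fitted_on: str = "train") -> NormalizationStats:
    """Pooled mean and standard deviation over all training samples."""
    if isinstance(training_sequences, np.ndarray):
        pool = training_sequences.ravel()
    else:
        if not training_sequences:
            raise ValueError("training set is empty")
        pool = np.concatenate([np.asarray(s, dtype=float).ravel() for s in training_sequences])
    if pool.size == 0:
        raise ValueError("training set is empty")
    sd = float(pool.std())
    if sd == 0:
        raise ValueError("constant training data: sd = 0")
    return NormalizationStats(float(pool.mean()), sd, fitted_on)


def apply_standardizer(stats: NormalizationStats, x: np.ndarray) -> np.ndarray:
    return (np.asarray(x, dtype=float) - stats.mean) / stats.sd
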