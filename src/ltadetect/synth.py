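"""Synthetic single-lead ECG cohorts with annotated rhythm structure.

Two cohort styles mirror the two source-data families the pipeline consumes:

* **FT-style** — minutes-long Holter-like recordings at 250/360 Hz with
  annotated transitions into and out of life-threatening rhythms (VT, VF,
  VFL, PVT) plus occasional Noise spans; class mix defaults to roughly 12 %
  LTA time, matching the imbalance of ambulatory arrhythmia databases.
* **PT-style** — fixed-length 10 s recordings at 500 Hz, each carrying a
  small multi-label rhythm set drawn from a non-LTA vocabulary, emulating
  large 12-lead rhythm-classification corpora.

Waveforms are parametric analytic shapes (Gaussian-bump QRS complexes,
modulated sinusoids), not resampled real beats: morphology is deliberately
schematic, but the *spectral* contrast between rhythm families is real —
sinus-like rhythms concentrate energy in sharp QRS harmonics while
VF/PVT-like rhythms put their power in a 4-7 Hz oscillation — which is the
structure the downstream classifier has to exploit.

Randomness uses ``numpy.random.Generator`` over the PCG64 bit generator,
seeded through ``SeedSequence(entropy=(cohort_seed, subject_index))`` so
each subject owns a counter-derived substream: cohort membership order
cannot change a subject's waveform, and a fixed seed reproduces cohorts
bit-identically across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rhythms import LTA_CODES, RhythmCode

__all__ = [
    "RhythmPlan",
    "AnnotatedRecording",
    "FtPlanDistribution",
    "generate_rhythm",
    "generate_recording",
    "generate_ft_cohort",
    "generate_pt_cohort",
    "DEFAULT_PT_VOCABULARY",
]

VALID_FS = (250, 360, 500, 200)


@dataclass(frozen=True)
class RhythmPlan:
    """A fully specified recipe for one synthetic recording."""

    entries: tuple[tuple[RhythmCode, float], ...]
    fs: int
    amplitude_scale: float = 1000.0  # uV, sinus R-wave peak
    noise_sd: float = 20.0  # uV additive white noise
    baseline_wander_amp: float = 50.0  # uV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs not in VALID_FS:
            raise ValueError(f"fs must be one of {VALID_FS}, got {self.fs}")
        if not self.entries:
            raise ValueError("plan needs at least one rhythm entry")
        for code, dur in self.entries:
            if not isinstance(code, RhythmCode):
                raise ValueError(f"unknown rhythm code {code!r}")
            if dur <= 0:
                raise ValueError("durations must be > 0")


@dataclass
class AnnotatedRecording:
    """One subject's single-lead waveform plus rhythm metadata.

    Exactly one of ``annotations`` (FT style: change points) or
    ``label_set`` (PT style: whole-recording multi-label set) is populated.
    """

    subject_id: str
    signal: np.ndarray  # uV
    fs: int
    annotations: list[tuple[int, RhythmCode]] = field(default_factory=list)
    label_set: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.annotations:
            onsets = [o for o, _ in self.annotations]
            if onsets[0] != 0:
                raise ValueError("first annotation onset must be 0")
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise ValueError("annotation onsets must be strictly increasing")
            if onsets[-1] >= len(self.signal):
                raise ValueError("annotation onset beyond signal end")
        if bool(self.annotations) == (self.label_set is not None):
            raise ValueError("exactly one of annotations / label_set must be set")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


# ---------------------------------------------------------------------------
# waveform primitives


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _beat_train(
    n: int,
    fs: int,
    rng: np.random.Generator,
    rate_bpm: tuple[float, float],
    rr_jitter: float,
    amp: float,
    p_amp: float,
    t_amp: float,
    fib_baseline: bool = False,
    irregular: bool = False,
) -> np.ndarray:
    """QRS-complex train with optional P/T deflections.

    Each beat is a narrow positive R bump flanked by small negative Q/S
    bumps; P and T are broader Gaussians.  ``irregular`` draws every RR
    interval independently (atrial-fibrillation-like), otherwise a single
    rate with multiplicative jitter is used.
    """
    t = np.arange(n) / fs
    x = np.zeros(n)
    hr = rng.uniform(*rate_bpm)
    rr = 60.0 / hr
    beat_t = -rng.uniform(0.0, rr)  # random phase so windows differ
    while beat_t < t[-1] + rr:
        if irregular:
            step = rng.uniform(0.4, 1.0)
        else:
            step = rr * (1.0 + rr_jitter * rng.standard_normal())
        beat_t += max(step, 0.25)
        lo = max(0, int((beat_t - 0.45) * fs))
        hi = min(n, int((beat_t + 0.55) * fs) + 1)
        if lo >= hi:
            continue
        tt = t[lo:hi]
        beat = amp * (
            _gauss(tt, beat_t, 0.012)
            - 0.25 * _gauss(tt, beat_t - 0.03, 0.012)
            - 0.30 * _gauss(tt, beat_t + 0.03, 0.012)
        )
        if p_amp:
            beat += p_amp * amp * _gauss(tt, beat_t - 0.19, 0.03)
        if t_amp:
            beat += t_amp * amp * _gauss(tt, beat_t + 0.30, 0.05)
        x[lo:hi] += beat
    if fib_baseline:
        f = rng.uniform(6.0, 8.0)
        x += 0.05 * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x


def _modulated_oscillation(
    n: int,
    fs: int,
    rng: np.random.Generator,
    f_range: tuple[float, float],
    amp: float,
    freq_jitter: float,
    amp_mod_depth: float,
    harmonic: float = 0.0,
) -> np.ndarray:
    """Amplitude- and frequency-modulated oscillation (VT/VF family)."""
    t = np.arange(n) / fs
    f0 = rng.uniform(*f_range)
    # smooth frequency wander: random walk low-pass filtered by cumulative mean
    wander = rng.standard_normal(max(n // max(fs // 4, 1), 1) + 2)
    wander = np.interp(np.linspace(0, len(wander) - 1, n), np.arange(len(wander)), wander)
    f_inst = f0 * (1.0 + freq_jitter * wander)
    phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
    env_src = rng.standard_normal(max(n // max(fs, 1), 1) + 2)
    env = np.interp(np.linspace(0, len(env_src) - 1, n), np.arange(len(env_src)), env_src)
    envelope = 1.0 - amp_mod_depth + amp_mod_depth * np.abs(np.tanh(env))
    x = np.sin(phase)
    if harmonic:
        x = x + harmonic * np.sin(2 * phase)
    return amp * envelope * x


def _rhythm_core(code: RhythmCode, n: int, fs: int, rng: np.random.Generator, amp: float) -> np.ndarray:
    if code in (RhythmCode.SINUS, RhythmCode.OTHER):
        return _beat_train(n, fs, rng, (60, 100), 0.03, amp, p_amp=0.12, t_amp=0.22)
    if code is RhythmCode.TACHY_OTHER:
        return _beat_train(n, fs, rng, (105, 150), 0.02, amp, p_amp=0.08, t_amp=0.15)
    if code is RhythmCode.AFIB_LIKE:
        return _beat_train(
            n, fs, rng, (70, 110), 0.0, amp, p_amp=0.0, t_amp=0.18, fib_baseline=True, irregular=True
        )
    if code is RhythmCode.VT:
        # monomorphic, 150-250 bpm (2.5-4.17 Hz), wide sharpened complexes
        return _modulated_oscillation(
            n, fs, rng, (2.6, 4.1), 1.4 * amp, freq_jitter=0.02, amp_mod_depth=0.05, harmonic=0.35
        )
    if code is RhythmCode.VFL:
        # near-sinusoidal flutter waves, upper end of the VT rate band
        return _modulated_oscillation(
            n, fs, rng, (3.3, 4.15), 1.3 * amp, freq_jitter=0.02, amp_mod_depth=0.05
        )
    if code is RhythmCode.VF:
        # coarse fibrillation: dominant frequency 4-7 Hz, strong modulation
        return _modulated_oscillation(
            n, fs, rng, (4.5, 6.5), 0.9 * amp, freq_jitter=0.08, amp_mod_depth=0.35
        )
    if code is RhythmCode.PVT:
        return _modulated_oscillation(
            n, fs, rng, (4.2, 5.5), 1.1 * amp, freq_jitter=0.12, amp_mod_depth=0.5, harmonic=0.2
        )
    if code is RhythmCode.NOISE:
        # broadband, no periodic structure
        return 0.4 * amp * rng.standard_normal(n)
    raise ValueError(f"unknown rhythm code {code!r}")


def _add_artifacts(
    x: np.ndarray, fs: int, rng: np.random.Generator, noise_sd: float, wander_amp: float
) -> np.ndarray:
    t = np.arange(len(x)) / fs
    out = x + noise_sd * rng.standard_normal(len(x))
    if wander_amp:
        f = rng.uniform(0.15, 0.35)
        out = out + wander_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def generate_rhythm(
    rhythm_code: RhythmCode | str,
    duration: float,
    fs: int,
    seed: int,
    amplitude_scale: float = 1000.0,
    noise_sd: float = 20.0,
    baseline_wander_amp: float = 50.0,
) -> np.ndarray:
    """Generate one rhythm span in microvolts.

    Parameters
    ----------
    rhythm_code
        One of the internal rhythm codes.
    duration
        Span length in seconds; ``duration * fs`` must be >= 1 sample.
    fs
        Sampling rate in Hz (one of 200/250/360/500).
    seed
        Fixed seed => bit-identical output.
    """
    try:
        code = RhythmCode(rhythm_code)
    except ValueError:
        raise ValueError(
            f"unknown rhythm code {rhythm_code!r}; valid codes: "
            f"{[c.value for c in RhythmCode]}"
        ) from None
    if fs not in VALID_FS:
        raise ValueError(f"fs must be one of {VALID_FS}, got {fs}")
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration * fs must be >= 1 sample")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    x = _rhythm_core(code, n, fs, rng, amplitude_scale)
    return _add_artifacts(x, fs, rng, noise_sd, baseline_wander_amp)


def generate_recording(plan: RhythmPlan, subject_id: str = "synth") -> AnnotatedRecording:
    """Materialize a :class:`RhythmPlan` into an annotated recording.

    Transitions between spans are instantaneous at annotation onsets;
    consecutive spans with the same code are merged in the annotation track.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(plan.seed)))
    pieces: list[np.ndarray] = []
    annotations: list[tuple[int, RhythmCode]] = []
    cursor = 0
    for code, dur in plan.entries:
        n = int(round(dur * plan.fs))
        pieces.append(_rhythm_core(code, n, plan.fs, rng, plan.amplitude_scale))
        if not annotations or annotations[-1][1] is not code:
            annotations.append((cursor, code))
        cursor += n
    signal = _add_artifacts(
        np.concatenate(pieces), plan.fs, rng, plan.noise_sd, plan.baseline_wander_amp
    )
    return AnnotatedRecording(subject_id, signal, plan.fs, annotations)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class FtPlanDistribution:
    """Distribution over per-subject recording plans for FT-style cohorts."""

    duration_s: tuple[float, float] = (50.0, 60.0)
    fs_choices: tuple[int, ...] = (250, 360)
    lta_fraction: float = 0.12  # target share of LTA-labeled time
    lta_codes: tuple[RhythmCode, ...] = (RhythmCode.VT, RhythmCode.VF, RhythmCode.VFL, RhythmCode.PVT)
    other_codes: tuple[RhythmCode, ...] = (RhythmCode.SINUS, RhythmCode.SINUS, RhythmCode.AFIB_LIKE, RhythmCode.TACHY_OTHER)
    noise_prob: float = 0.25  # chance of one Noise span per recording
    noise_duration_s: tuple[float, float] = (1.5, 3.0)
    amplitude_scale: float = 1000.0
    noise_sd: float = 20.0
    baseline_wander_amp: float = 50.0
    fixed_entries: tuple[tuple[RhythmCode, float], ...] | None = None  # overrides sampling

    def sample_plan(self, rng: np.random.Generator, seed: int) -> RhythmPlan:
        fs = int(rng.choice(self.fs_choices))
        if self.fixed_entries is not None:
            return RhythmPlan(tuple(self.fixed_entries), fs, self.amplitude_scale,
                              self.noise_sd, self.baseline_wander_amp, seed)
        total = rng.uniform(*self.duration_s)
        if self.lta_fraction <= 0:
            entries = [(RhythmCode(rng.choice(self.other_codes)), float(total))]
            return RhythmPlan(tuple(entries), fs, self.amplitude_scale,
                              self.noise_sd, self.baseline_wander_amp, seed)
        lta_total = total * self.lta_fraction * rng.uniform(0.8, 1.2)
        n_episodes = 1 if (lta_total < 8.0 or rng.random() < 0.5) else 2
        episode_durs = np.full(n_episodes, lta_total / n_episodes)
        entries: list[tuple[RhythmCode, float]] = []
        other_total = total - lta_total
        # split the non-LTA time into one span per episode boundary (+ tail)
        cuts = np.sort(rng.uniform(0.2, 0.8, size=n_episodes)) * other_total
        bounds = np.concatenate([[0.0], cuts, [other_total]])
        other_durs = np.diff(bounds)
        for i in range(n_episodes):
            entries.append((RhythmCode(rng.choice(self.other_codes)), float(other_durs[i])))
            entries.append((RhythmCode(rng.choice(self.lta_codes)), float(episode_durs[i])))
        entries.append((RhythmCode(rng.choice(self.other_codes)), float(other_durs[-1])))
        if self.noise_prob and rng.random() < self.noise_prob:
            # steal the noise span from the longest Other span
            idx = int(np.argmax([d for _, d in entries]))
            code, d = entries[idx]
            nd = min(rng.uniform(*self.noise_duration_s), d / 2)
            entries[idx] = (code, d - nd)
            entries.insert(idx + 1, (RhythmCode.NOISE, float(nd)))
        return RhythmPlan(tuple(entries), fs, self.amplitude_scale,
                          self.noise_sd, self.baseline_wander_amp, seed)


def _subject_rng(seed: int, index: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence(entropy=(seed, index))
    sub_seed = int(ss.generate_state(1, np.uint32)[0])
    return np.random.Generator(np.random.PCG64(ss)), sub_seed


def generate_ft_cohort(
    n_subjects: int,
    plan_distribution: FtPlanDistribution | None = None,
    seed: int = 0,
) -> list[AnnotatedRecording]:
    """Generate an FT-style cohort of annotated minutes-scale recordings."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    dist = plan_distribution or FtPlanDistribution()
    if dist.fixed_entries is None and dist.lta_fraction <= 0:
        warnings.warn("FT cohort configured with zero LTA probability", stacklevel=2)
    out = []
    for i in range(n_subjects):
        rng, sub_seed = _subject_rng(seed, i)
        plan = dist.sample_plan(rng, sub_seed)
        out.append(generate_recording(plan, subject_id=f"ft{i:04d}"))
    return out


#: Ten schematic non-LTA rhythm labels; each maps to a waveform family.
DEFAULT_PT_VOCABULARY: dict[str, RhythmCode] = {
    "SR": RhythmCode.SINUS,
    "SB": RhythmCode.SINUS,
    "STACH": RhythmCode.TACHY_OTHER,
    "SA": RhythmCode.SINUS,
    "AFIB": RhythmCode.AFIB_LIKE,
    "AFLT": RhythmCode.AFIB_LIKE,
    "SVT": RhythmCode.TACHY_OTHER,
    "PACE": RhythmCode.OTHER,
    "BIGU": RhythmCode.OTHER,
    "TRIGU": RhythmCode.OTHER,
}


def generate_pt_cohort(
    n_subjects: int,
    label_vocabulary: dict[str, RhythmCode] | None = None,
    seed: int = 0,
    duration_s: float = 10.0,
    fs: int = 500,
    second_label_prob: float = 0.15,
) -> list[AnnotatedRecording]:
    """Generate a PT-style cohort: 10 s multi-label recordings, no LTA.

    Each recording carries 1-2 labels from ``label_vocabulary`` (name ->
    waveform family); the waveform follows the primary label's family.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    vocab = label_vocabulary if label_vocabulary is not None else DEFAULT_PT_VOCABULARY
    bad = [k for k, v in vocab.items() if v in LTA_CODES]
    if bad:
        raise ValueError(f"PT vocabulary must not contain LTA rhythms: {bad}")
    names = sorted(vocab)
    out = []
    for i in range(n_subjects):
        rng, _ = _subject_rng(seed, i)
        primary = str(rng.choice(names))
        labels = {primary}
        if len(names) > 1 and rng.random() < second_label_prob:
            secondary = str(rng.choice([n for n in names if n != primary]))
            labels.add(secondary)
        n = int(round(duration_s * fs))
        x = _rhythm_core(vocab[primary], n, fs, rng, 1000.0)
        x = _add_artifacts(x, fs, rng, 20.0, 50.0)
        out.append(
            AnnotatedRecording(f"pt{i:05d}", x, fs, annotations=[], label_set=frozenset(labels))
        )
    return out
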