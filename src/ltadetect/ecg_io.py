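"""Read/write annotated ECG recordings in a WFDB-compatible dialect.

Supports the subset of the PhysioNet WFDB family the pipeline touches:

* text headers (``.hea``) with per-lead gain/baseline/units and ``# Dx:``
  diagnosis-code comment lines,
* format-16 signal files (``.dat``, interleaved little-endian int16),
* MIT annotation files (``.atr``) restricted to rhythm-change annotations
  (RHYTHM code + aux string such as ``(VT``), with SKIP words for interval
  increments beyond the 10-bit field.

Multi-segment records, format 212, and EDF/DICOM are out of scope.  All
sample indices are 0-based; an annotation onset marks the first sample of
the new rhythm, so spans are half-open ``[onset_i, onset_{i+1})``.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rhythms import LabelCodeMap, RhythmCode
from .synth import AnnotatedRecording

log = logging.getLogger(__name__)

__all__ = [
    "EcgRecord",
    "RhythmAnnotationTrack",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "read_label_set",
    "LabelSetResult",
    "write_cohort",
    "read_ft_cohort",
    "annotations_to_csv",
    "CODE_TO_AUX",
]

# MIT annotation type codes used here
_RHYTHM = 28
_SKIP = 59
_AUX = 63

#: Canonical aux string written for each internal rhythm code.
CODE_TO_AUX: dict[RhythmCode, str] = {
    RhythmCode.SINUS: "(N",
    RhythmCode.AFIB_LIKE: "(AFIB",
    RhythmCode.TACHY_OTHER: "(SVTA",
    RhythmCode.VT: "(VT",
    RhythmCode.VF: "(VF",
    RhythmCode.VFL: "(VFL",
    RhythmCode.PVT: "(PVT",
    RhythmCode.NOISE: "(NOISE",
    RhythmCode.OTHER: "(N",
}


@dataclass
class EcgRecord:
    """A single selected lead in resolvable physical units."""

    subject_id: str
    signal: np.ndarray
    fs: int
    units: str = "uV"  # one of {"uV", "mV"}
    lead_name: str = "II"

    def to_uv(self) -> "EcgRecord":
        """Convert to microvolts; a no-op on µV records (idempotent)."""
        if self.units == "uV":
            return self
        if self.units == "mV":
            return EcgRecord(self.subject_id, self.signal * 1000.0, self.fs, "uV", self.lead_name)
        raise ValueError(f"cannot resolve units {self.units!r} to uV")


@dataclass
class RhythmAnnotationTrack:
    """Sorted rhythm-change entries; first entry defines rhythm from sample 0."""

    entries: list[tuple[int, RhythmCode]] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [o for o, _ in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotation onsets must be strictly increasing")

    def spans(self, n_samples: int) -> list[tuple[int, int, RhythmCode]]:
        """Half-open (start, stop, code) spans covering [0, n_samples)."""
        out = []
        for i, (onset, code) in enumerate(self.entries):
            stop = self.entries[i + 1][0] if i + 1 < len(self.entries) else n_samples
            if onset < n_samples:
                out.append((onset, min(stop, n_samples), code))
        return out


# ---------------------------------------------------------------------------
# header + signal


def write_record(
    directory: str | Path,
    record_name: str,
    signals: dict[str, np.ndarray],
    fs: int,
    units: str = "uV",
    gain: float = 4.0,
    subject_id: str | None = None,
    dx_codes: list[str] | None = None,
) -> Path:
    """Write a WFDB header + format-16 signal file.

    ``gain`` is in ADC units per physical unit; samples are rounded to the
    nearest ADC quantum (the round-trip error bound).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    leads = list(signals)
    arrs = [np.asarray(signals[k], dtype=float) for k in leads]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("all leads must have equal length")
    adc = np.stack([np.clip(np.rint(a * gain), -32768, 32767) for a in arrs], axis=1).astype("<i2")
    dat_name = f"{record_name}.dat"
    (directory / dat_name).write_bytes(adc.tobytes())
    lines = [f"{record_name} {len(leads)} {fs} {n}"]
    gain_txt = f"{gain:g}"
    for j, lead in enumerate(leads):
        init = int(adc[0, j])
        checksum = int(np.sum(adc[:, j], dtype=np.int64) % 65536)
        lines.append(f"{dat_name} 16 {gain_txt}(0)/{units} 16 0 {init} {checksum} 0 {lead}")
    if subject_id:
        lines.append(f"# subject: {subject_id}")
    if dx_codes:
        lines.append(f"# Dx: {','.join(dx_codes)}")
    hea = directory / f"{record_name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def _parse_header(header_path: Path) -> dict:
    lines = [ln.rstrip("\n") for ln in header_path.read_text().splitlines() if ln.strip()]
    rec_line = lines[0].split()
    name, nsig, fs, nsamp = rec_line[0], int(rec_line[1]), float(rec_line[2]), int(rec_line[3])
    sig_lines, comments = [], []
    for ln in lines[1:]:
        (comments if ln.startswith("#") else sig_lines).append(ln)
    if len(sig_lines) < nsig:
        raise ValueError(f"header {header_path} declares {nsig} signals, found {len(sig_lines)}")
    signals = []
    for ln in sig_lines[:nsig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1]
        spec = parts[2]  # gain(baseline)/units
        if "/" in spec:
            gb, units = spec.split("/", 1)
        else:
            gb, units = spec, "mV"  # WFDB default physical unit
        if "(" in gb:
            gain_s, base_s = gb.split("(")
            baseline = int(base_s.rstrip(")"))
        else:
            gain_s, baseline = gb, 0
        try:
            gain = float(gain_s)
        except ValueError as exc:
            raise ValueError(f"unreadable gain {gain_s!r} in {header_path}") from exc
        if gain == 0:
            raise ValueError(f"zero gain in {header_path}; refusing to guess units")
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(signals)}"
        signals.append(dict(file=fname, fmt=fmt, gain=gain, baseline=baseline, units=units, lead=desc))
    return dict(name=name, fs=fs, n=nsamp, signals=signals, comments=comments)


def read_record(path: str | Path, lead_selector: str = "II") -> EcgRecord:
    """Read one lead of a WFDB record, converted to microvolts.

    ``path`` is the header path or the record path without extension.
    """
    header_path = Path(str(path) if str(path).endswith(".hea") else str(path) + ".hea")
    hdr = _parse_header(header_path)
    leads = [s["lead"] for s in hdr["signals"]]
    matches = [i for i, s in enumerate(hdr["signals"]) if s["lead"] == lead_selector]
    if not matches:
        raise ValueError(
            f"lead {lead_selector!r} not found in {header_path.name}; available leads: {leads}"
        )
    j = matches[0]
    sig = hdr["signals"][j]
    if sig["fmt"] != "16":
        raise ValueError(f"unsupported WFDB signal format {sig['fmt']} (only 16)")
    raw = np.frombuffer((header_path.parent / sig["file"]).read_bytes(), dtype="<i2")
    nsig = len(hdr["signals"])
    raw = raw.reshape(-1, nsig)
    physical = (raw[:, j].astype(float) - sig["baseline"]) / sig["gain"]
    units = sig["units"]
    if units in ("uV", "uv", "µV"):
        uv = physical
    elif units in ("mV", "mv"):
        uv = physical * 1000.0
    else:
        raise ValueError(f"cannot resolve units {units!r} to uV")
    subject = hdr["name"]
    for c in hdr["comments"]:
        if c.lstrip("# ").startswith("subject:"):
            subject = c.split("subject:", 1)[1].strip()
    return EcgRecord(subject, uv, int(round(hdr["fs"])), "uV", lead_selector)


# ---------------------------------------------------------------------------
# annotations (MIT format, rhythm changes only)


def write_annotations(path: str | Path, entries: list[tuple[int, str]]) -> Path:
    """Write rhythm-change annotations (onset sample, aux string) to ``path``."""
    buf = bytearray()
    prev = 0
    for onset, aux in sorted(entries):
        dt = onset - prev
        if not (0 <= dt <= 1023):
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (dt >> 16) & 0xFFFF)  # high word first (PDP-11 long)
            buf += struct.pack("<H", dt & 0xFFFF)
            dt = 0
        buf += struct.pack("<H", (_RHYTHM << 10) | dt)
        data = aux.encode("ascii")
        buf += struct.pack("<H", (_AUX << 10) | len(data))
        buf += data
        if len(data) % 2:
            buf += b"\x00"
        prev = onset
    buf += struct.pack("<H", 0)  # EOF
    path = Path(path)
    path.write_bytes(bytes(buf))
    return path


def _read_raw_annotations(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, incr = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            hi, lo = struct.unpack_from("<HH", data, i)
            i += 4
            pending_skip = (hi << 16) | lo
        elif code == _AUX:
            aux = data[i : i + incr].decode("ascii")
            i += incr + (incr % 2)
            if out:
                onset, _ = out[-1]
                out[-1] = (onset, aux)
        else:
            t += incr + pending_skip
            pending_skip = 0
            out.append((t, ""))
    return out


def read_annotations(
    path: str | Path,
    label_map: LabelCodeMap | None = None,
    n_samples: int | None = None,
) -> RhythmAnnotationTrack:
    """Read rhythm annotations and map aux strings to internal codes.

    Unknown aux strings map to OTHER with a logged warning (``strict`` mode
    on the map raises instead).  A track that does not start at sample 0 is
    prepended with an OTHER span from 0.
    """
    label_map = label_map or LabelCodeMap()
    raw = _read_raw_annotations(Path(path))
    raw = [(o, a) for o, a in raw if a]
    if not raw:
        raise ValueError(f"annotation file {path} defines no rhythm")
    entries: list[tuple[int, RhythmCode]] = []
    for onset, aux in raw:
        code = label_map.map_aux(aux)
        if aux.strip() not in label_map.aux_map:
            log.warning("unknown rhythm string %r at sample %d mapped to OTHER", aux, onset)
        if n_samples is not None and onset >= n_samples:
            continue
        if entries and entries[-1][0] == onset:
            entries[-1] = (onset, code)
        else:
            entries.append((onset, code))
    if entries[0][0] != 0:
        log.info("annotation track starts at sample %d; prepending OTHER from 0", entries[0][0])
        entries.insert(0, (0, RhythmCode.OTHER))
    return RhythmAnnotationTrack(entries)


def annotations_to_csv(track: RhythmAnnotationTrack, path: str | Path) -> Path:
    path = Path(path)
    lines = ["onset_sample,rhythm_code"] + [f"{o},{c.value}" for o, c in track.entries]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# PT-style label sets


@dataclass
class LabelSetResult:
    labels: frozenset[str]
    excluded: bool
    reason: str | None = None


def read_label_set(header_path: str | Path, label_map: LabelCodeMap) -> LabelSetResult:
    """Extract the rhythm-label subset of a header's diagnosis codes.

    Only codes the map recognizes as rhythm labels are kept; a record with
    zero rhythm labels is flagged for exclusion (not an error).
    """
    hdr = _parse_header(Path(header_path))
    codes: list[str] = []
    for c in hdr["comments"]:
        body = c.lstrip("# ").strip()
        if body.lower().startswith("dx:"):
            codes += [x.strip() for x in body[3:].split(",") if x.strip()]
    rhythm = frozenset(c for c in codes if label_map.is_rhythm_dx(c))
    if not rhythm:
        return LabelSetResult(frozenset(), True, "no_rhythm_label")
    return LabelSetResult(rhythm, False)


# ---------------------------------------------------------------------------
# cohort round trips


def write_cohort(records: list[AnnotatedRecording], directory: str | Path) -> list[str]:
    """Write synthetic recordings as WFDB record (+ annotation) pairs.

    FT-style recordings get an ``.atr`` rhythm track; PT-style recordings
    get their label set as a ``# Dx:`` header comment.
    """
    directory = Path(directory)
    names = []
    for rec in records:
        name = rec.subject_id
        dx = sorted(rec.label_set) if rec.label_set is not None else None
        write_record(directory, name, {"II": rec.signal}, rec.fs, units="uV",
                     subject_id=rec.subject_id, dx_codes=dx)
        if rec.annotations:
            write_annotations(directory / f"{name}.atr",
                              [(o, CODE_TO_AUX[c]) for o, c in rec.annotations])
        names.append(name)
    return names


def read_ft_cohort(
    directory: str | Path, label_map: LabelCodeMap | None = None
) -> list[tuple[EcgRecord, RhythmAnnotationTrack]]:
    """Read every record+annotation pair in a cohort directory."""
    directory = Path(directory)
    out = []
    for hea in sorted(directory.glob("*.hea")):
        rec = read_record(hea)
        atr = hea.with_suffix(".atr")
        if not atr.exists():
            warnings.warn(f"{hea.stem}: no annotation file, skipped", stacklevel=2)
            continue
        out.append((rec, read_annotations(atr, label_map, n_samples=len(rec.signal))))
    return out
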