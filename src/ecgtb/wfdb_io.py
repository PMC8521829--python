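"""Minimal WFDB record/annotation I/O and 10-s segmentation.

Supports the subset of the WFDB specification the study needs:

* headers (``.hea``): record line + signal-spec lines, physical-unit scaling
  via gain/baseline;
* signals (``.dat``): format 16 (little-endian int16, interleaved channels)
  and format 212 (packed 12-bit pairs, the common arrhythmia-database format);
* annotations (``.atr``): the MIT annotation format, including SKIP/NUM/SUB/
  CHN/AUX pseudo-annotations and rhythm-change labels such as ``(AFIB``.

A writer is provided so synthetic datasets can be round-tripped through the
on-disk format.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .segments import EcgSegment

__all__ = [
    "AnnotationStream",
    "SegmentationRule",
    "read_record",
    "extract_segments",
    "write_record",
    "write_dataset_wfdb",
    "DEFAULT_CLASS_MAP",
]

# MIT annotation codes used in this study
_CODE_N = 1  # normal beat
_CODE_V = 5  # premature ventricular contraction
_CODE_A = 8  # atrial premature beat
_CODE_RHYTHM = 28
_CODE_SKIP = 59
_CODE_NUM = 60
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_AUX = 63

_BEAT_CODE_TO_MNEMONIC = {_CODE_N: "N", _CODE_V: "V", _CODE_A: "A"}
_MNEMONIC_TO_BEAT_CODE = {v: k for k, v in _BEAT_CODE_TO_MNEMONIC.items()}

#: Beat/rhythm mnemonics -> study class. AF is rhythm-level in WFDB practice.
DEFAULT_CLASS_MAP = {"N": "Norm", "V": "PVC", "A": "APB", "(AFIB": "AF"}


@dataclass
class AnnotationStream:
    """Beat and rhythm annotations of one record (0-based sample indices)."""

    beat_marks: list[tuple[int, str]] = field(default_factory=list)
    rhythm_marks: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for marks in (self.beat_marks, self.rhythm_marks):
            idx = [m[0] for m in marks]
            if any(b < a for a, b in zip(idx, idx[1:])):
                raise ValueError("annotation sample indices must be non-decreasing")


@dataclass(frozen=True)
class SegmentationRule:
    """How a record is cut into labeled study segments."""

    segment_len: float = 10.0  # seconds
    class_map: dict[str, str] | None = None  # None -> DEFAULT_CLASS_MAP
    homogeneity: str = "strict"  # "strict" or "majority"

    def __post_init__(self) -> None:
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        if self.homogeneity not in ("strict", "majority"):
            raise ValueError("homogeneity must be 'strict' or 'majority'")

    @property
    def mapping(self) -> dict[str, str]:
        return DEFAULT_CLASS_MAP if self.class_map is None else self.class_map


# ---------------------------------------------------------------------------
# header + signal reading


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    record_name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        signals.append(
            {"file": tok[0], "fmt": fmt, "gain": gain, "baseline": baseline, "units": units}
        )
    return record_name, n_sig, fs, n_samples, signals


def _read_dat(dat_path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Return raw ADC counts with shape (n_samples, n_sig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = len(data) // n_sig
        return data[: n * n_sig].reshape(n, n_sig).astype(np.int32)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2] = first
        flat[1::2] = second
        n = len(flat) // n_sig
        return flat[: n * n_sig].reshape(n, n_sig)
    raise IOError(f"unsupported WFDB signal format {fmt} in {dat_path.name}")


def _read_annotations(atr_path: Path) -> AnnotationStream:
    data = atr_path.read_bytes()
    beat_marks: list[tuple[int, str]] = []
    rhythm_marks: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_rhythm_at: int | None = None
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        tfield = word & 0x3FF
        if word == 0:
            break  # EOF
        if code == _CODE_SKIP:
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            off = (hi << 16) | lo
            if off >= 1 << 31:
                off -= 1 << 32
            t += off
        elif code in (_CODE_NUM, _CODE_SUB, _CODE_CHN):
            continue
        elif code == _CODE_AUX:
            aux = data[i : i + tfield].split(b"\x00")[0].decode("ascii", "replace")
            i += tfield + (tfield & 1)  # pad to even
            if pending_rhythm_at is not None:
                rhythm_marks.append((pending_rhythm_at, aux))
                pending_rhythm_at = None
        else:
            t += tfield
            if code == _CODE_RHYTHM:
                pending_rhythm_at = t
            elif code in _BEAT_CODE_TO_MNEMONIC:
                beat_marks.append((t, _BEAT_CODE_TO_MNEMONIC[code]))
            else:
                beat_marks.append((t, f"code{code}"))
    return AnnotationStream(beat_marks=beat_marks, rhythm_marks=rhythm_marks)


def read_record(
    path: str | Path, channel: int = 0
) -> tuple[np.ndarray, float, AnnotationStream]:
    """Read a WFDB record: physical-unit samples, fs, and annotations.

    ``path`` names the record (with or without the ``.hea`` extension).
    Multi-channel records yield the configured channel (default: first).
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise IOError(f"WFDB header not found: {hea_path}")
    record_name, n_sig, fs, n_samples, signals = _parse_header(hea_path)
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig} signals")
    sig = signals[channel]
    if n_sig > 1:
        warnings.warn(
            f"{record_name}: {n_sig} channels, using channel {channel}", stacklevel=2
        )
    dat_path = hea_path.parent / sig["file"]
    if not dat_path.exists():
        raise IOError(f"WFDB signal file not found: {dat_path}")
    adc = _read_dat(dat_path, sig["fmt"], n_sig)[:, channel]
    if n_samples:
        adc = adc[:n_samples]
    samples = (adc - sig["baseline"]) / sig["gain"]

    atr_path = hea_path.with_suffix(".atr")
    annotations = _read_annotations(atr_path) if atr_path.exists() else AnnotationStream()
    return samples.astype(float), fs, annotations


# ---------------------------------------------------------------------------
# segmentation


def _afib_spans(
    rhythm_marks: list[tuple[int, str]], n_samples: int
) -> list[tuple[int, int]]:
    """Half-open sample spans covered by an AFIB rhythm label."""
    spans = []
    for i, (start, lab) in enumerate(rhythm_marks):
        if lab.startswith("(AFIB"):
            end = rhythm_marks[i + 1][0] if i + 1 < len(rhythm_marks) else n_samples
            spans.append((start, end))
    return spans


def extract_segments(
    samples: np.ndarray,
    fs: float,
    annotations: AnnotationStream,
    rule: SegmentationRule = SegmentationRule(),
    record_id: str = "",
) -> list[EcgSegment]:
    """Cut a record into consecutive non-overlapping labeled windows.

    Under ``strict`` homogeneity a window is kept iff every beat annotation
    inside maps to one single study class; windows fully covered by an AFIB
    rhythm span are AF regardless of beat codes.  Mixed or unmapped windows
    are discarded.  ``majority`` keeps the most frequent mapped class instead
    (ties discarded).
    """
    if not annotations.beat_marks and not annotations.rhythm_marks:
        warnings.warn("empty annotation stream: no segments extracted", stacklevel=2)
        return []
    win = int(round(rule.segment_len * fs))
    n_windows = len(samples) // win
    mapping = rule.mapping
    spans = _afib_spans(annotations.rhythm_marks, len(samples))
    segments: list[EcgSegment] = []
    for k in range(n_windows):
        start, end = k * win, (k + 1) * win
        covered = any(s <= start and end <= e for s, e in spans)
        if covered and mapping.get("(AFIB") == "AF":
            label = "AF"
        else:
            codes = [c for idx, c in annotations.beat_marks if start <= idx < end]
            if not codes:
                continue
            classes = [mapping.get(c) for c in codes]
            if rule.homogeneity == "strict":
                unique = set(classes)
                if len(unique) != 1 or None in unique:
                    continue
                label = unique.pop()
            else:
                mapped = [c for c in classes if c is not None]
                if not mapped:
                    continue
                counts: dict[str, int] = {}
                for c in mapped:
                    counts[c] = counts.get(c, 0) + 1
                best = max(counts.values())
                winners = [c for c, v in counts.items() if v == best]
                if len(winners) != 1:
                    continue
                label = winners[0]
        segments.append(
            EcgSegment(
                samples=samples[start:end],
                fs=fs,
                label=label,
                source="wfdb",
                record_id=record_id,
                start_sample=start,
                filtered=False,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# writing


def _write_annotations(atr_path: Path, events: list[tuple[int, int, str | None]]) -> None:
    """events: (sample_index, code, aux-or-None), sorted by sample index."""
    out = bytearray()
    t_prev = 0
    for idx, code, aux in events:
        delta = idx - t_prev
        while delta >= 1024:
            off = min(delta, (1 << 31) - 1)
            out += struct.pack("<H", _CODE_SKIP << 10)
            out += struct.pack("<HH", (off >> 16) & 0xFFFF, off & 0xFFFF)
            t_prev += off
            delta = idx - t_prev
        out += struct.pack("<H", (code << 10) | delta)
        t_prev = idx
        if aux is not None:
            raw = aux.encode("ascii")
            out += struct.pack("<H", (_CODE_AUX << 10) | len(raw))
            out += raw
            if len(raw) & 1:
                out += b"\x00"
    out += struct.pack("<H", 0)  # EOF
    atr_path.write_bytes(bytes(out))


def write_record(
    directory: str | Path,
    record_name: str,
    samples: np.ndarray,
    fs: float,
    annotations: AnnotationStream,
    gain: float = 200.0,
    units: str = "mV",
) -> Path:
    """Write a single-channel WFDB record (format 16) with annotations."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.clip(np.round(np.asarray(samples) * gain), -32768, 32767).astype("<i2")
    (directory / f"{record_name}.dat").write_bytes(adc.tobytes())
    hea = (
        f"{record_name} 1 {fs:g} {len(adc)}\n"
        f"{record_name}.dat 16 {gain:g}(0)/{units} 16 0 {int(adc[0]) if len(adc) else 0} 0 0 ECG\n"
    )
    (directory / f"{record_name}.hea").write_text(hea)

    events: list[tuple[int, int, str | None]] = []
    for idx, lab in annotations.rhythm_marks:
        events.append((idx, _CODE_RHYTHM, lab))
    for idx, code in annotations.beat_marks:
        events.append((idx, _MNEMONIC_TO_BEAT_CODE.get(code, _CODE_N), None))
    events.sort(key=lambda e: (e[0], e[1] != _CODE_RHYTHM))
    _write_annotations(directory / f"{record_name}.atr", events)
    return directory / f"{record_name}.hea"


def write_dataset_wfdb(
    segments: list[EcgSegment], directory: str | Path, record_name: str = "syn"
) -> Path:
    """Concatenate segments into one WFDB record whose annotations round-trip.

    Every beat in a segment is annotated with the segment's class code
    (N/V/A); AF segments are wrapped in an ``(AFIB`` rhythm span.  This is a
    round-trip-oriented encoding (one code per segment), not a beat-accurate
    clinical annotation.
    """
    if not segments:
        raise ValueError("no segments to write")
    fs = segments[0].fs
    if any(s.fs != fs for s in segments):
        raise ValueError("all segments must share one sampling rate")
    sig = np.concatenate([s.samples for s in segments])
    beat_marks: list[tuple[int, str]] = []
    rhythm_marks: list[tuple[int, str]] = []
    code_for = {"Norm": "N", "PVC": "V", "APB": "A", "AF": "N"}
    offset = 0
    prev_rhythm = None
    for seg in segments:
        n = len(seg.samples)
        rhythm = "(AFIB" if seg.label == "AF" else "(N"
        if rhythm != prev_rhythm:
            rhythm_marks.append((offset, rhythm))
            prev_rhythm = rhythm
        beat_times = seg.meta.get("beat_times")
        if beat_times is None:
            beat_times = np.arange(0.5, seg.duration, 0.8)
        for bt in np.asarray(beat_times):
            idx = int(round(bt * fs))
            if 0 <= idx < n:
                beat_marks.append((offset + idx, code_for[seg.label]))
        offset += n
    ann = AnnotationStream(beat_marks=beat_marks, rhythm_marks=rhythm_marks)
    return write_record(directory, record_name, sig, fs, ann)
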