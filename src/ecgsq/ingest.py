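"""Reading, band-pass filtering and sliding-window segmentation of ECG.

Segments are single-lead amplitude series with a sampling rate and an
optional binary quality label (+1 clean, -1 noisy, 0 unlabelled).  Two
on-disk formats are supported:

* a CSV table with header ``segment_id,fs,label,modality,samples`` where
  ``samples`` holds the space-separated amplitude values of one segment
  per row (values are written with 17 significant digits, so a
  write/read round-trip is exact);
* a minimal WFDB subset: a ``<record>.hea`` header plus a format-16
  little-endian 16-bit ``<record>.dat`` file, single signal.  This reader
  and writer cover only that subset of the WFDB specification; amplitudes
  are (digital - baseline) / gain in mV.

Preprocessing is the zero-phase cascade of a 2nd-order high-pass at 1 Hz
(baseline wander) and a 4th-order low-pass at 40 Hz (high-frequency
noise), applied forward-backward so the passband incurs no phase lag and
the magnitude response is squared.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EcgSegment",
    "FilterSpec",
    "WindowGrid",
    "load_segments",
    "save_segments_csv",
    "save_segment_wfdb",
    "bandpass_filter",
    "slide_windows",
]

UNLABELLED = 0


@dataclass
class EcgSegment:
    """Single-lead ECG samples (mV) with sampling rate and optional label."""

    samples: np.ndarray
    fs: float
    label: int = UNLABELLED          # +1 clean, -1 noisy, 0 unlabelled
    segment_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive (got {self.fs})")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(
                f"segment {self.segment_id!r} contains non-finite samples")
        if self.label not in (-1, 0, 1):
            raise ValueError("label must be +1, -1 or 0 (unlabelled)")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FilterSpec:
    """Band-pass design: high-pass then low-pass Butterworth, zero phase."""

    hp_order: int = 2
    hp_cutoff: float = 1.0
    lp_order: int = 4
    lp_cutoff: float = 40.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff < fs / 2:
            raise ValueError(
                f"need 0 < hp_cutoff < lp_cutoff < fs/2 "
                f"(got {self.hp_cutoff}, {self.lp_cutoff}, fs={fs})")


@dataclass
class WindowGrid:
    """Sliding-window layout: 5-s windows with 80% overlap by default."""

    width: float = 5.0
    overlap: float = 0.8

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def step(self) -> float:
        return self.width * (1.0 - self.overlap)


class FormatError(ValueError):
    """Malformed or unsupported on-disk segment data."""


# ---------------------------------------------------------------- CSV I/O

_CSV_FIELDS = ["segment_id", "fs", "label", "modality", "samples"]

# one row holds a whole segment's samples; lift the stdlib field cap
csv.field_size_limit(1 << 27)


def save_segments_csv(segments: list[EcgSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for seg in segments:
            writer.writerow([
                seg.segment_id, repr(float(seg.fs)), seg.label, seg.modality,
                " ".join(f"{v:.17g}" for v in seg.samples),
            ])


def _load_csv(path: Path) -> list[EcgSegment]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "fs" not in header or "samples" not in header:
            raise FormatError(
                f"{path}: CSV header must carry 'fs' and 'samples' columns "
                f"(got {header})")
        segments = []
        for i, row in enumerate(reader):
            seg_id = row.get("segment_id") or f"row{i}"
            try:
                fs = float(row["fs"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: segment {seg_id!r} has no valid "
                                  f"sampling rate") from exc
            try:
                samples = np.array(row["samples"].split(), dtype=float)
            except (AttributeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: segment {seg_id!r} has malformed samples") from exc
            if not np.all(np.isfinite(samples)):
                raise FormatError(
                    f"{path}: segment {seg_id!r} contains non-finite samples")
            label = int(row["label"]) if row.get("label") not in (None, "") \
                else UNLABELLED
            segments.append(EcgSegment(samples=samples, fs=fs, label=label,
                                       segment_id=seg_id,
                                       modality=row.get("modality") or ""))
    return segments


# ----------------------------------------------------- minimal WFDB subset

def save_segment_wfdb(seg: EcgSegment, record_path: str | Path,
                      gain: float = 1000.0) -> None:
    """Write one segment as a format-16 WFDB record (``.hea`` + ``.dat``).

    Amplitudes are quantised to 16-bit integers at the given gain
    (ADC units per mV), the only lossy step of the round-trip.
    """
    record_path = Path(record_path)
    record = record_path.name
    digital = np.clip(np.round(seg.samples * gain), -32768, 32767).astype("<i2")
    fs_text = f"{seg.fs:.12g}"
    with open(record_path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{record} 1 {fs_text} {digital.size}\n")
        fh.write(f"{record}.dat 16 {gain:.12g}(0)/mV 16 0 "
                 f"{int(digital[0]) if digital.size else 0} 0 0 ECG\n")
        if seg.label != UNLABELLED:
            fh.write(f"# label {seg.label:+d}\n")
        if seg.modality:
            fh.write(f"# modality {seg.modality}\n")
    digital.tofile(record_path.with_suffix(".dat"))


def _load_wfdb(path: Path) -> list[EcgSegment]:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines() if ln.strip()]
    rec_fields = lines[0].split()
    if len(rec_fields) < 3:
        raise FormatError(f"{hea}: record line must carry name, n_sig and fs")
    record, n_sig, fs = rec_fields[0], int(rec_fields[1]), float(rec_fields[2])
    if n_sig != 1:
        raise FormatError(f"{hea}: only single-signal records are supported")
    sig = lines[1].split()
    fname, fmt = sig[0], sig[1].split("x")[0]
    if fmt != "16":
        raise FormatError(f"{hea}: only format 16 is supported (got {fmt})")
    gain_field = sig[2] if len(sig) > 2 else "200"
    gain_text = gain_field.split("/")[0]
    baseline = 0.0
    if "(" in gain_text:
        gain_text, base_text = gain_text.split("(")
        baseline = float(base_text.rstrip(")"))
    gain = float(gain_text) if float(gain_text) != 0 else 200.0
    label, modality = UNLABELLED, ""
    for ln in lines[2:]:
        parts = ln.lstrip("#").split()
        if parts[:1] == ["label"]:
            label = int(parts[1])
        elif parts[:1] == ["modality"]:
            modality = parts[1]
    digital = np.fromfile(hea.parent / fname, dtype="<i2").astype(float)
    return [EcgSegment(samples=(digital - baseline) / gain, fs=fs,
                       label=label, segment_id=record, modality=modality)]


def load_segments(path: str | Path, format: str | None = None) -> list[EcgSegment]:
    """Load ECG segments from a CSV table or a WFDB record.

    ``format`` is ``"csv"`` or ``"wfdb"``; when omitted it is inferred
    from the file suffix.  Raises :class:`FormatError` on missing
    sampling-rate metadata or non-finite samples.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in (".hea", ".dat") or not path.suffix \
            else "csv"
    if format == "csv":
        return _load_csv(path)
    if format == "wfdb":
        return _load_wfdb(path)
    raise FormatError(f"unknown segment format {format!r}")


# ------------------------------------------------------------- processing

def bandpass_filter(seg: EcgSegment, spec: FilterSpec | None = None) -> EcgSegment:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    spec = spec or FilterSpec()
    spec.validate(seg.fs)
    sos_hp = butter(spec.hp_order, spec.hp_cutoff, "highpass", fs=seg.fs,
                    output="sos")
    sos_lp = butter(spec.lp_order, spec.lp_cutoff, "lowpass", fs=seg.fs,
                    output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    if not spec.zero_phase:
        from scipy.signal import sosfilt
        filtered = sosfilt(sos, seg.samples)
    else:
        # forward-backward padlen, as used by sosfiltfilt internally
        padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                                 (sos[:, 5] == 0).sum()))
        if seg.samples.size <= padlen:
            raise ValueError(
                f"segment {seg.segment_id!r} is shorter than the filter "
                f"warm-up length ({seg.samples.size} <= {padlen} samples)")
        filtered = sosfiltfilt(sos, seg.samples)
    return EcgSegment(samples=filtered, fs=seg.fs, label=seg.label,
                      segment_id=seg.segment_id, modality=seg.modality)


def slide_windows(seg: EcgSegment, grid: WindowGrid | None = None) -> list[np.ndarray]:
    """Split a segment into overlapping windows anchored at sample 0.

    Window count is ``floor((duration - width) / step) + 1``; a trailing
    remainder shorter than one step is discarded (no partial windows).
    """
    grid = grid or WindowGrid()
    if seg.duration < grid.width - 1e-12:
        raise ValueError(
            f"segment {seg.segment_id!r} lasts {seg.duration:.3f} s, "
            f"shorter than the {grid.width} s window")
    win_len = int(round(grid.width * seg.fs))
    step_len = grid.step * seg.fs
    count = int(math.floor((seg.samples.size - win_len) / step_len + 1e-9)) + 1
    starts = [int(round(k * step_len)) for k in range(count)]
    return [seg.samples[s:s + win_len] for s in starts]
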