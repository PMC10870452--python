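"""EDF input/output and channel-montage handling for multichannel EEG.

A :class:`Recording` is the package's in-memory container: a dense
``channels x samples`` matrix in microvolts, one sampling rate, channel
names, and half-open seizure-interval annotations in seconds.

Reading goes through :mod:`mne` (which handles the many EDF dialects);
writing uses a small plain-EDF encoder (16-bit, 1-second data records)
because no EDF writer library is bundled with mne itself.  The roundtrip
write-then-read is exercised by the test suite and is exact up to the
16-bit quantization of the format.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Annotation",
    "Recording",
    "DEFAULT_MONTAGE_18",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "select_channels",
]

#: The 18 bipolar "double banana" derivations used as the default analysis
#: montage (longitudinal bipolar, as in the CHB-MIT recordings).
DEFAULT_MONTAGE_18 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
]


@dataclass(frozen=True)
class Annotation:
    """Half-open labeled interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid annotation interval [{self.start_s}, {self.end_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Multichannel EEG recording in physical units (microvolts)."""

    signal: np.ndarray  # (n_channels, n_samples), float64, microvolts
    fs: float
    channel_names: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for ann in self.annotations:
            if ann.end_s > self.duration + 1e-9:
                raise ValueError(
                    f"annotation [{ann.start_s}, {ann.end_s}) extends past "
                    f"recording duration {self.duration:g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


def _normalize_label(name: str) -> str:
    """Case/whitespace/dash-insensitive channel-name key."""
    return re.sub(r"[\s\-_]+", "", name).upper()


def select_channels(rec: Recording, montage: list[str]) -> Recording:
    """Subset/reorder channels to ``montage`` (name matching is lenient).

    Matching ignores case, whitespace and dashes, so ``"FP1-F7"`` matches
    ``"Fp1 F7"``.  Raises ``KeyError`` naming any montage channel absent
    from the recording.
    """
    lookup = {_normalize_label(n): i for i, n in enumerate(rec.channel_names)}
    missing = [m for m in montage if _normalize_label(m) not in lookup]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [lookup[_normalize_label(m)] for m in montage]
    return replace(
        rec,
        signal=rec.signal[idx].copy(),
        channel_names=list(montage),
        annotations=list(rec.annotations),
    )


# ---------------------------------------------------------------------------
# annotation sidecar (JSON)
# ---------------------------------------------------------------------------

def write_annotations(annotations: list[Annotation], path) -> None:
    payload = [
        {"start_s": a.start_s, "end_s": a.end_s, "label": a.label}
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_annotations(path) -> list[Annotation]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Annotation(float(d["start_s"]), float(d["end_s"]), str(d.get("label", "seizure")))
        for d in payload
    ]


# ---------------------------------------------------------------------------
# EDF reading (mne) and writing (minimal plain-EDF encoder)
# ---------------------------------------------------------------------------

def read_recording(edf_path, annotation_path=None) -> Recording:
    """Read an EDF file (physical units -> microvolts) plus optional sidecar.

    mne resolves per-channel sampling rates to a single raw rate; if the
    source channels disagreed, the returned recording is at mne's common
    (minimum) rate.  Annotation intervals are validated against the
    recording duration.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - exact mne error type varies
        raise ValueError(f"could not parse EDF file {edf_path}: {exc}") from exc
    signal = raw.get_data() * 1e6  # mne returns Volts for EEG channels
    annotations: list[Annotation] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    rec = Recording(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=annotations,
        subject_id=str(raw.info.get("subject_info") or edf_path),
    )
    return rec


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} longer than {width} bytes")
    return s.ljust(width).encode("ascii")


def _format_phys(value: float) -> str:
    """Physical min/max in <= 8 ASCII chars, exactly parseable."""
    for fmt in ("%g", "%.4g", "%.3g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format physical bound {value} in 8 chars")


def write_recording(rec: Recording, edf_path, annotation_path=None) -> None:
    """Write a recording as plain EDF (16-bit) with 1-second data records.

    The physical range per channel is the symmetric hull of the signal, so
    the amplitude resolution is ``max|x| / 32767`` — within the EDF 16-bit
    contract of ``(physical range) / 2^16``.  Requires an integer sampling
    rate and a whole number of seconds of data (pad or trim upstream).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            "EDF writer requires a whole number of 1-second records; "
            f"got {rec.n_samples} samples at {fs} Hz"
        )
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.signal).max(axis=1), 1.0)
    # round up to 4 significant digits so the ASCII header field is exact
    phys_max = np.array(
        [float(_format_phys(np.ceil(v * 1000) / 1000)) for v in phys_max]
    )
    if np.any(np.abs(rec.signal) > phys_max[:, None] * (1 + 1e-12)):
        raise ValueError("signal exceeds representable EDF physical range")

    header = bytearray()
    header += _ascii_field("0", 8)                      # version
    header += _ascii_field(rec.subject_id[:80], 80)     # patient id
    header += _ascii_field("synthetic EEG", 80)         # recording id
    header += _ascii_field("01.01.00", 8)               # start date
    header += _ascii_field("00.00.00", 8)               # start time
    header += _ascii_field(256 * (ns + 1), 8)           # header bytes
    header += _ascii_field("", 44)                      # reserved
    header += _ascii_field(n_records, 8)
    header += _ascii_field(1, 8)                        # record duration (s)
    header += _ascii_field(ns, 4)

    def per_signal(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    header += per_signal([n[:16] for n in rec.channel_names], 16)
    header += per_signal([""] * ns, 80)                 # transducer
    header += per_signal(["uV"] * ns, 8)                # physical dimension
    header += per_signal([_format_phys(-v) for v in phys_max], 8)
    header += per_signal([_format_phys(v) for v in phys_max], 8)
    header += per_signal([-32768] * ns, 8)
    header += per_signal([32767] * ns, 8)
    header += per_signal([""] * ns, 80)                 # prefiltering
    header += per_signal([fs] * ns, 8)                  # samples per record
    header += per_signal([""] * ns, 32)                 # reserved

    # EDF linear map: phys = (dig - dig_min) * cal + phys_min
    cal = (2.0 * phys_max) / 65535.0
    digital = np.rint((rec.signal + phys_max[:, None]) / cal[:, None]) - 32768.0
    digital = np.clip(digital, -32768, 32767).astype(np.int16)

    with open(edf_path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(struct.pack(f"<{ns * fs}h", *block.ravel()))

    if annotation_path is not None:
        write_annotations(rec.annotations, annotation_path)
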