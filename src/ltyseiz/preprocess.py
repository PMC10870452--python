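"""Resampling, powerline/high-pass filtering, windowing and class balancing.

The preprocessing chain mirrors common long-term EEG practice: downsample
to 256 Hz, notch out powerline energy (57-63 and 117-123 Hz stop bands),
high-pass above 1 Hz to suppress slow drifts, then cut the recording into
fixed 64-second analysis windows (16,384 samples at 256 Hz).

Filters are realized as 4th-order Butterworth sections applied forward and
backward (zero phase).  The stated cutoffs and stop bands are treated as
response *contracts* — attenuation >= 40 dB inside the notches, unity
within +-1 dB in the passband — rather than literal first-order transfer
functions, which are not realizable discrete filters.

Window labels come from annotation overlap: a window is ictal (1) when at
least half of it lies inside a seizure interval, interictal (0) when it
does not touch one, and ambiguous windows are dropped by default.  The
minority (ictal) class can be enriched by re-cutting annotated seizure
spans at a finer stride (75% overlap at the reference settings); background
windows are never duplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .eeg_io import Annotation, Recording

__all__ = [
    "FilterSpec",
    "WindowSet",
    "resample",
    "apply_bandstop",
    "apply_highpass",
    "segment",
    "label_windows",
    "balance_by_overlap",
]

REFERENCE_STOP_BANDS = ((57.0, 63.0), (117.0, 123.0))


@dataclass(frozen=True)
class FilterSpec:
    """Band-stop or high-pass filter specification.

    ``band_edges`` is a list of (low, high) pairs for band-stop, or a
    single cutoff for high-pass.  ``order`` is the analog prototype order
    of each Butterworth section; with ``zero_phase`` the section is applied
    forward-backward, squaring the magnitude response.
    """

    kind: str  # "band-stop" | "high-pass"
    band_edges: tuple = REFERENCE_STOP_BANDS
    cutoff: float = 1.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("band-stop", "high-pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "band-stop":
            for lo, hi in self.band_edges:
                if not lo < hi:
                    raise ValueError("band edges must be strictly increasing")
        elif self.cutoff <= 0:
            raise ValueError("high-pass cutoff must be positive")


@dataclass
class WindowSet:
    """Fixed-length labeled analysis windows with provenance."""

    windows: np.ndarray          # (n_windows, n_channels, window_samples)
    labels: np.ndarray           # (n_windows,) int, 0/1
    start_s: np.ndarray          # (n_windows,) float, start time in source
    source_id: list[str]         # per window
    fs: float
    window_s: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.start_s = np.asarray(self.start_s, dtype=np.float64)
        n = len(self.windows)
        if not (len(self.labels) == len(self.start_s) == len(self.source_id) == n):
            raise ValueError("inconsistent WindowSet field lengths")
        if n and self.windows.shape[2] != int(round(self.window_s * self.fs)):
            raise ValueError("window_samples != round(window_s * fs)")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            self.windows[idx], self.labels[idx], self.start_s[idx],
            [self.source_id[i] for i in np.atleast_1d(idx)],
            self.fs, self.window_s,
        )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        fs, ws = sets[0].fs, sets[0].window_s
        if any(s.fs != fs or s.window_s != ws for s in sets):
            raise ValueError("mismatched fs/window_s across WindowSets")
        return WindowSet(
            np.concatenate([s.windows for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.start_s for s in sets]),
            sum((s.source_id for s in sets), []),
            fs, ws,
        )

    # -- HDF5 serialization -------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=self.windows, compression="gzip")
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("start_s", data=self.start_s)
            f.create_dataset(
                "source_id", data=np.array(self.source_id, dtype="S64")
            )
            f.attrs["fs"] = self.fs
            f.attrs["window_s"] = self.window_s

    @staticmethod
    def load(path) -> "WindowSet":
        import h5py

        with h5py.File(path, "r") as f:
            return WindowSet(
                f["windows"][()], f["labels"][()], f["start_s"][()],
                [s.decode() for s in f["source_id"][()]],
                float(f.attrs["fs"]), float(f.attrs["window_s"]),
            )


# ---------------------------------------------------------------------------
# resampling & filtering
# ---------------------------------------------------------------------------

def resample(rec: Recording, target_fs: float = 256.0) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_fs``.

    Annotations are in seconds and carry over unchanged.  Upsampling is
    refused: the analysis regime only ever reduces the rate (512 or
    1024 Hz sources down to 256 Hz).
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz not supported")
    if target_fs == rec.fs:
        return replace(rec, signal=rec.signal.copy(),
                       annotations=list(rec.annotations))
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    return Recording(
        signal=out, fs=target_fs, channel_names=list(rec.channel_names),
        annotations=list(rec.annotations), subject_id=rec.subject_id,
    )


def _bandstop_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2
    sections = []
    for lo, hi in spec.band_edges:
        if hi >= nyq:
            raise ValueError(f"stop band edge {hi} Hz >= Nyquist {nyq} Hz")
        sections.append(
            sps.butter(spec.order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        )
    return np.vstack(sections)


def apply_bandstop(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Notch out the powerline stop bands (57-63 and 117-123 Hz reference)."""
    if spec is None:
        spec = FilterSpec(kind="band-stop")
    if spec.kind != "band-stop":
        raise ValueError("apply_bandstop requires a band-stop FilterSpec")
    sos = _bandstop_sos(spec, rec.fs)
    filt = sps.sosfiltfilt if spec.zero_phase else sps.sosfilt
    out = filt(sos, rec.signal, axis=1)
    return replace(rec, signal=np.ascontiguousarray(out),
                   annotations=list(rec.annotations))


def apply_highpass(rec: Recording, f_c: float = 1.0, order: int = 4,
                   zero_phase: bool = True) -> Recording:
    """High-pass above ``f_c`` (default 1 Hz): removes DC and slow drifts."""
    if not 0 < f_c < rec.fs / 2:
        raise ValueError(f"cutoff {f_c} Hz outside (0, {rec.fs / 2}) Hz")
    sos = sps.butter(order, f_c, btype="highpass", fs=rec.fs, output="sos")
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    out = filt(sos, rec.signal, axis=1)
    return replace(rec, signal=np.ascontiguousarray(out),
                   annotations=list(rec.annotations))


# ---------------------------------------------------------------------------
# windowing & labeling
# ---------------------------------------------------------------------------

def segment(rec: Recording, window_s: float = 64.0,
            stride_s: float | None = None) -> WindowSet:
    """Cut the recording into windows starting at 0, stride, 2*stride, ...

    A window is kept while ``start + window_s <= duration``; at 64 s /
    256 Hz each window holds 16,384 samples.  Labels are initialized to 0;
    call :func:`label_windows` to assign them.
    """
    if stride_s is None:
        stride_s = window_s
    w = int(round(window_s * rec.fs))
    stride = int(round(stride_s * rec.fs))
    if rec.n_samples < w:
        warnings.warn("recording shorter than one window; empty WindowSet")
        return WindowSet(
            np.empty((0, rec.n_channels, w)), np.empty(0, dtype=int),
            np.empty(0), [], rec.fs, window_s,
        )
    starts = np.arange(0, rec.n_samples - w + 1, stride)
    windows = np.stack([rec.signal[:, s : s + w] for s in starts])
    return WindowSet(
        windows=windows,
        labels=np.zeros(len(starts), dtype=int),
        start_s=starts / rec.fs,
        source_id=[rec.subject_id] * len(starts),
        fs=rec.fs,
        window_s=window_s,
    )


def _overlap_seconds(start: float, window_s: float,
                     annotations: list[Annotation]) -> float:
    end = start + window_s
    total = 0.0
    for a in annotations:
        if a.label != "seizure":
            continue
        total += max(0.0, min(end, a.end_s) - max(start, a.start_s))
    return total


def label_windows(ws: WindowSet, annotations: list[Annotation],
                  ambiguous: str = "drop") -> WindowSet:
    """Label windows by seizure-interval overlap.

    overlap >= 50% of the window -> 1; zero overlap -> 0; in between the
    window is ambiguous: dropped by default, or kept as seizure/background
    with ``ambiguous="seizure"`` / ``ambiguous="background"``.
    """
    if ambiguous not in ("drop", "seizure", "background"):
        raise ValueError(f"unknown ambiguous policy {ambiguous!r}")
    labels = np.zeros(len(ws), dtype=int)
    keep = np.ones(len(ws), dtype=bool)
    half = 0.5 * ws.window_s
    for i, s in enumerate(ws.start_s):
        ov = _overlap_seconds(s, ws.window_s, annotations)
        if ov >= half:
            labels[i] = 1
        elif ov > 0:
            if ambiguous == "drop":
                keep[i] = False
            else:
                labels[i] = 1 if ambiguous == "seizure" else 0
    out = WindowSet(ws.windows.copy(), labels, ws.start_s.copy(),
                    list(ws.source_id), ws.fs, ws.window_s)
    return out.subset(np.flatnonzero(keep))


def balance_by_overlap(ws: WindowSet, rec: Recording,
                       minority_stride_s: float = 16.0,
                       target_ratio: float = 1.0) -> WindowSet:
    """Enrich the ictal class by re-cutting seizure spans at a fine stride.

    Additional windows are extracted fully inside annotated seizure spans
    of ``rec`` at ``minority_stride_s`` (75% overlap at 64 s / 16 s) until
    ``count(ictal) / count(background) >= target_ratio`` or the spans are
    exhausted.  Existing windows (and their labels) are untouched and
    background windows are never duplicated.
    """
    seizures = [a for a in rec.annotations if a.label == "seizure"]
    if not seizures:
        warnings.warn("no seizure annotations; balance_by_overlap is a no-op")
        return ws
    n_min = int((ws.labels == 1).sum())
    n_maj = int((ws.labels == 0).sum())
    if target_ratio <= 0 or (n_maj > 0 and n_min / n_maj >= target_ratio):
        return ws

    w = int(round(ws.window_s * ws.fs))
    existing = {
        (sid, int(round(s * ws.fs)))
        for sid, s in zip(ws.source_id, ws.start_s)
        if sid == rec.subject_id
    }
    new_windows, new_starts = [], []
    for a in seizures:
        start = a.start_s
        while start + ws.window_s <= a.end_s + 1e-9:
            i0 = int(round(start * ws.fs))
            if (rec.subject_id, i0) not in existing and i0 + w <= rec.n_samples:
                new_windows.append(rec.signal[:, i0 : i0 + w])
                new_starts.append(i0 / ws.fs)
                existing.add((rec.subject_id, i0))
                n_min += 1
                if n_maj > 0 and n_min / n_maj >= target_ratio:
                    break
            start += minority_stride_s
        if n_maj > 0 and n_min / n_maj >= target_ratio:
            break
    if not new_windows:
        return ws
    added = WindowSet(
        np.stack(new_windows), np.ones(len(new_windows), dtype=int),
        np.array(new_starts), [rec.subject_id] * len(new_windows),
        ws.fs, ws.window_s,
    )
    return WindowSet.concatenate([ws, added])
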