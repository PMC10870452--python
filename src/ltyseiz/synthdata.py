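"""Synthetic multichannel scalp EEG with annotated seizures.

The generator emulates the regime of long-term 18-channel scalp EEG at
256 Hz: a 1/f ("pink") broadband background, narrowband alpha (8-12 Hz)
and beta (13-30 Hz) oscillations with per-channel random phase, powerline
contamination at 60 Hz plus its 120 Hz harmonic, and annotated ictal
episodes of high-amplitude rhythmic spike-wave-like activity at a low
fundamental frequency (default 3 Hz) synchronized across at least half
of the channels.

Amplitudes are in microvolts with a background RMS near 30 uV, so signals
sit comfortably in EDF 16-bit physical ranges.  All randomness flows from
``SynthConfig.seed`` through one ``numpy`` Generator: identical configs
give bit-identical recordings, and (through the deterministic EDF writer)
bit-identical files.

The ictal morphology is deliberately simple — a sinusoid at the ictal
fundamental plus its first two harmonics with exponentially decaying
amplitudes — band-limited, detectable by bandpower, and not a claim of
clinical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eeg_io import Annotation, Recording, DEFAULT_MONTAGE_18, write_recording

__all__ = ["SynthConfig", "PlacementError", "generate_recording", "write_dataset"]


class PlacementError(RuntimeError):
    """Seizure intervals could not be placed without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Powers are variances in uV^2: the default background is ~28 uV RMS of
    1/f noise plus ~10 uV RMS of alpha and ~5 uV RMS of beta.  The ictal
    amplitude is ``ictal_amplitude_gain`` times the background RMS.
    """

    n_channels: int = 18
    duration: float = 600.0          # seconds
    fs: float = 256.0                # Hz
    n_seizures: int = 2
    seizure_duration_range: tuple[float, float] = (60.0, 120.0)
    ictal_amplitude_gain: float = 5.0
    ictal_freq: float = 3.0          # Hz, spike-wave fundamental
    powerline_freq: float = 60.0     # Hz (first harmonic at 2x)
    background_alpha_power: float = 100.0   # uV^2
    background_noise_power: float = 800.0   # uV^2, 1/f component
    seed: int = 0
    channel_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(DEFAULT_MONTAGE_18)
    )

    def __post_init__(self) -> None:
        lo, hi = self.seizure_duration_range
        if not (0 < lo <= hi):
            raise ValueError("seizure_duration_range must satisfy 0 < min <= max")
        if self.n_seizures * hi >= self.duration:
            raise ValueError(
                "n_seizures x max seizure duration must be < duration "
                "(episodes must fit without overlap)"
            )
        if self.fs < 2 * 2 * self.powerline_freq:
            raise ValueError(
                "fs must be >= twice the powerline harmonic (2x powerline_freq)"
            )
        if self.ictal_amplitude_gain < 1:
            raise ValueError("ictal_amplitude_gain must be >= 1")
        if len(self.channel_names) < self.n_channels:
            object.__setattr__(
                self,
                "channel_names",
                tuple(f"CH{i + 1:02d}" for i in range(self.n_channels)),
            )


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, fs: float,
                power: float) -> np.ndarray:
    """1/f background: white noise spectrally shaped to PSD slope -1."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** -0.5  # amplitude f^-1/2 -> power 1/f
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms * np.sqrt(power)


def _place_intervals(rng: np.random.Generator, config: SynthConfig,
                     margin: float = 5.0) -> list[tuple[float, float]]:
    """Random disjoint seizure intervals inside [margin, duration - margin)."""
    n = config.n_seizures
    durations = rng.uniform(*config.seizure_duration_range, size=n)
    # feasibility: episodes + inter-episode and edge margins must fit,
    # then the free slack is split randomly over the n+1 gaps
    free = config.duration - durations.sum() - margin * (n + 1)
    if free < 0:
        raise PlacementError(
            f"could not place {n} seizures of up to "
            f"{config.seizure_duration_range[1]:g} s in "
            f"{config.duration:g} s without overlap"
        )
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    intervals: list[tuple[float, float]] = []
    cursor = 0.0
    for i, dur in enumerate(durations):
        cursor += gaps[i] + margin
        intervals.append((cursor, cursor + dur))
        cursor += dur
    return intervals


def generate_recording(config: SynthConfig) -> Recording:
    """Generate one annotated synthetic recording (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    C = config.n_channels

    signal = _pink_noise(rng, C, n, config.fs, config.background_noise_power)

    # narrowband rhythms, per-channel random frequency and phase
    alpha_amp = np.sqrt(2 * config.background_alpha_power)
    beta_amp = 0.5 * alpha_amp
    for ch in range(C):
        f_a = rng.uniform(8.0, 12.0)
        f_b = rng.uniform(13.0, 30.0)
        signal[ch] += alpha_amp * np.sin(2 * np.pi * f_a * t + rng.uniform(0, 2 * np.pi))
        signal[ch] += beta_amp * np.sin(2 * np.pi * f_b * t + rng.uniform(0, 2 * np.pi))

    # powerline contamination, common phase across the montage
    phase = rng.uniform(0, 2 * np.pi)
    signal += 8.0 * np.sin(2 * np.pi * config.powerline_freq * t + phase)
    signal += 3.0 * np.sin(2 * np.pi * 2 * config.powerline_freq * t + phase)

    background_rms = float(np.sqrt(np.mean(signal**2)))

    intervals = _place_intervals(rng, config) if config.n_seizures else []
    annotations = [Annotation(s, e, "seizure") for s, e in intervals]

    ictal_amp = config.ictal_amplitude_gain * background_rms
    for start, end in intervals:
        i0, i1 = int(round(start * config.fs)), int(round(end * config.fs))
        seg_t = t[i0:i1]
        n_affected = rng.integers((C + 1) // 2, C + 1)
        affected = rng.choice(C, size=n_affected, replace=False)
        phi = rng.uniform(0, 2 * np.pi)
        wave = np.zeros_like(seg_t)
        for h, gain in enumerate((1.0, 0.5, 0.25), start=1):
            wave += gain * np.sin(2 * np.pi * h * config.ictal_freq * seg_t + phi)
        wave *= ictal_amp / np.sqrt(np.sum(np.array([1.0, 0.5, 0.25]) ** 2) / 2)
        # cosine taper over the first/last second avoids onset clicks
        taper = np.ones_like(seg_t)
        edge = min(int(config.fs), len(seg_t) // 2)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        taper[:edge] = ramp
        taper[-edge:] = ramp[::-1]
        per_channel_gain = rng.uniform(0.8, 1.2, size=n_affected)
        signal[affected, i0:i1] += per_channel_gain[:, None] * (wave * taper)[None, :]

    return Recording(
        signal=signal,
        fs=config.fs,
        channel_names=list(config.channel_names[:C]),
        annotations=annotations,
        subject_id=f"synth-{config.seed:05d}",
    )


def write_dataset(recordings: list[Recording], out_dir) -> dict:
    """Write recordings as EDF + JSON annotation sidecars, plus a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    Signals exceeding the representable EDF physical range raise; callers
    must rescale first.
    """
    if not recordings:
        raise ValueError("recordings list is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        stem = rec.subject_id if rec.subject_id else f"recording-{i:03d}"
        edf = out_dir / f"{stem}.edf"
        ann = out_dir / f"{stem}.annotations.json"
        write_recording(rec, edf, ann)
        entries.append(
            {
                "edf": edf.name,
                "annotations": ann.name,
                "subject_id": rec.subject_id,
                "duration_s": rec.duration,
                "fs": rec.fs,
                "n_channels": rec.n_channels,
                "n_seizures": len(rec.annotations),
            }
        )
    manifest = {"n_recordings": len(entries), "recordings": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
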