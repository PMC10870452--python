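"""Time-frequency features: spectrograms, channel correlation, and PCA.

One 64-second window at 256 Hz (16,384 samples) is mapped per channel to a
log-magnitude short-time Fourier spectrogram with 127 time frames and 114
frequency bins:

* Hann window of 256 samples (1 s), hop 128 samples (50% overlap), frames
  fully inside the window: ``(16384 - 256) / 128 + 1 = 127`` frames;
* one-sided spectrum at 1 Hz resolution, retaining bins 1..114 Hz — above
  the 1 Hz high-pass cutoff and below the 117 Hz stop band;
* magnitude compressed as ``log(1 + |X|)``.

For the classifier, each of the 127 frames is flattened across
(channel, frequency) into an 18 x 114 = 2052-dimensional vector and
projected onto 64 principal axes, producing a 127-step sequence of 64-dim
feature vectors.  The PCA basis comes from the singular value
decomposition of the mean-centered training frames only — the fit is the
one place data leakage could enter the pipeline, so the basis object is
explicit and immutable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

__all__ = [
    "StftConfig",
    "SpectrogramTensor",
    "PCABasis",
    "CorrelationMatrix",
    "compute_spectrogram",
    "channel_correlation",
    "fit_pca",
    "apply_pca",
    "windows_to_sequences",
    "spectrogram_frames",
]


@dataclass(frozen=True)
class StftConfig:
    nperseg: int = 256      # 1 s at 256 Hz -> 1 Hz bins
    hop: int = 128          # 50% overlap
    fmin_bin: int = 1       # first retained bin (Hz at 1 Hz resolution)
    n_bins: int = 114       # retained bins: 1..114 Hz
    window: str = "hann"


@dataclass
class SpectrogramTensor:
    """Per-channel log-magnitude spectrogram of one analysis window."""

    values: np.ndarray      # (channels, time_frames, freq_bins)
    frame_times: np.ndarray  # seconds, frame centers
    bin_freqs: np.ndarray    # Hz

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    channel_names: list[str]


@dataclass(frozen=True)
class PCABasis:
    """Orthonormal projection onto the top-k principal axes.

    ``components`` columns are the right singular vectors of the centered
    training matrix; ``singular_values`` are the corresponding singular
    values and ``total_sq`` the full centered Frobenius energy, so
    explained-variance ratios and tail reconstruction error are exact.
    """

    mean: np.ndarray              # (input_dim,)
    components: np.ndarray        # (input_dim, k), orthonormal columns
    singular_values: np.ndarray   # (k,), nonincreasing
    k: int
    total_sq: float               # sum of ALL squared singular values

    @property
    def input_dim(self) -> int:
        return self.components.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_sq == 0:
            return np.zeros(self.k)
        return self.singular_values**2 / self.total_sq

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, components=self.components,
                 singular_values=self.singular_values, k=self.k,
                 total_sq=self.total_sq)

    @staticmethod
    def load(path) -> "PCABasis":
        d = np.load(path)
        return PCABasis(d["mean"], d["components"], d["singular_values"],
                        int(d["k"]), float(d["total_sq"]))


def compute_spectrogram(window: np.ndarray, fs: float = 256.0,
                        stft: StftConfig | None = None) -> SpectrogramTensor:
    """Log-magnitude STFT of one multichannel window.

    ``window`` is (channels, samples); at the reference 16,384 samples the
    output is (channels, 127, 114).
    """
    if stft is None:
        stft = StftConfig()
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    n = window.shape[-1]
    if n < stft.nperseg:
        raise ValueError(
            f"window of {n} samples shorter than one STFT segment "
            f"({stft.nperseg})"
        )
    taper = get_window(stft.window, stft.nperseg, fftbins=True)
    frames = sliding_window_view(window, stft.nperseg, axis=-1)[:, ::stft.hop, :]
    spec = np.fft.rfft(frames * taper, axis=-1)
    mag = np.abs(spec[..., stft.fmin_bin : stft.fmin_bin + stft.n_bins])
    values = np.log1p(mag)
    n_frames = values.shape[1]
    starts = np.arange(n_frames) * stft.hop
    frame_times = (starts + stft.nperseg / 2) / fs
    df = fs / stft.nperseg
    bin_freqs = (np.arange(stft.fmin_bin, stft.fmin_bin + stft.n_bins)) * df
    return SpectrogramTensor(values, frame_times, bin_freqs)


def channel_correlation(rec) -> CorrelationMatrix:
    """Pearson correlation between channel time series.

    Zero-variance channels get zero off-diagonal entries (with a warning)
    and a unit diagonal.
    """
    x = rec.signal
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    std = x.std(axis=1)
    dead = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    if dead.any():
        warnings.warn(
            f"zero-variance channels {list(np.flatnonzero(dead))}; "
            "correlation entries set to 0"
        )
        corr[dead, :] = 0.0
        corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return CorrelationMatrix(corr, list(rec.channel_names))


def fit_pca(frames: np.ndarray, k: int = 64) -> PCABasis:
    """PCA by singular value decomposition of the centered frame matrix.

    For tall matrices the top-k axes are obtained from the eigendecomposition
    of the (input_dim x input_dim) scatter matrix, which is algebraically the
    same SVD factor but avoids the full decomposition; small problems use
    ``numpy.linalg.svd`` directly.
    """
    frames = np.asarray(frames, dtype=np.float64)
    n, d = frames.shape
    if n <= k:
        raise ValueError(f"need more frames ({n}) than components ({k})")
    if k < 1 or k > d:
        raise ValueError(f"k={k} outside [1, input_dim={d}]")
    mean = frames.mean(axis=0)
    xc = frames - mean
    total_sq = float(np.sum(xc**2))
    if min(n, d) <= 768:
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        comps = vt[:k].T
        sv = s[:k]
    else:
        from scipy.linalg import eigh

        scatter = xc.T @ xc
        lo = d - k
        evals, evecs = eigh(scatter, subset_by_index=(lo, d - 1))
        order = np.argsort(evals)[::-1]
        sv = np.sqrt(np.clip(evals[order], 0, None))
        comps = evecs[:, order]
    # sign convention: largest-magnitude loading positive (determinism)
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(comps.shape[1])])
    flip[flip == 0] = 1.0
    comps = comps * flip
    return PCABasis(mean=mean, components=comps, singular_values=sv,
                    k=k, total_sq=total_sq)


def apply_pca(frames: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Project frames: ``Y = (X - mean) W`` with output dimension k."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.shape[-1] != basis.input_dim:
        raise ValueError(
            f"frame dimension {frames.shape[-1]} != basis input_dim "
            f"{basis.input_dim}"
        )
    return (frames - basis.mean) @ basis.components


def spectrogram_frames(spect: SpectrogramTensor) -> np.ndarray:
    """Flatten a spectrogram into (time_frames, channels * freq_bins)."""
    c, t, f = spect.values.shape
    return spect.values.transpose(1, 0, 2).reshape(t, c * f)


def windows_to_sequences(spect: SpectrogramTensor, basis: PCABasis) -> np.ndarray:
    """One window's spectrogram -> (time_frames, k) model input sequence."""
    frames = spectrogram_frames(spect)
    if frames.shape[1] != basis.input_dim:
        raise ValueError(
            f"basis input_dim {basis.input_dim} != channels*freq_bins "
            f"{frames.shape[1]}"
        )
    return apply_pca(frames, basis)
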