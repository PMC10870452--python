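"""Independent brute-force oracles used across the test suite.

These are deliberately written as plain loops, independent of the library
implementations they cross-check.
"""

import numpy as np


def conv1d_same_oracle(x: np.ndarray, w: np.ndarray, d: int = 1,
                       bias=None) -> np.ndarray:
    """Direct dilated cross-correlation with 'same' zero padding.

    x: (C_in, T), w: (C_out, C_in, k) -> (C_out, T).  Position-by-position
    triple loop; the output at t sums x[t + d*m - pad_left] * w[m].
    """
    c_in, t_len = x.shape
    c_out, _, k = w.shape
    pad_left = ((k - 1) * d) // 2
    out = np.zeros((c_out, t_len))
    for o in range(c_out):
        for t in range(t_len):
            acc = 0.0
            for i in range(c_in):
                for m in range(k):
                    src = t + d * m - pad_left
                    if 0 <= src < t_len:
                        acc += x[i, src] * w[o, i, m]
            out[o, t] = acc
    if bias is not None:
        out += np.asarray(bias)[:, None]
    return out


def auc_concordance_oracle(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability over all
    positive-negative pairs (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bandpower_welch(x: np.ndarray, fs: float, fmin: float, fmax: float) -> float:
    """Mean Welch PSD power in [fmin, fmax] averaged over channels."""
    from scipy.signal import welch

    f, p = welch(x, fs=fs, nperseg=min(2048, x.shape[-1]))
    band = (f >= fmin) & (f <= fmax)
    return float(np.mean(p[..., band]))
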