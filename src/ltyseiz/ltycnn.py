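"""The LTY-CNN: parallel multiscale convolution, quantized dilated
convolution, and multihead self-attention over spectrogram-PCA sequences.

Architecture (input: a 127-step sequence of 64-dim feature vectors):

1. three parallel 1-D convolution branches over time with wide/medium/
   narrow kernels (reference 7/5/3, 4 output channels each), ReLU, and
   channel concatenation — ``F_total = Concat[Act(F_wide), Act(F_medium),
   Act(F_narrow)]``;
2. an n-bit *quantized* dilated convolution (reference 8 bits, dilation 2,
   kernel 3) projecting the 12 concatenated channels to 64.  Quantization
   is uniform mid-tread fake quantization, ``Q(x) = Delta * floor(x/Delta
   + 1/2)`` with per-tensor step ``Delta = 2 max|x| / 2^n``, applied to
   both activations and weights; gradients pass straight through;
3. layer normalization and 4-head scaled dot-product self-attention at
   total width 64 (16 dims per head), ``softmax(Q K^T / sqrt(d_k)) V``
   per head, heads concatenated and projected;
4. mean pooling over time and a linear 2-class head.

The reference configuration has 23,118 trainable parameters, within the
24,506 budget of the reference design.  Forward *and* backward passes are
written in NumPy: with a fixed seed and one BLAS thread the whole model is
bit-reproducible, and the finite-difference tests in the suite check the
analytic gradients end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "QuantizationSpec",
    "quantize",
    "quantization_error",
    "receptive_field",
    "dilated_conv",
    "quantized_dilated_conv",
    "parallel_branches",
    "multihead_attention",
    "LTYCNN",
    "forward",
    "count_parameters",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the reference architecture."""

    input_dim: int = 64
    seq_len: int = 127
    branch_kernels: tuple[int, ...] = (7, 5, 3)   # wide, medium, narrow
    branch_channels: tuple[int, ...] = (4, 4, 4)
    activation: str = "relu"
    q_bits: int = 8
    dilation: int = 2
    dilated_kernel: int = 3
    dilated_out: int = 64
    attn_heads: int = 4
    attn_dim: int = 64
    n_classes: int = 2
    parameter_budget: int = 24_506

    def __post_init__(self) -> None:
        if len(self.branch_kernels) != len(self.branch_channels):
            raise ValueError("branch_kernels and branch_channels mismatch")
        if self.attn_dim % self.attn_heads:
            raise ValueError(
                f"attn_dim {self.attn_dim} not divisible by "
                f"{self.attn_heads} heads"
            )
        if self.q_bits < 1:
            raise ValueError("q_bits must be >= 1")
        if self.dilation < 1 or self.dilated_kernel < 1:
            raise ValueError("dilation and kernel must be >= 1")
        if self.dilated_out != self.attn_dim:
            raise ValueError("dilated_out must equal attn_dim (stream width)")

    @property
    def concat_channels(self) -> int:
        return sum(self.branch_channels)


@dataclass(frozen=True)
class QuantizationSpec:
    """Per-tensor uniform quantization: ``Delta = 2 max|x| / 2^n``."""

    n: int
    delta: float
    max_abs: float


# ---------------------------------------------------------------------------
# quantization primitives
# ---------------------------------------------------------------------------

def _step(max_abs: float, n: int) -> float:
    # zero-safe: an all-zero tensor quantizes to itself with Delta := 1
    return 2.0 * max_abs / 2.0**n if max_abs > 0 else 1.0


def quantize(x: np.ndarray, n: int) -> tuple[np.ndarray, QuantizationSpec]:
    """Mid-tread uniform quantizer ``Q(x) = Delta * floor(x/Delta + 1/2)``."""
    if n < 1:
        raise ValueError("quantization bit width must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    max_abs = float(np.max(np.abs(x))) if x.size else 0.0
    delta = _step(max_abs, n)
    xq = delta * np.floor(x / delta + 0.5)
    return xq, QuantizationSpec(n=n, delta=delta, max_abs=max_abs)


def quantization_error(x: np.ndarray, n: int) -> float:
    """Mean absolute quantization error ``E = E[|x - Q(x)|]``."""
    xq, _ = quantize(x, n)
    return float(np.mean(np.abs(np.asarray(x, dtype=np.float64) - xq)))


def receptive_field(k: int, d: int) -> int:
    """Receptive field of a dilated kernel: ``R = k + (k-1)(d-1)``."""
    if k < 1 or d < 1:
        raise ValueError("kernel size and dilation must be >= 1")
    return k + (k - 1) * (d - 1)


# ---------------------------------------------------------------------------
# convolution (channels-first, "same" zero padding over time)
# ---------------------------------------------------------------------------

def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
            d: int) -> np.ndarray:
    """Dilated cross-correlation, x (B,Cin,T), w (Cout,Cin,k) -> (B,Cout,T)."""
    B, Cin, T = x.shape
    Cout, _, k = w.shape
    pad = (k - 1) * d
    pl = pad // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pad - pl)))
    out = np.zeros((B, Cout, T))
    for m in range(k):
        out += np.einsum("oi,bit->bot", w[:, :, m], xp[:, :, m * d : m * d + T])
    if b is not None:
        out += b[None, :, None]
    return out


def _conv1d_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray, d: int):
    """Gradients of _conv1d w.r.t. input, weights, bias."""
    B, Cin, T = x.shape
    Cout, _, k = w.shape
    pad = (k - 1) * d
    pl = pad // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pad - pl)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for m in range(k):
        sl = slice(m * d, m * d + T)
        dw[:, :, m] = np.einsum("bot,bit->oi", dout, xp[:, :, sl])
        dxp[:, :, sl] += np.einsum("oi,bot->bit", w[:, :, m], dout)
    dx = dxp[:, :, pl : pl + T]
    db = dout.sum(axis=(0, 2))
    return dx, dw, db


def _as_batched(seq: np.ndarray) -> tuple[np.ndarray, bool]:
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim == 2:
        return seq[None], True
    if seq.ndim == 3:
        return seq, False
    raise ValueError("sequence must be (C,T) or (B,C,T)")


def dilated_conv(seq: np.ndarray, weights: np.ndarray, d: int,
                 bias: np.ndarray | None = None) -> np.ndarray:
    """Dilated 1-D convolution over time with "same" padding.

    ``seq`` is (C_in, T) or (B, C_in, T); ``weights`` is (C_out, C_in, k).
    At ``d == 1`` this is exactly a standard convolution.
    """
    x, squeeze = _as_batched(seq)
    w = np.asarray(weights, dtype=np.float64)
    if d < 1:
        raise ValueError("dilation must be >= 1")
    T = x.shape[2]
    if receptive_field(w.shape[2], d) > T:
        raise ValueError(
            f"receptive field {receptive_field(w.shape[2], d)} exceeds "
            f"sequence length {T}"
        )
    out = _conv1d(x, w, bias, d)
    return out[0] if squeeze else out


def quantized_dilated_conv(seq: np.ndarray, weights: np.ndarray, d: int,
                           n_bits: int,
                           bias: np.ndarray | None = None) -> np.ndarray:
    """Dilated convolution of quantized activations with quantized weights:
    ``O_q = Q(A) * Q(W)`` (bias, if any, is left full precision)."""
    x, squeeze = _as_batched(seq)
    xq, _ = quantize(x, n_bits)
    wq, _ = quantize(weights, n_bits)
    out = dilated_conv(xq, wq, d, bias)
    return out[0] if squeeze else out


def parallel_branches(seq: np.ndarray, config: ModelConfig,
                      params: dict[str, np.ndarray]) -> np.ndarray:
    """Three parallel convolutions on the SAME input, activated and
    concatenated along the channel axis: (D, T) -> (sum(channels), T)."""
    x, squeeze = _as_batched(seq)
    T = x.shape[2]
    outs = []
    for i, k in enumerate(config.branch_kernels):
        if k > T:
            raise ValueError(f"branch kernel {k} exceeds sequence length {T}")
        z = _conv1d(x, params[f"branch{i}_W"], params[f"branch{i}_b"], d=1)
        outs.append(np.maximum(z, 0.0))
    out = np.concatenate(outs, axis=1)
    return out[0] if squeeze else out


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def multihead_attention(seq: np.ndarray, params: dict[str, np.ndarray],
                        n_heads: int = 4, return_weights: bool = False):
    """Multihead scaled dot-product self-attention, (T, D) -> (T, D).

    ``params`` holds in-projections ``Wq/Wk/Wv`` with biases ``bq/bk/bv``
    and the out-projection ``Wo``/``bo``.  Heads split the model width D
    into ``D / n_heads`` dims each; every softmax row sums to one.
    """
    x, squeeze = _as_batched_seq(seq)
    B, T, D = x.shape
    if D % n_heads:
        raise ValueError(f"width {D} not divisible by {n_heads} heads")
    dk = D // n_heads
    q = x @ params["Wq"] + params["bq"]
    k = x @ params["Wk"] + params["bk"]
    v = x @ params["Wv"] + params["bv"]

    def split(m):
        return m.reshape(B, T, n_heads, dk).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dk)
    attn = _softmax(scores, axis=-1)
    heads = attn @ vh                              # (B, H, T, dk)
    concat = heads.transpose(0, 2, 1, 3).reshape(B, T, D)
    out = concat @ params["Wo"] + params["bo"]
    if squeeze:
        out, attn = out[0], attn[0]
    return (out, attn) if return_weights else out


def _as_batched_seq(seq: np.ndarray) -> tuple[np.ndarray, bool]:
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim == 2:
        return seq[None], True
    if seq.ndim == 3:
        return seq, False
    raise ValueError("sequence must be (T,D) or (B,T,D)")


# ---------------------------------------------------------------------------
# the full model, with hand-written backprop
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


class LTYCNN:
    """Reference model; parameters live in a flat name -> array dict.

    ``fake_quant`` toggles the simulated quantization of the dilated
    layer; disabling it gives the full-precision ablation (and makes the
    whole network differentiable for exact gradient checks).
    """

    fake_quant: bool = True

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        if params is not None:
            self.params = {k: np.asarray(v, dtype=np.float64) for k, v in params.items()}
        else:
            rng = np.random.default_rng(seed)
            p: dict[str, np.ndarray] = {}
            for i, (kk, cc) in enumerate(zip(cfg.branch_kernels, cfg.branch_channels)):
                fan_in = cfg.input_dim * kk
                p[f"branch{i}_W"] = rng.normal(0, np.sqrt(2 / fan_in),
                                               (cc, cfg.input_dim, kk))
                p[f"branch{i}_b"] = np.zeros(cc)
            c_in = cfg.concat_channels
            p["dilated_W"] = rng.normal(0, np.sqrt(2 / (c_in * cfg.dilated_kernel)),
                                        (cfg.dilated_out, c_in, cfg.dilated_kernel))
            p["dilated_b"] = np.zeros(cfg.dilated_out)
            p["ln_g"] = np.ones(cfg.attn_dim)
            p["ln_b"] = np.zeros(cfg.attn_dim)
            s = np.sqrt(1 / cfg.attn_dim)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[name] = rng.normal(0, s, (cfg.attn_dim, cfg.attn_dim))
            for name in ("bq", "bk", "bv", "bo"):
                p[name] = np.zeros(cfg.attn_dim)
            p["Wc"] = rng.normal(0, s, (cfg.attn_dim, cfg.n_classes))
            p["bc"] = np.zeros(cfg.n_classes)
            self.params = p
        self._cache: dict | None = None

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Class scores for a batch: (B, T, D) or (T, D) -> (B, 2) / (2,)."""
        cfg, p = self.config, self.params
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        B, T, D = x.shape
        if D != cfg.input_dim:
            raise ValueError(
                f"branch stage: feature dim {D} != input_dim {cfg.input_dim}")
        xc = x.transpose(0, 2, 1)                       # (B, D, T)

        z_branch, a_branch = [], []
        for i in range(len(cfg.branch_kernels)):
            z = _conv1d(xc, p[f"branch{i}_W"], p[f"branch{i}_b"], d=1)
            z_branch.append(z)
            a_branch.append(np.maximum(z, 0.0))
        h = np.concatenate(a_branch, axis=1)            # (B, C, T)

        if self.fake_quant:
            aq, _ = quantize(h, cfg.q_bits)
            wq, _ = quantize(p["dilated_W"], cfg.q_bits)
        else:
            aq, wq = h, p["dilated_W"]
        if receptive_field(cfg.dilated_kernel, cfg.dilation) > T:
            raise ValueError("dilated stage: receptive field exceeds seq length")
        z2 = _conv1d(aq, wq, p["dilated_b"], d=cfg.dilation)   # (B, 64, T)
        u = z2.transpose(0, 2, 1)                       # (B, T, 64)

        mu = u.mean(axis=-1, keepdims=True)
        var = u.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (u - mu) * inv_std
        y = p["ln_g"] * xhat + p["ln_b"]

        H, dk = cfg.attn_heads, cfg.attn_dim // cfg.attn_heads
        q = y @ p["Wq"] + p["bq"]
        kk = y @ p["Wk"] + p["bk"]
        v = y @ p["Wv"] + p["bv"]

        def split(m):
            return m.reshape(B, T, H, dk).transpose(0, 2, 1, 3)

        qh, kh, vh = split(q), split(kk), split(v)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dk)
        attn = _softmax(scores, axis=-1)
        heads = attn @ vh
        concat = heads.transpose(0, 2, 1, 3).reshape(B, T, cfg.attn_dim)
        o = concat @ p["Wo"] + p["bo"]

        pooled = o.mean(axis=1)                         # (B, 64)
        logits = pooled @ p["Wc"] + p["bc"]

        if cache:
            self._cache = dict(
                x=x, xc=xc, z_branch=z_branch, h=h, aq=aq, wq=wq,
                xhat=xhat, inv_std=inv_std, y=y,
                qh=qh, kh=kh, vh=vh, attn=attn, concat=concat,
                pooled=pooled, T=T, B=B, H=H, dk=dk,
            )
        return logits[0] if single else logits

    # -- backward -----------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients w.r.t. all parameters given d(loss)/d(logits).

        Quantized tensors use straight-through gradients: the quantizer is
        treated as the identity in the backward pass (its adaptive step
        keeps every value inside the representable range).
        """
        if self._cache is None:
            raise RuntimeError("call forward(..., cache=True) first")
        c, cfg, p = self._cache, self.config, self.params
        B, T, H, dk = c["B"], c["T"], c["H"], c["dk"]
        g: dict[str, np.ndarray] = {}

        g["Wc"] = c["pooled"].T @ dlogits
        g["bc"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["Wc"].T
        do = np.repeat(dpooled[:, None, :] / T, T, axis=1)

        g["Wo"] = c["concat"].reshape(-1, cfg.attn_dim).T @ do.reshape(-1, cfg.attn_dim)
        g["bo"] = do.sum(axis=(0, 1))
        dconcat = do @ p["Wo"].T
        dheads = dconcat.reshape(B, T, H, dk).transpose(0, 2, 1, 3)

        dattn = dheads @ c["vh"].transpose(0, 1, 3, 2)
        dvh = c["attn"].transpose(0, 1, 3, 2) @ dheads
        attn = c["attn"]
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dk)
        dqh = dscores @ c["kh"]
        dkh = dscores.transpose(0, 1, 3, 2) @ c["qh"]

        def merge(m):
            return m.transpose(0, 2, 1, 3).reshape(B, T, cfg.attn_dim)

        dq, dkk, dv = merge(dqh), merge(dkh), merge(dvh)
        y2 = c["y"].reshape(-1, cfg.attn_dim)
        dy = np.zeros_like(c["y"])
        for name, dm in (("Wq", dq), ("Wk", dkk), ("Wv", dv)):
            g[name] = y2.T @ dm.reshape(-1, cfg.attn_dim)
            g["b" + name[1:].lower()] = dm.sum(axis=(0, 1))
            dy += dm @ p[name].T

        xhat, inv_std = c["xhat"], c["inv_std"]
        g["ln_g"] = (dy * xhat).sum(axis=(0, 1))
        g["ln_b"] = dy.sum(axis=(0, 1))
        dxhat = dy * p["ln_g"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        du = inv_std * (dxhat - m1 - xhat * m2)

        dz2 = du.transpose(0, 2, 1)                     # (B, 64, T)
        dh, g["dilated_W"], g["dilated_b"] = _conv1d_backward(
            dz2, c["aq"], c["wq"], cfg.dilation
        )

        offset = 0
        dxc = np.zeros_like(c["xc"])
        for i, cc in enumerate(cfg.branch_channels):
            dzi = dh[:, offset : offset + cc, :] * (c["z_branch"][i] > 0)
            dxi, dwi, dbi = _conv1d_backward(dzi, c["xc"], p[f"branch{i}_W"], 1)
            g[f"branch{i}_W"] = dwi
            g[f"branch{i}_b"] = dbi
            dxc += dxi
            offset += cc
        g["_dx"] = dxc.transpose(0, 2, 1)   # input gradient, for diagnostics
        return g

    # -- bookkeeping ---------------------------------------------------------
    def parameter_sizes(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.params.items()}

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def forward(seq: np.ndarray, config: ModelConfig,
            weights: dict[str, np.ndarray]) -> np.ndarray:
    """Functional forward pass: sequence(s) + weights -> class scores."""
    return LTYCNN(config, params=weights).forward(seq)


def count_parameters(config: ModelConfig) -> int:
    """Brute-force parameter count: instantiate and sum every tensor size."""
    return LTYCNN(config, seed=0).n_parameters()
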