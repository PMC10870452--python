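"""Training and evaluation: cross-entropy + Adam with straight-through
quantization gradients, stratified/grouped k-fold cross-validation, and
the standard detection metrics.

Metrics follow the usual confusion-matrix definitions —
``Acc = (TP+TN)/(TP+TN+FP+FN)``, ``Sen = TP/(TP+FN)``,
``Spe = TN/(TN+FP)``, ``TPR = Sen``, ``FPR = FP/(FP+TN)`` — with
zero-denominator ratios reported as NaN plus an explicit flag, never as a
silent 0.  The ROC is built by sweeping every score threshold and the AUC
by trapezoidal integration; with midpoint tie handling it coincides with
the Mann-Whitney concordance probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ltycnn import LTYCNN, ModelConfig

__all__ = [
    "TrainConfig",
    "MetricResult",
    "FoldResult",
    "EvalReport",
    "compute_metrics",
    "roc_auc",
    "kfold_split",
    "Adam",
    "TrainedModel",
    "train",
    "evaluate_cv",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    k_folds: int = 5
    seed: int = 0
    stratified: bool = True
    group_by_recording: bool = False

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricResult:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "acc": self.acc, "sen": self.sen, "spe": self.spe,
            "undefined": list(self.undefined),
        }


def compute_metrics(pred_labels, true_labels) -> MetricResult:
    """Confusion counts and Acc/Sen/Spe from hard 0/1 predictions."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    undefined = []
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else math.nan
    if total == 0:
        undefined.append("acc")
    if tp + fn:
        sen = tp / (tp + fn)
    else:
        sen = math.nan
        undefined.append("sen")
    if tn + fp:
        spe = tn / (tn + fp)
    else:
        spe = math.nan
        undefined.append("spe")
    return MetricResult(tp, tn, fp, fn, acc, sen, spe, undefined)


def roc_auc(scores, true_labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over all score thresholds + trapezoidal AUC.

    Requires both classes present.  Ties contribute half a concordance
    each (trapezoid over the tied block), so the AUC equals the
    Mann-Whitney U statistic probability.
    """
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true_labels)
    if scores.shape != true.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int((true == 1).sum())
    n_neg = int((true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], true[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep only the last point of each tied-score block
    distinct = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def kfold_split(labels, k: int, seed: int = 0, stratified: bool = True,
                groups=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint, covering (train, test) index pairs via sklearn splitters.

    ``labels`` may be an array of 0/1 labels or a WindowSet (in which case
    ``groups`` defaults to its per-window source recording when grouped
    splitting is requested through a non-None ``groups``).
    """
    from sklearn.model_selection import (
        GroupKFold, KFold, StratifiedGroupKFold, StratifiedKFold,
    )

    if hasattr(labels, "labels"):  # WindowSet duck-typing
        labels = labels.labels
    y = np.asarray(labels)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds number of windows n={n}")
    if stratified and k > min(np.bincount(y, minlength=2)[np.bincount(y, minlength=2) > 0]):
        raise ValueError("stratified k exceeds the smallest class count")
    x_dummy = np.zeros((n, 1))
    if groups is not None:
        cls = StratifiedGroupKFold if stratified else GroupKFold
        splitter = cls(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(x_dummy, y, groups=np.asarray(groups))
    elif stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(x_dummy, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(x_dummy, y)
    return [(np.asarray(tr), np.asarray(te)) for tr, te in folds]


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam over a name -> array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k in params:
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _cross_entropy(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -float(np.mean(logp[np.arange(len(y)), y]))
    probs = np.exp(logp)
    dlogits = probs.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    return loss, dlogits / len(y)


@dataclass
class TrainedModel:
    model: LTYCNN
    loss_curve: list[float]
    feature_scale: float = 1.0

    def predict_scores(self, sequences: np.ndarray) -> np.ndarray:
        """Probability of the ictal class per window."""
        logits = self.model.forward(np.asarray(sequences) * self.feature_scale)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return p[:, 1]

    def predict_labels(self, sequences: np.ndarray) -> np.ndarray:
        return (self.predict_scores(sequences) >= 0.5).astype(int)


def train(sequences: np.ndarray, labels: np.ndarray,
          model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None) -> TrainedModel:
    """Minimize cross-entropy with Adam; quantized layers use
    straight-through gradients.  Deterministic for a fixed seed.

    ``sequences`` is (n, T, D).  Features are rescaled by the inverse
    global RMS of the training set so the quantized stream starts in a
    well-conditioned range; the scale is stored with the model.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    x = np.asarray(sequences, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 3:
        raise ValueError("sequences must be (n, T, D)")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    rms = float(np.sqrt(np.mean(x**2)))
    scale = 1.0 / rms if rms > 0 else 1.0
    xs = x * scale

    rng = np.random.default_rng(train_config.seed)
    model = LTYCNN(model_config, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(model.params, lr=train_config.learning_rate)
    n = len(xs)
    bs = min(train_config.batch_size, n)
    loss_curve: list[float] = []
    for _epoch in range(train_config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, bs):
            idx = perm[i : i + bs]
            logits = model.forward(xs[idx], cache=True)
            loss, dlogits = _cross_entropy(logits, y[idx])
            grads = model.backward(dlogits)
            grads.pop("_dx", None)
            if train_config.learning_rate > 0:
                opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        loss_curve.append(epoch_loss / n)
    return TrainedModel(model=model, loss_curve=loss_curve, feature_scale=scale)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    metrics: MetricResult
    auc: float
    roc: list[tuple[float, float]]
    loss_curve: list[float]
    test_idx: np.ndarray

    def as_dict(self) -> dict:
        d = self.metrics.as_dict()
        d["auc"] = self.auc
        d["n_test"] = int(len(self.test_idx))
        return d


@dataclass
class EvalReport:
    per_fold: list[FoldResult]

    @property
    def mean_acc(self) -> float:
        return float(np.mean([f.metrics.acc for f in self.per_fold]))

    @property
    def mean_sen(self) -> float:
        return float(np.nanmean([f.metrics.sen for f in self.per_fold]))

    @property
    def mean_spe(self) -> float:
        return float(np.nanmean([f.metrics.spe for f in self.per_fold]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.per_fold]))

    def pooled_confusion(self) -> dict:
        return {
            key: int(sum(getattr(f.metrics, key.lower()) for f in self.per_fold))
            for key in ("TP", "TN", "FP", "FN")
        }

    def as_dict(self) -> dict:
        return {
            "per_fold": [f.as_dict() for f in self.per_fold],
            "mean": {
                "acc": self.mean_acc, "sen": self.mean_sen,
                "spe": self.mean_spe, "auc": self.mean_auc,
            },
            "pooled_confusion": self.pooled_confusion(),
        }


def evaluate_cv(windows, model_config: ModelConfig | None = None,
                train_config: TrainConfig | None = None,
                pca_k: int = 64, pca_max_frames: int = 6000,
                permute_labels: bool = False) -> EvalReport:
    """K-fold cross-validated train/evaluate on a labeled WindowSet.

    Spectrograms are computed once; the PCA basis is refit on each fold's
    *training* windows only (optionally on a seeded subsample of frames to
    bound the decomposition cost) and applied to both splits, so no test
    statistic leaks into the features.  ``permute_labels`` shuffles labels
    once up front — the permutation-null control.
    """
    from .features import compute_spectrogram, fit_pca, spectrogram_frames, apply_pca

    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    y = windows.labels.copy()
    rng = np.random.default_rng(train_config.seed)
    if permute_labels:
        y = rng.permutation(y)

    spects = [compute_spectrogram(w, fs=windows.fs) for w in windows.windows]
    frames = np.stack([spectrogram_frames(s) for s in spects])  # (n, T, d)
    n, t_frames, d = frames.shape

    groups = (np.asarray(windows.source_id)
              if train_config.group_by_recording else None)
    folds = kfold_split(y, train_config.k_folds, seed=train_config.seed,
                        stratified=train_config.stratified, groups=groups)

    results: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {fold_i}: a split is single-class")
        train_frames = frames[tr].reshape(-1, d)
        if len(train_frames) > pca_max_frames:
            pick = np.random.default_rng(train_config.seed + fold_i).choice(
                len(train_frames), size=pca_max_frames, replace=False)
            fit_frames = train_frames[pick]
        else:
            fit_frames = train_frames
        basis = fit_pca(fit_frames, k=pca_k)
        seq_tr = apply_pca(frames[tr].reshape(-1, d), basis).reshape(
            len(tr), t_frames, pca_k)
        seq_te = apply_pca(frames[te].reshape(-1, d), basis).reshape(
            len(te), t_frames, pca_k)
        fitted = train(seq_tr, y[tr], model_config, train_config)
        scores = fitted.predict_scores(seq_te)
        pred = (scores >= 0.5).astype(int)
        metrics = compute_metrics(pred, y[te])
        roc, auc = roc_auc(scores, y[te])
        results.append(FoldResult(metrics, auc, roc, fitted.loss_curve,
                                  np.asarray(te)))
    return EvalReport(per_fold=results)
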