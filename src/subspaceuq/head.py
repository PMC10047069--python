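"""The classifier head: feature normalization, dropout, dense softmax.

Architecture (the only trainable parts of the full model): the embedding is
batch-normalized, 50% of features are randomly masked by inverted dropout
during training, and a single dense layer with softmax produces the
(ACP, NOTACP) probability pair. Training uses a sparse-aware adaptive-moment
optimizer with decoupled weight decay, a triangular cyclic learning rate and
categorical cross-entropy; per-epoch parameter snapshots feed the SWA /
subspace stage.

Class index 0 is ACP (the positive class), index 1 is NOTACP.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import ACP, NOTACP, EmbeddingDataset

_BN_EPS = 1e-3
_CLIP_EPS = 1e-12


@dataclasses.dataclass
class HeadParameters:
    """All optimizable parameters plus the normalization running statistics.

    Flattens (in the fixed order scale, shift, mean, var, dense_w row-major,
    dense_b) to a single vector of length ``6 * dim + 2``; the trailing
    ``2 * dim + 2`` coordinates are the dense layer, the only part that is
    calibrated for uncertainty downstream.
    """

    norm_scale: np.ndarray
    norm_shift: np.ndarray
    norm_mean: np.ndarray
    norm_var: np.ndarray
    dense_w: np.ndarray  # (dim, 2)
    dense_b: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        d = self.norm_scale.shape[0]
        if self.dense_w.shape != (d, 2) or self.dense_b.shape != (2,):
            raise ValueError("dense layer shape inconsistent with dim")
        if np.any(self.norm_var <= 0):
            raise ValueError("norm_var must be strictly positive")

    @property
    def dim(self) -> int:
        return self.norm_scale.shape[0]

    @property
    def n_params(self) -> int:
        return 6 * self.dim + 2

    @staticmethod
    def dense_slice(dim: int) -> slice:
        """Location of the dense-layer coordinates in the flattened vector."""
        return slice(4 * dim, 6 * dim + 2)

    @classmethod
    def zeros(cls, dim: int) -> "HeadParameters":
        return cls(
            norm_scale=np.ones(dim),
            norm_shift=np.zeros(dim),
            norm_mean=np.zeros(dim),
            norm_var=np.ones(dim),
            dense_w=np.zeros((dim, 2)),
            dense_b=np.zeros(2),
        )

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [
                self.norm_scale,
                self.norm_shift,
                self.norm_mean,
                self.norm_var,
                self.dense_w.ravel(),
                self.dense_b,
            ]
        )

    @classmethod
    def unflatten(cls, vec: np.ndarray, dim: int) -> "HeadParameters":
        if vec.shape != (6 * dim + 2,):
            raise ValueError(f"expected flattened length {6 * dim + 2}, got {vec.shape}")
        return cls(
            norm_scale=vec[0:dim].copy(),
            norm_shift=vec[dim : 2 * dim].copy(),
            norm_mean=vec[2 * dim : 3 * dim].copy(),
            norm_var=vec[3 * dim : 4 * dim].copy(),
            dense_w=vec[4 * dim : 6 * dim].reshape(dim, 2).copy(),
            dense_b=vec[6 * dim : 6 * dim + 2].copy(),
        )

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(v).tolist() for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HeadParameters":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=np.float64) for k, v in payload.items()})


class TrainConfig(BaseModel):
    """Training recipe for the head.

    The optimizer components (cyclic learning rate, decoupled weight decay,
    lazy adaptive moments) are fixed by the method; their numeric values are
    not pinned by it, so every one is exposed here with a documented default.
    """

    batch_size: int = Field(default=2, ge=1)
    dropout_rate: float = Field(default=0.5, ge=0.0, lt=1.0)
    epochs: int = Field(default=50, ge=1)
    base_lr: float = Field(default=1e-3, gt=0.0)
    max_lr: float = Field(default=1e-2, gt=0.0)
    cycle_len: int = Field(default=100, ge=2)
    weight_decay: float = Field(default=1e-4, ge=0.0, lt=1.0)
    adam_beta1: float = Field(default=0.9, ge=0.0, lt=1.0)
    adam_beta2: float = Field(default=0.999, ge=0.0, lt=1.0)
    adam_eps: float = Field(default=1e-8, gt=0.0)
    sparse_updates: bool = True
    bn_momentum: float = Field(default=0.99, ge=0.0, lt=1.0)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_lr(self) -> "TrainConfig":
        if self.base_lr > self.max_lr:
            raise ValueError("base_lr must not exceed max_lr")
        return self


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def hidden_activation(
    params: HeadParameters,
    x: np.ndarray,
    training: bool = False,
    dropout_rate: float = 0.0,
    dropout_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Normalized (and, in training, dropout-masked) features before the dense layer."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != params.dim:
        raise ValueError(f"expected input with {params.dim} columns, got {x.shape}")
    if training:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
    else:
        mean, var = params.norm_mean, params.norm_var
    h = params.norm_scale * (x - mean) / np.sqrt(var + _BN_EPS) + params.norm_shift
    if training and dropout_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng(dropout_seed)
        mask = rng.random(h.shape) >= dropout_rate
        h = h * mask / (1.0 - dropout_rate)
    return h


def forward(
    params: HeadParameters,
    x: np.ndarray,
    training: bool = False,
    dropout_rate: float = 0.0,
    dropout_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Push embeddings through normalize -> dropout -> dense -> softmax.

    Training mode normalizes with batch statistics and applies an inverted
    dropout mask; inference mode uses the running statistics and no dropout,
    so it is deterministic for fixed parameters.
    """
    h = hidden_activation(params, x, training, dropout_rate, dropout_seed, rng)
    return softmax(h @ params.dense_w + params.dense_b)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy of probability rows vs one-hot labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must be aligned")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    return float(-np.mean(np.sum(labels * np.log(np.clip(probs, _CLIP_EPS, 1.0)), axis=1)))


def cyclic_lr(step: int, cfg: TrainConfig) -> float:
    """Triangular learning-rate wave: base at the cycle start, max at mid-cycle."""
    if step < 0:
        raise ValueError("step must be non-negative")
    half = cfg.cycle_len / 2.0
    phase = step % cfg.cycle_len
    frac = phase / half if phase <= half else (cfg.cycle_len - phase) / half
    return cfg.base_lr + (cfg.max_lr - cfg.base_lr) * frac


def head_with_frozen_norm(vec: np.ndarray, frozen: np.ndarray, dim: int) -> HeadParameters:
    """Head whose dense layer comes from ``vec`` and normalization from ``frozen``.

    Only the dense layer is calibrated for uncertainty; normalization
    statistics and scales stay pinned at their SWA values, carried by the
    ``frozen`` flattened vector (typically the subspace anchor mean).
    """
    out = np.asarray(frozen, dtype=np.float64).copy()
    sl = HeadParameters.dense_slice(dim)
    out[sl] = np.asarray(vec, dtype=np.float64)[sl]
    return HeadParameters.unflatten(out, dim)


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, 2))
    out[np.arange(y.size), y] = 1.0
    return out


class _AdamWState:
    """Adaptive moments with decoupled decay; lazily skips zero-gradient slices."""

    def __init__(self, shape: tuple[int, ...], cfg: TrainConfig) -> None:
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = np.zeros(shape[0] if len(shape) else (), dtype=np.int64)
        self.cfg = cfg

    def step(self, param: np.ndarray, grad: np.ndarray, lr: float) -> None:
        cfg = self.cfg
        if cfg.sparse_updates:
            if grad.ndim == 2:
                active = np.any(grad != 0.0, axis=1)
            else:
                active = grad != 0.0
        else:
            active = np.ones(grad.shape[0], dtype=bool)
        if not np.any(active):
            return
        g = grad[active]
        self.m[active] = cfg.adam_beta1 * self.m[active] + (1 - cfg.adam_beta1) * g
        self.v[active] = cfg.adam_beta2 * self.v[active] + (1 - cfg.adam_beta2) * g * g
        self.t[active] += 1
        t = self.t[active].astype(np.float64)
        bc1 = 1.0 - cfg.adam_beta1 ** t
        bc2 = 1.0 - cfg.adam_beta2 ** t
        if grad.ndim == 2:
            bc1, bc2 = bc1[:, None], bc2[:, None]
        mhat = self.m[active] / bc1
        vhat = self.v[active] / bc2
        param[active] -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)


def fit(
    dataset: EmbeddingDataset, cfg: TrainConfig
) -> tuple[HeadParameters, list[np.ndarray]]:
    """Train the head on the dataset's training split.

    Returns the final parameters and one flattened snapshot per epoch.
    Deterministic given ``cfg.seed``.
    """
    train = dataset.select("train")
    if train.n_images == 0:
        raise ValueError("training split is empty")
    head = SoftmaxHead(**cfg.model_dump())
    head.fit(train.features, train.y())
    return head.params_, head.snapshots_


def evaluate(params: HeadParameters, dataset: EmbeddingDataset, split: str) -> dict[str, float]:
    """Accuracy and AUPR (ACP positive) of the head on one split."""
    part = dataset.select(split)
    if part.n_images == 0:
        raise ValueError(f"split {split!r} is empty")
    probs = forward(params, part.features, training=False)
    y = part.y()
    pred = np.where(probs[:, 0] > probs[:, 1], 0, 1)  # tie -> NOTACP
    return {
        "accuracy": float(np.mean(pred == y)),
        "aupr": aupr(probs[:, 0], (y == 0).astype(int)),
    }


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision: mean over positives of the precision at their rank.

    Ranks are by descending score with ties broken by stable sort order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("aupr requires at least one positive label")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_pos = np.cumsum(ranked)
    precision_at_rank = cum_pos / np.arange(1, ranked.size + 1)
    return float(precision_at_rank[ranked == 1].sum() / n_pos)


class SoftmaxHead(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for the batch-norm / dropout / softmax head.

    Parameters mirror :class:`TrainConfig`. After :meth:`fit` the estimator
    exposes ``params_`` (a :class:`HeadParameters`) and ``snapshots_`` (one
    flattened parameter vector per epoch, consumed by the SWA stage).

    Inputs to ``fit`` are embeddings ``X`` of shape (n, dim) and integer
    labels ``y`` with 0 = ACP, 1 = NOTACP.
    """

    def __init__(
        self,
        batch_size: int = 2,
        dropout_rate: float = 0.5,
        epochs: int = 50,
        base_lr: float = 1e-3,
        max_lr: float = 1e-2,
        cycle_len: int = 100,
        weight_decay: float = 1e-4,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        adam_eps: float = 1e-8,
        sparse_updates: bool = True,
        bn_momentum: float = 0.99,
        seed: int = 0,
    ) -> None:
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.cycle_len = cycle_len
        self.weight_decay = weight_decay
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.sparse_updates = sparse_updates
        self.bn_momentum = bn_momentum
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(**self.get_params())

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxHead":
        cfg = self._config()
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            y = np.where(y == ACP, 0, 1)
        y = y.astype(int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched lengths")
        n, dim = X.shape
        rng = np.random.default_rng(cfg.seed)

        params = HeadParameters.zeros(dim)
        # small symmetric init for the dense layer so gradients break symmetry
        params.dense_w = 0.01 * rng.standard_normal((dim, 2))
        params.norm_mean = X.mean(axis=0)
        params.norm_var = np.maximum(X.var(axis=0), _BN_EPS)

        Y = _one_hot(y)
        opt_w = _AdamWState((dim, 2), cfg)
        opt_b = _AdamWState((2,), cfg)
        opt_gamma = _AdamWState((dim,), cfg)
        opt_beta = _AdamWState((dim,), cfg)

        step = 0
        snapshots: list[np.ndarray] = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], Y[idx]
                bmean = xb.mean(axis=0)
                bvar = xb.var(axis=0)
                xhat = (xb - bmean) / np.sqrt(bvar + _BN_EPS)
                hnorm = params.norm_scale * xhat + params.norm_shift
                if cfg.dropout_rate > 0.0:
                    mask = (rng.random(hnorm.shape) >= cfg.dropout_rate) / (
                        1.0 - cfg.dropout_rate
                    )
                else:
                    mask = np.ones_like(hnorm)
                h = hnorm * mask
                probs = softmax(h @ params.dense_w + params.dense_b)
                loss = cross_entropy(probs, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at step {step}")

                b = xb.shape[0]
                dlogits = (probs - yb) / b
                grad_w = h.T @ dlogits
                grad_b = dlogits.sum(axis=0)
                dh = (dlogits @ params.dense_w.T) * mask
                grad_gamma = (dh * xhat).sum(axis=0)
                grad_beta = dh.sum(axis=0)

                lr = cyclic_lr(step, cfg)
                # decoupled decay: shrink dense weights directly, independent of lr
                if cfg.weight_decay > 0.0:
                    params.dense_w *= 1.0 - cfg.weight_decay
                opt_w.step(params.dense_w, grad_w, lr)
                opt_b.step(params.dense_b, grad_b, lr)
                opt_gamma.step(params.norm_scale, grad_gamma, lr)
                opt_beta.step(params.norm_shift, grad_beta, lr)

                m = cfg.bn_momentum
                params.norm_mean = m * params.norm_mean + (1 - m) * bmean
                params.norm_var = np.maximum(m * params.norm_var + (1 - m) * bvar, _BN_EPS)
                step += 1
            snapshots.append(params.flatten())

        self.params_ = params
        self.snapshots_ = snapshots
        self.classes_ = np.array([ACP, NOTACP], dtype=object)
        self.n_features_in_ = dim
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=np.float64)
        return forward(self.params_, X, training=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.where(probs[:, 0] > probs[:, 1], ACP, NOTACP).astype(object)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        y = np.asarray(y)
        if y.dtype.kind not in "OUS":
            y = np.where(np.asarray(y).astype(int) == 0, ACP, NOTACP).astype(object)
        return float(np.mean(self.predict(X) == y))
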