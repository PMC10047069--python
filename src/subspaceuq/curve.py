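"""Quadratic Bezier curve connecting two SWA solutions in the PCA subspace.

The curve phi_theta(t) = (1-t)^2 w1 + 2 t (1-t) theta + t^2 w2 has its
endpoints pinned at the subspace coordinates of the two SWA-tuned heads;
only the midpoint control vector theta is trained, so that the whole curve
traverses a low-loss region of parameter space (mode connectivity). Every
curve point is a convex combination of {w1, theta, w2}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .datasets import EmbeddingDataset
from .head import cross_entropy, forward, head_with_frozen_norm, aupr, _one_hot, softmax
from .swa import SubspaceBasis, to_full


@dataclasses.dataclass
class BezierCurve:
    """Three control vectors in subspace coordinates; endpoints immutable."""

    w1: np.ndarray
    theta: np.ndarray
    w2: np.ndarray
    frozen: bool = True

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        if not (self.w1.shape == self.theta.shape == self.w2.shape):
            raise ValueError("w1, theta, w2 must have identical shapes")

    @classmethod
    def from_endpoints(cls, w1: np.ndarray, w2: np.ndarray) -> "BezierCurve":
        """Midpoint-initialized curve: theta = (w1+w2)/2 is the straight segment."""
        w1 = np.asarray(w1, dtype=np.float64)
        w2 = np.asarray(w2, dtype=np.float64)
        return cls(w1=w1, theta=0.5 * (w1 + w2), w2=w2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"w1": self.w1.tolist(), "theta": self.theta.tolist(), "w2": self.w2.tolist()}
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BezierCurve":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["w1"]), np.asarray(payload["theta"]), np.asarray(payload["w2"])
        )


def bezier_coefficients(t: float) -> tuple[float, float, float]:
    """((1-t)^2, 2t(1-t), t^2); nonnegative on [0,1] and summing to 1."""
    return (1.0 - t) ** 2, 2.0 * t * (1.0 - t), t**2


def evaluate_curve(curve: BezierCurve, t: float) -> np.ndarray:
    """Point on the quadratic Bezier curve at position t in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    a1, a2, a3 = bezier_coefficients(t)
    return a1 * curve.w1 + a2 * curve.theta + a3 * curve.w2


def _curve_loss_and_theta_grad(
    curve: BezierCurve,
    t: float,
    basis: SubspaceBasis,
    X: np.ndarray,
    Y: np.ndarray,
    dim: int,
) -> tuple[float, np.ndarray]:
    """Training cross-entropy at phi(t) and its gradient with respect to theta.

    The loss sees only the dense-layer coordinates (normalization is frozen
    at the subspace anchor), so the chain rule reduces to the dense block of
    the basis times the Bezier midpoint coefficient 2t(1-t).
    """
    _, a2, _ = bezier_coefficients(t)
    z = evaluate_curve(curve, t)
    vec = to_full(basis, z)
    params = head_with_frozen_norm(vec, basis.mean, dim)
    h = params.norm_scale * (X - params.norm_mean) / np.sqrt(
        params.norm_var + 1e-3
    ) + params.norm_shift
    probs = softmax(h @ params.dense_w + params.dense_b)
    loss = cross_entropy(probs, Y)
    n = X.shape[0]
    dlogits = (probs - Y) / n
    grad_dense = np.concatenate([(h.T @ dlogits).ravel(), dlogits.sum(axis=0)])
    sl = slice(4 * dim, 6 * dim + 2)
    grad_z = basis.basis[:, sl] @ grad_dense
    return loss, a2 * grad_z


def fit_curve(
    curve: BezierCurve,
    basis: SubspaceBasis,
    dataset: EmbeddingDataset,
    epochs: int = 50,
    lr: float = 0.05,
    seed: int = 0,
    steps_per_epoch: int = 10,
    t_batch: int = 1,
) -> tuple[BezierCurve, list[dict[str, float]]]:
    """Optimize the midpoint theta so the curve crosses low-loss territory.

    Each step samples ``t_batch`` positions t ~ Uniform[0, 1], maps phi(t)
    through the subspace basis to full head parameters, and takes an Adam
    step on theta against the training cross-entropy; the endpoints are
    never touched. Returns the fitted curve and a per-epoch trace of test
    accuracy/AUPR evaluated at the curve midpoint t = 0.5.
    """
    rng = np.random.default_rng(seed)
    train = dataset.select("train")
    if train.n_images == 0:
        raise ValueError("training split is empty")
    dim = train.dim
    X, Y = train.features, _one_hot(train.y())
    test = dataset.select("test")

    theta = curve.theta.copy()
    w1, w2 = curve.w1.copy(), curve.w2.copy()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[dict[str, float]] = []
    for _epoch in range(epochs):
        for _ in range(steps_per_epoch):
            grad = np.zeros_like(theta)
            loss_acc = 0.0
            work = BezierCurve(w1, theta, w2)
            for _ in range(t_batch):
                t = float(rng.uniform())
                loss, g = _curve_loss_and_theta_grad(work, t, basis, X, Y, dim)
                loss_acc += loss
                grad += g
            grad /= t_batch
            if not np.isfinite(loss_acc):
                raise RuntimeError("non-finite curve-fitting loss")
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad * grad
            theta -= lr * (m / (1 - beta1**step)) / (
                np.sqrt(v / (1 - beta2**step)) + eps
            )
        if test.n_images > 0:
            mid = to_full(basis, evaluate_curve(BezierCurve(w1, theta, w2), 0.5))
            params = head_with_frozen_norm(mid, basis.mean, dim)
            probs = forward(params, test.features, training=False)
            ytest = test.y()
            trace.append(
                {
                    "accuracy": float(np.mean(np.where(probs[:, 0] > probs[:, 1], 0, 1) == ytest)),
                    "aupr": aupr(probs[:, 0], (ytest == 0).astype(int)),
                }
            )
    fitted = BezierCurve(w1=curve.w1, theta=theta, w2=curve.w2, frozen=True)
    return fitted, trace


def curve_weight_spread(curve: BezierCurve, t_grid: np.ndarray) -> dict[str, float]:
    """Coordinate-pooled variances of curve points and of each control vector.

    Diagnostic for the observation that curve weights spread wider than any
    single anchor: all coordinates of all phi(t) samples are pooled into one
    variance, compared against the pooled variance of w1, theta, w2.
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    if t_grid.size == 0:
        raise ValueError("t_grid is empty")
    if np.any((t_grid < 0) | (t_grid > 1)):
        raise ValueError("t_grid values must lie in [0, 1]")
    points = np.vstack([evaluate_curve(curve, float(t)) for t in t_grid])
    return {
        "curve_variance": float(points.var()),
        "w1_variance": float(curve.w1.var()),
        "theta_variance": float(curve.theta.var()),
        "w2_variance": float(curve.w2.var()),
    }
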