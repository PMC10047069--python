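"""Elliptical slice sampling over the Bezier curve's induced subspace.

The posterior over head parameters is approximated inside a 2-d affine
"curve subspace" spanned by the endpoint axis (w2 - w1)/2 and the midpoint
axis theta - (w1 + w2)/2, centred at the segment midpoint. Coordinates get
an isotropic Gaussian prior; the likelihood is the training-set categorical
cross-entropy (scaled by the training count and an optional temperature).
Elliptical slice sampling (a rejection-free MCMC transition exact for
Gaussian priors) draws posterior coordinates, each of which is mapped back
to full head parameters (dense layer only; normalization frozen at the SWA
values) and pushed through the model to give, per test case, a matrix of
sampled (ACP, NOTACP) probability pairs — the predictive distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from pydantic import BaseModel, Field
from scipy.stats import norm as _norm

from .curve import BezierCurve, evaluate_curve
from .datasets import EmbeddingDataset
from .head import HeadParameters, _one_hot, cross_entropy, head_with_frozen_norm, softmax
from .swa import SubspaceBasis, to_full

_BN_EPS = 1e-3


class ESSConfig(BaseModel):
    """Sampler settings; defaults give 5000 predictive draws per case."""

    n_samples: int = Field(default=5000, ge=1)
    burn_in: int = Field(default=500, ge=0)
    thinning: int = Field(default=1, ge=1)
    prior_sd: float = Field(default=1.0, gt=0.0)
    temperature: float = Field(default=1.0, gt=0.0)
    space: str = Field(default="curve2d", pattern="^(curve2d|t1d)$")
    max_steps: int = Field(default=2_000_000, ge=1)
    seed: int = Field(default=0, ge=0)


@dataclasses.dataclass
class CurveSubspace:
    """Affine map from sampler coordinates to PCA-subspace coordinates.

    In the default 2-d mode, z = (-1, 0) is w1, (1, 0) is w2 and (0, 1) is
    theta. In the 1-d mode a scalar coordinate is squashed through the
    standard-normal CDF to a curve position t and evaluated on the Bezier
    curve itself.
    """

    curve: BezierCurve
    prior_sd: float = 1.0
    space: str = "curve2d"

    def __post_init__(self) -> None:
        c = 0.5 * (self.curve.w1 + self.curve.w2)
        self.center = c
        self.axis_end = 0.5 * (self.curve.w2 - self.curve.w1)
        self.axis_mid = self.curve.theta - c

    @property
    def n_coords(self) -> int:
        return 2 if self.space == "curve2d" else 1

    def map(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=np.float64))
        if z.shape != (self.n_coords,):
            raise ValueError(f"expected {self.n_coords} coordinates, got {z.shape}")
        if self.space == "curve2d":
            return self.center + z[0] * self.axis_end + z[1] * self.axis_mid
        t = float(_norm.cdf(z[0] / self.prior_sd))
        return evaluate_curve(self.curve, t)


@dataclasses.dataclass
class PredictiveDistribution:
    """Per-case S x 2 matrix of sampled (ACP, NOTACP) probabilities.

    Under a two-class softmax the columns sum to one row-wise, so the two
    class variances are identical by construction.
    """

    case_id: str
    samples: np.ndarray
    class_means: np.ndarray = dataclasses.field(init=False)
    class_variances: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an S x 2 matrix")
        if np.any(np.abs(self.samples.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("sample rows must sum to 1")
        self.class_means = self.samples.mean(axis=0)
        self.class_variances = self.samples.var(axis=0)

    @property
    def acp_samples(self) -> np.ndarray:
        """The ACP-probability margin; the NOTACP margin is its mirror."""
        return self.samples[:, 0]


def ess_step(
    current: np.ndarray,
    log_lik,
    prior_sd: float,
    rng: np.random.Generator,
    max_shrink: int = 1000,
) -> np.ndarray:
    """One elliptical slice sampling transition (shrinking-bracket form).

    Draws an auxiliary point from the N(0, prior_sd^2 I) prior, a log slice
    threshold under the current state, then shrinks an angle bracket around
    proposals on the ellipse through both points until the threshold is
    exceeded. Leaves prior x likelihood invariant; non-finite likelihoods
    are treated as log-likelihood -inf (the bracket just shrinks past them).
    """
    current = np.asarray(current, dtype=np.float64)
    ll_cur = float(log_lik(current))
    if not np.isfinite(ll_cur):
        raise ValueError("log-likelihood must be finite at the current state")
    nu = prior_sd * rng.standard_normal(current.shape)
    log_y = ll_cur + np.log(rng.uniform())
    angle = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = angle - 2.0 * np.pi, angle
    for _ in range(max_shrink):
        prop = current * np.cos(angle) + nu * np.sin(angle)
        ll = float(log_lik(prop))
        if np.isfinite(ll) and ll > log_y:
            return prop
        if angle < 0.0:
            lo = angle
        else:
            hi = angle
        angle = rng.uniform(lo, hi)
    return current  # bracket collapsed onto the current state


def _train_log_lik(
    subspace: CurveSubspace,
    basis: SubspaceBasis,
    X: np.ndarray,
    Y: np.ndarray,
    temperature: float,
):
    """Tempered training log-likelihood as a function of sampler coordinates.

    Normalization is frozen, so the normalized features are precomputed and
    each evaluation costs one dense layer + softmax.
    """
    dim = X.shape[1]
    anchor = HeadParameters.unflatten(basis.mean, dim)
    h = anchor.norm_scale * (X - anchor.norm_mean) / np.sqrt(
        anchor.norm_var + _BN_EPS
    ) + anchor.norm_shift
    n = X.shape[0]

    def log_lik(z: np.ndarray) -> float:
        vec = to_full(basis, subspace.map(z))
        params = head_with_frozen_norm(vec, basis.mean, dim)
        probs = softmax(h @ params.dense_w + params.dense_b)
        return -cross_entropy(probs, Y) * n / temperature

    return log_lik


def sample_posterior(
    curve: BezierCurve,
    basis: SubspaceBasis,
    train_data: EmbeddingDataset,
    cfg: ESSConfig,
) -> list[np.ndarray]:
    """Run the ESS chain and return exactly ``cfg.n_samples`` coordinate vectors.

    The chain starts at the curve-subspace origin (the segment midpoint),
    discards ``burn_in`` transitions and keeps every ``thinning``-th draw.
    Deterministic given ``cfg.seed``.
    """
    total = cfg.burn_in + cfg.n_samples * cfg.thinning
    if total > cfg.max_steps:
        raise ValueError(
            f"requested {total} ESS transitions exceeds the step cap {cfg.max_steps}"
        )
    train = train_data.select("train")
    if train.n_images == 0:
        raise ValueError("training split is empty")
    subspace = CurveSubspace(curve, prior_sd=cfg.prior_sd, space=cfg.space)
    log_lik = _train_log_lik(
        subspace, basis, train.features, _one_hot(train.y()), cfg.temperature
    )
    rng = np.random.default_rng(cfg.seed)
    z = np.zeros(subspace.n_coords)
    samples: list[np.ndarray] = []
    for step in range(total):
        z = ess_step(z, log_lik, cfg.prior_sd, rng)
        if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thinning == cfg.thinning - 1:
            samples.append(z.copy())
    return samples


def predictive_distributions(
    samples: list[np.ndarray],
    basis: SubspaceBasis,
    curve: BezierCurve,
    test_data: EmbeddingDataset,
    split: str = "test",
    prior_sd: float = 1.0,
    space: str = "curve2d",
) -> list[PredictiveDistribution]:
    """Push every posterior coordinate sample through the head for each case.

    Each sampled coordinate supplies the dense-layer weights; everything
    else stays frozen at the SWA values, so the normalized features are
    computed once and reused across all S samples.
    """
    part = test_data.select(split)
    if part.n_images == 0:
        raise ValueError(f"split {split!r} is empty")
    dim = part.dim
    subspace = CurveSubspace(curve, prior_sd=prior_sd, space=space)
    anchor = HeadParameters.unflatten(basis.mean, dim)
    h = anchor.norm_scale * (part.features - anchor.norm_mean) / np.sqrt(
        anchor.norm_var + _BN_EPS
    ) + anchor.norm_shift

    out = np.empty((len(samples), part.n_images, 2))
    for s, z in enumerate(samples):
        vec = to_full(basis, subspace.map(z))
        params = head_with_frozen_norm(vec, basis.mean, dim)
        out[s] = softmax(h @ params.dense_w + params.dense_b)
    return [
        PredictiveDistribution(case_id=str(part.case_ids[i]), samples=out[:, i, :])
        for i in range(part.n_images)
    ]
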