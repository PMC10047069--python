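"""End-to-end orchestration: simulate -> train x2 -> subspace -> curve -> ESS -> decide.

Two heads are trained from different seeds (defaults 6567 and 7656), SWA
collects their trajectories, a pooled PCA subspace is built over both runs'
deviation rows (plus each SWA solution's offset from the pooled mean, so
the direction connecting the endpoints is exactly representable), a Bezier
curve is fitted between the two projected solutions, elliptical slice
sampling draws posterior coordinates, calibration patients held out of
fitting supply the KS-branch reference distributions, and the two-branch
abstention rule scores the test patients.

The whole procedure is also packaged as the scikit-learn estimator
:class:`SubspaceAbstainClassifier`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import decision as decision_mod
from .curve import BezierCurve, fit_curve
from .datasets import (
    ACP,
    CALIB,
    NOTACP,
    TEST,
    TRAIN,
    EmbeddingDataset,
    SyntheticConfig,
    augment_embeddings,
    generate_embeddings,
    hold_out_calibration_patients,
)
from .decision import build_references, confusion_metrics, decide_cases, mean_difference_filter
from .ess import ESSConfig, predictive_distributions, sample_posterior
from .head import HeadParameters, TrainConfig, evaluate, fit as fit_head
from .swa import collect_from_snapshots, pca_subspace, project

logger = logging.getLogger("subspaceuq")


class SubspaceSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rank: int = Field(default=5, ge=1)
    collect_every: int = Field(default=10, ge=1)
    scale_by_singular_values: bool = False


class CurveSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(default=30, ge=1)
    steps_per_epoch: int = Field(default=10, ge=1)
    lr: float = Field(default=0.05, gt=0.0)
    t_batch: int = Field(default=1, ge=1)
    seed: int = Field(default=0, ge=0)


class DecisionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    calibration_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    calibration_seed: int = Field(default=97, ge=0)
    filter_alphas: list[float] = Field(default=[0.05, 0.01, 0.005, 0.001])


class PipelineConfig(BaseModel):
    """Validated, fully-defaulted configuration for a pipeline run."""

    model_config = ConfigDict(extra="forbid")

    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    seed_a: int = Field(default=6567, ge=0)
    seed_b: int = Field(default=7656, ge=0)
    subspace: SubspaceSettings = Field(default_factory=SubspaceSettings)
    curve: CurveSettings = Field(default_factory=CurveSettings)
    ess: ESSConfig = Field(default_factory=ESSConfig)
    decision: DecisionSettings = Field(default_factory=DecisionSettings)
    out_dir: str = "runs/latest"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_seeds(self) -> "PipelineConfig":
        if self.seed_a == self.seed_b:
            raise ValueError("seed_a and seed_b must differ (two independent models)")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and cross-validate a YAML config; empty file -> full defaults.

    All violations are reported at once (pydantic aggregates them).
    """
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig(**payload)


@dataclasses.dataclass
class FitBundle:
    """Everything the fitted pipeline needs to score new cases."""

    head_a: HeadParameters
    head_b: HeadParameters
    snapshots_a: list[np.ndarray]
    snapshots_b: list[np.ndarray]
    basis: "object"
    curve: BezierCurve
    curve_trace: list[dict[str, float]]
    coord_samples: list[np.ndarray]
    ref_acp: np.ndarray
    ref_notacp: np.ndarray
    config: PipelineConfig
    w1_init: np.ndarray | None = None
    w2_init: np.ndarray | None = None


def fit_stages(dataset: EmbeddingDataset, cfg: PipelineConfig) -> FitBundle:
    """Run the training-side stages on a dataset whose splits are prepared.

    Expects ``train`` (possibly augmented), ``calib`` and ``test`` tags to
    be in place already.
    """
    train_cfg_a = cfg.train.model_copy(update={"seed": cfg.seed_a})
    train_cfg_b = cfg.train.model_copy(update={"seed": cfg.seed_b})

    logger.info("training head A (seed %d)", cfg.seed_a)
    head_a, snaps_a = fit_head(dataset, train_cfg_a)
    logger.info("training head B (seed %d)", cfg.seed_b)
    head_b, snaps_b = fit_head(dataset, train_cfg_b)

    traj_a = collect_from_snapshots(snaps_a, cfg.subspace.collect_every)
    traj_b = collect_from_snapshots(snaps_b, cfg.subspace.collect_every)
    swa_a, swa_b = traj_a.running_mean, traj_b.running_mean
    pooled_mean = 0.5 * (swa_a + swa_b)

    merged = dataclasses.replace(
        traj_a, deviation_rows=traj_a.deviation_rows + traj_b.deviation_rows
    )
    basis = pca_subspace(
        merged,
        rank=cfg.subspace.rank,
        mean=pooled_mean,
        extra_rows=np.vstack([swa_a - pooled_mean, swa_b - pooled_mean]),
        scale_by_singular_values=cfg.subspace.scale_by_singular_values,
    )

    logger.info("fitting Bezier curve (rank-%d subspace)", basis.rank)
    w1_init = project(basis, swa_a)
    w2_init = project(basis, swa_b)
    curve0 = BezierCurve.from_endpoints(w1_init.copy(), w2_init.copy())
    curve, trace = fit_curve(
        curve0,
        basis,
        dataset,
        epochs=cfg.curve.epochs,
        lr=cfg.curve.lr,
        seed=cfg.curve.seed,
        steps_per_epoch=cfg.curve.steps_per_epoch,
        t_batch=cfg.curve.t_batch,
    )

    logger.info("elliptical slice sampling (%d samples)", cfg.ess.n_samples)
    coords = sample_posterior(curve, basis, dataset, cfg.ess)

    calib = dataset.select(CALIB)
    if calib.n_images == 0:
        raise RuntimeError("no calibration patients; set decision.calibration_fraction > 0")
    calib_preds = predictive_distributions(
        coords, basis, curve, dataset, split=CALIB,
        prior_sd=cfg.ess.prior_sd, space=cfg.ess.space,
    )
    truths = dict(zip(calib.case_ids.astype(str), calib.labels.astype(str)))
    ref_acp, ref_notacp = build_references(calib_preds, truths)

    return FitBundle(
        head_a=head_a,
        head_b=head_b,
        snapshots_a=snaps_a,
        snapshots_b=snaps_b,
        basis=basis,
        curve=curve,
        curve_trace=trace,
        coord_samples=coords,
        ref_acp=ref_acp,
        ref_notacp=ref_notacp,
        config=cfg,
        w1_init=w1_init,
        w2_init=w2_init,
    )


def prepare_dataset(cfg: PipelineConfig) -> EmbeddingDataset:
    """Simulate the cohort, carve calibration patients, augment training."""
    ds = generate_embeddings(cfg.synthetic)
    ds = hold_out_calibration_patients(
        ds, cfg.decision.calibration_fraction, cfg.decision.calibration_seed
    )
    ds = augment_embeddings(
        ds,
        cfg.synthetic.augment_target_per_class,
        cfg.synthetic.augment_jitter_sd,
        cfg.synthetic.seed + 1,
    )
    return ds


def _metrics_dict(m: decision_mod.ConfusionMetrics) -> dict:
    return dataclasses.asdict(m)


def write_predictives_csv(preds, path: str | Path) -> None:
    """Long-format predictive samples: case_id, sample_index, p_acp, p_notacp."""
    n_s = preds[0].samples.shape[0]
    frame = pd.DataFrame(
        {
            "case_id": np.repeat([p.case_id for p in preds], n_s),
            "sample_index": np.tile(np.arange(n_s), len(preds)),
            "p_acp": np.concatenate([p.samples[:, 0] for p in preds]),
            "p_notacp": np.concatenate([p.samples[:, 1] for p in preds]),
        }
    )
    frame.to_csv(path, index=False)


def read_predictives_csv(path: str | Path):
    """Inverse of :func:`write_predictives_csv`."""
    from .ess import PredictiveDistribution

    frame = pd.read_csv(path)
    preds = []
    for cid, grp in frame.groupby("case_id", sort=False):
        grp = grp.sort_values("sample_index")
        preds.append(
            PredictiveDistribution(
                case_id=str(cid), samples=grp[["p_acp", "p_notacp"]].to_numpy()
            )
        )
    return preds


def run_all(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write all artifacts plus a manifest.

    Returns a results bundle with the decision records and all metrics;
    rerunning with an identical config reproduces identical outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ds = prepare_dataset(cfg)
    ds.write_csv(out / "data.csv", cfg.synthetic)

    bundle = fit_stages(ds, cfg)
    bundle.head_a.to_json(out / "head_a.json")
    bundle.head_b.to_json(out / "head_b.json")
    pd.DataFrame(np.vstack(bundle.snapshots_a)).to_csv(out / "snapshots_a.csv", index=False)
    pd.DataFrame(np.vstack(bundle.snapshots_b)).to_csv(out / "snapshots_b.csv", index=False)
    bundle.basis.to_json(out / "subspace.json")
    bundle.curve.to_json(out / "curve.json")

    test = ds.select(TEST)
    preds = predictive_distributions(
        bundle.coord_samples, bundle.basis, bundle.curve, ds, split=TEST,
        prior_sd=cfg.ess.prior_sd, space=cfg.ess.space,
    )
    write_predictives_csv(preds, out / "preds.csv")

    truths = dict(zip(test.case_ids.astype(str), test.labels.astype(str)))
    records = decide_cases(preds, bundle.ref_acp, bundle.ref_notacp)
    dec_frame = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "argmax_call": r.argmax_call,
                "ks_call": r.ks_call,
                "p_acp": r.p_acp,
                "p_notacp": r.p_notacp,
                "ratio": r.ks_ratio,
                "final_call": r.final_call,
                "truth": truths[r.case_id],
            }
            for r in records
        ]
    )
    dec_frame.to_csv(out / "decisions.csv", index=False)

    argmax_records = [
        dataclasses.replace(r, final_call=r.argmax_call) for r in records
    ]
    ks_records = [dataclasses.replace(r, final_call=r.ks_call) for r in records]
    metrics = {
        "argmax": _metrics_dict(confusion_metrics(argmax_records, truths)),
        "ks_ratio": _metrics_dict(confusion_metrics(ks_records, truths)),
        "final": _metrics_dict(confusion_metrics(records, truths)),
        "head_a_test": evaluate(bundle.head_a, ds, TEST),
        "head_b_test": evaluate(bundle.head_b, ds, TEST),
        "mean_difference_filter": {
            str(alpha): (_metrics_dict(entry["metrics"]) if entry["metrics"] else None)
            for alpha, entry in mean_difference_filter(
                preds, truths, cfg.decision.filter_alphas
            ).items()
        },
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config_hash": cfg.config_hash(),
        "seeds": {"a": cfg.seed_a, "b": cfg.seed_b, "ess": cfg.ess.seed,
                  "synthetic": cfg.synthetic.seed},
        "artifacts": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(out.iterdir())
            if f.name not in {"manifest.json"}
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "dataset": ds,
        "bundle": bundle,
        "predictives": preds,
        "records": records,
        "metrics": metrics,
        "out_dir": out,
    }


def scaled_config(seed: int, dim: int = 16, n_ess: int = 500) -> PipelineConfig:
    """Desk-scale study profile: dim-16 embeddings, ~50 patients, 500 ESS draws."""
    return PipelineConfig(
        synthetic=SyntheticConfig(
            dim=dim,
            n_train_pos=12,
            n_train_neg=15,
            n_test_pos=10,
            n_test_neg=11,
            n_neg_subclusters=5,
            augment_target_per_class=120,
            seed=seed,
        ),
        train=TrainConfig(epochs=50),
        seed_a=6567 + seed,
        seed_b=7656 + seed,
        ess=ESSConfig(n_samples=n_ess, burn_in=200, seed=seed),
        curve=CurveSettings(seed=seed),
        decision=DecisionSettings(calibration_seed=seed),
    )


def run_replicate(seed: int, dim: int = 16, n_ess: int = 500) -> dict:
    """One in-memory end-to-end replicate of the scaled-down study.

    Returns the decision metrics of all three prediction modes plus two
    uncertainty probes: the predictive standard deviation of a synthetic
    case at the midpoint between the estimated class centroids (a
    boundary-region case) and of a case pushed well inside the positive
    class (a well-separated case).
    """
    cfg = scaled_config(seed, dim=dim, n_ess=n_ess)
    ds = prepare_dataset(cfg)
    bundle = fit_stages(ds, cfg)

    test = ds.select(TEST)
    preds = predictive_distributions(
        bundle.coord_samples, bundle.basis, bundle.curve, ds, split=TEST,
        prior_sd=cfg.ess.prior_sd, space=cfg.ess.space,
    )
    truths = dict(zip(test.case_ids.astype(str), test.labels.astype(str)))
    records = decide_cases(preds, bundle.ref_acp, bundle.ref_notacp)
    argmax_records = [dataclasses.replace(r, final_call=r.argmax_call) for r in records]
    m_argmax = confusion_metrics(argmax_records, truths)
    m_final = confusion_metrics(records, truths)

    # uncertainty probes at the estimated class midpoint vs deep inside ACP
    train = ds.select(TRAIN)
    mu_acp = train.features[train.labels == ACP].mean(axis=0)
    mu_not = train.features[train.labels == NOTACP].mean(axis=0)
    mid = 0.5 * (mu_acp + mu_not)
    far = mu_acp + (mu_acp - mid)
    probe_ds = EmbeddingDataset(
        np.vstack([mid, far]),
        np.array([ACP, ACP], dtype=object),
        np.array(["probe-mid", "probe-far"], dtype=object),
        np.array([TEST, TEST], dtype=object),
        np.array([-1, -1], dtype=np.int64),
    )
    probe = predictive_distributions(
        bundle.coord_samples, bundle.basis, bundle.curve, probe_ds, split=TEST,
        prior_sd=cfg.ess.prior_sd, space=cfg.ess.space,
    )

    head_metrics = evaluate(bundle.head_a, ds, TEST)
    return {
        "endpoints_frozen": bool(
            np.array_equal(bundle.curve.w1, bundle.w1_init)
            and np.array_equal(bundle.curve.w2, bundle.w2_init)
        ),
        "argmax_accuracy": m_argmax.accuracy,
        "selective_accuracy": m_final.accuracy,
        "abstention_rate": m_final.abstention_rate,
        "all_branches_agree": all(r.argmax_call == r.ks_call for r in records),
        "boundary_sd": float(np.sqrt(probe[0].class_variances[0])),
        "separated_sd": float(np.sqrt(probe[1].class_variances[0])),
        "head_test_accuracy": head_metrics["accuracy"],
        "head_test_aupr": head_metrics["aupr"],
        "n_test": test.n_images,
    }


class SubspaceAbstainClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for the full uncertainty-aware pipeline.

    ``fit(X, y, groups=...)`` takes embeddings, labels (strings ``"ACP"`` /
    ``"NOTACP"`` or ints 0/1 with 0 positive) and optional patient
    identifiers (``groups``); calibration reference patients are carved at
    patient level and held out of model fitting. ``predict`` returns
    ``"ACP"``, ``"NOTACP"`` or ``"ABSTAIN"``; ``predict_proba`` returns the
    mean posterior predictive probabilities.
    """

    def __init__(
        self,
        epochs: int = 50,
        base_lr: float = 1e-3,
        max_lr: float = 1e-2,
        weight_decay: float = 1e-4,
        dropout_rate: float = 0.5,
        batch_size: int = 2,
        seed_a: int = 6567,
        seed_b: int = 7656,
        subspace_rank: int = 5,
        collect_every: int = 10,
        curve_epochs: int = 30,
        curve_lr: float = 0.05,
        n_samples: int = 5000,
        burn_in: int = 500,
        prior_sd: float = 1.0,
        temperature: float = 1.0,
        calibration_fraction: float = 0.2,
        augment_target_per_class: Optional[int] = None,
        augment_jitter_sd: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.epochs = epochs
        self.base_lr = base_lr
        self.max_lr = max_lr
        self.weight_decay = weight_decay
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.seed_a = seed_a
        self.seed_b = seed_b
        self.subspace_rank = subspace_rank
        self.collect_every = collect_every
        self.curve_epochs = curve_epochs
        self.curve_lr = curve_lr
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.prior_sd = prior_sd
        self.temperature = temperature
        self.calibration_fraction = calibration_fraction
        self.augment_target_per_class = augment_target_per_class
        self.augment_jitter_sd = augment_jitter_sd
        self.random_state = random_state

    def _pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            train=TrainConfig(
                epochs=self.epochs,
                base_lr=self.base_lr,
                max_lr=self.max_lr,
                weight_decay=self.weight_decay,
                dropout_rate=self.dropout_rate,
                batch_size=self.batch_size,
            ),
            seed_a=self.seed_a,
            seed_b=self.seed_b,
            subspace=SubspaceSettings(rank=self.subspace_rank, collect_every=self.collect_every),
            curve=CurveSettings(epochs=self.curve_epochs, lr=self.curve_lr,
                                seed=self.random_state),
            ess=ESSConfig(
                n_samples=self.n_samples,
                burn_in=self.burn_in,
                prior_sd=self.prior_sd,
                temperature=self.temperature,
                seed=self.random_state,
            ),
            decision=DecisionSettings(
                calibration_fraction=self.calibration_fraction,
                calibration_seed=self.random_state,
            ),
        )

    @staticmethod
    def _as_labels(y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            return y.astype(object)
        return np.where(y.astype(int) == 0, ACP, NOTACP).astype(object)

    def fit(self, X: np.ndarray, y: np.ndarray, groups: Optional[Sequence] = None):
        X = check_array(X, dtype=np.float64)
        labels = self._as_labels(y)
        if X.shape[0] != labels.shape[0]:
            raise ValueError("X and y have mismatched lengths")
        if groups is None:
            groups = [f"case{i:05d}" for i in range(X.shape[0])]
        ds = EmbeddingDataset(
            X,
            labels,
            np.asarray([str(g) for g in groups], dtype=object),
            np.full(X.shape[0], TRAIN, dtype=object),
            np.full(X.shape[0], -1, dtype=np.int64),
        )
        cfg = self._pipeline_config()
        ds = hold_out_calibration_patients(
            ds, cfg.decision.calibration_fraction, cfg.decision.calibration_seed
        )
        if self.augment_target_per_class is not None:
            ds = augment_embeddings(
                ds, self.augment_target_per_class, self.augment_jitter_sd,
                self.random_state + 1,
            )
        self.bundle_ = fit_stages(ds, cfg)
        self.classes_ = np.array([ACP, NOTACP], dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _predictives(self, X: np.ndarray, case_ids: Optional[Sequence] = None):
        check_is_fitted(self, "bundle_")
        X = check_array(X, dtype=np.float64)
        if case_ids is None:
            case_ids = [f"q{i:05d}" for i in range(X.shape[0])]
        ds = EmbeddingDataset(
            X,
            np.full(X.shape[0], NOTACP, dtype=object),  # placeholder labels
            np.asarray([str(c) for c in case_ids], dtype=object),
            np.full(X.shape[0], TEST, dtype=object),
            np.full(X.shape[0], -1, dtype=np.int64),
        )
        cfg = self.bundle_.config
        return predictive_distributions(
            self.bundle_.coord_samples, self.bundle_.basis, self.bundle_.curve, ds,
            split=TEST, prior_sd=cfg.ess.prior_sd, space=cfg.ess.space,
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        preds = self._predictives(X)
        return np.vstack([p.class_means for p in preds])

    def decision_records(self, X: np.ndarray, case_ids: Optional[Sequence] = None):
        """Full two-branch decision records (including ABSTAIN) per row."""
        preds = self._predictives(X, case_ids)
        return decide_cases(preds, self.bundle_.ref_acp, self.bundle_.ref_notacp)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(
            [r.final_call for r in self.decision_records(X)], dtype=object
        )

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Selective accuracy: fraction correct among non-abstained cases."""
        labels = self._as_labels(y)
        calls = self.predict(X)
        kept = calls != decision_mod.ABSTAIN
        if not np.any(kept):
            raise ValueError("all cases abstained; selective accuracy undefined")
        return float(np.mean(calls[kept] == labels[kept]))
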