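"""Bayesian subspace inference and selective abstention for embedding classifiers.

The package implements an uncertainty-aware binary classifier for fixed
image-feature embeddings (e.g. 2048-d pretrained-CNN features of brain MRI):
a batch-norm / dropout / dense-softmax head trained with an AdamW-style
optimizer and a cyclic learning rate, calibrated by subspace inference
(stochastic weight averaging, a PCA subspace of the optimizer trajectory,
a quadratic Bezier curve connecting two solutions, and elliptical slice
sampling), feeding a two-branch decision rule that abstains when an ArgMax
call and a Kolmogorov-Smirnov p-value-ratio call disagree.

The positive class is ACP (adamantinomatous craniopharyngioma); the negative
class NOTACP pools all other suprasellar tumour diagnoses.
"""

from .datasets import (
    ACP,
    NOTACP,
    EmbeddingDataset,
    SyntheticConfig,
    augment_embeddings,
    generate_embeddings,
    hold_out_calibration_patients,
)
from .head import HeadParameters, SoftmaxHead, TrainConfig, aupr, cross_entropy, cyclic_lr, forward
from .swa import SubspaceBasis, SWATrajectory, collect, pca_subspace, project, swa_update, to_full
from .curve import BezierCurve, curve_weight_spread, evaluate_curve, fit_curve
from .ess import (
    CurveSubspace,
    ESSConfig,
    PredictiveDistribution,
    ess_step,
    predictive_distributions,
    sample_posterior,
)
from .decision import (
    ABSTAIN,
    ConfusionMetrics,
    DecisionRecord,
    abstain_predict,
    argmax_predict,
    confusion_metrics,
    ks_pvalue,
    ks_ratio_predict,
    ks_statistic,
    mean_difference_filter,
)
from .pipeline import PipelineConfig, SubspaceAbstainClassifier, run_all, validate_config

__version__ = "0.1.0"

__all__ = [
    "ACP",
    "NOTACP",
    "ABSTAIN",
    "EmbeddingDataset",
    "SyntheticConfig",
    "generate_embeddings",
    "augment_embeddings",
    "hold_out_calibration_patients",
    "HeadParameters",
    "TrainConfig",
    "SoftmaxHead",
    "forward",
    "cross_entropy",
    "cyclic_lr",
    "aupr",
    "SWATrajectory",
    "SubspaceBasis",
    "swa_update",
    "collect",
    "pca_subspace",
    "to_full",
    "project",
    "BezierCurve",
    "evaluate_curve",
    "fit_curve",
    "curve_weight_spread",
    "ESSConfig",
    "CurveSubspace",
    "PredictiveDistribution",
    "ess_step",
    "sample_posterior",
    "predictive_distributions",
    "DecisionRecord",
    "ConfusionMetrics",
    "ks_statistic",
    "ks_pvalue",
    "argmax_predict",
    "ks_ratio_predict",
    "abstain_predict",
    "mean_difference_filter",
    "confusion_metrics",
    "PipelineConfig",
    "SubspaceAbstainClassifier",
    "run_all",
    "validate_config",
]
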