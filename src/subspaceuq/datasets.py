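"""Synthetic embedding cohorts with the structure of the MRI study.

The real cohort (suprasellar-tumour MRI embeddings) is private, so this
module generates datasets with its statistical skeleton: a homogeneous
positive class (ACP, one diagnosis) versus a heterogeneous negative class
(NOTACP, a mixture of many diagnosis subclusters), a patient hierarchy
(several images per training patient, exactly one per test patient), and
jitter-based augmentation of the training split to a balanced 500/500 set.

Generative model, per image::

    class centroid -> subcluster mean (negative class only)
                   -> patient mean   (+ between_patient_sd noise)
                   -> image          (+ within_patient_sd noise)

The two class centroids sit ``separation`` apart along a random direction.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

ACP = "ACP"
NOTACP = "NOTACP"

#: split tags; "calib" marks reference patients held out of model fitting
TRAIN, CALIB, TEST = "train", "calib", "test"


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Counts default to the study cohort: 23 ACP / 30 NOTACP training
    patients with three images each, 16 ACP / 17 NOTACP test patients
    with one image each, and 13 negative-class diagnosis subclusters.
    """

    dim: int = Field(default=2048, ge=1)
    n_train_pos: int = Field(default=23, ge=1)
    n_train_neg: int = Field(default=30, ge=1)
    images_per_train_patient: int = Field(default=3, ge=1)
    n_test_pos: int = Field(default=16, ge=1)
    n_test_neg: int = Field(default=17, ge=1)
    n_neg_subclusters: int = Field(default=13, ge=1)
    separation: float = Field(default=3.0, ge=0.0)
    within_patient_sd: float = Field(default=1.0, gt=0.0)
    between_patient_sd: float = Field(default=1.0, gt=0.0)
    subcluster_sd: float = Field(default=1.5, gt=0.0)
    augment_target_per_class: int = Field(default=500, ge=1)
    augment_jitter_sd: float = Field(default=0.1, ge=0.0)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_subclusters(self) -> "SyntheticConfig":
        if self.n_neg_subclusters > self.n_train_neg + self.n_test_neg:
            raise ValueError(
                "n_neg_subclusters must not exceed the total number of "
                f"negative patients ({self.n_train_neg + self.n_test_neg})"
            )
        return self


@dataclasses.dataclass
class EmbeddingDataset:
    """Per-image embedding vectors with patient and split metadata.

    ``subcluster`` is the negative-class diagnosis subcluster index, and
    -1 for positive-class images (the positive class is one diagnosis).
    """

    features: np.ndarray  # (n_images, dim) float64
    labels: np.ndarray  # (n_images,) str in {ACP, NOTACP}
    case_ids: np.ndarray  # (n_images,) str patient identifiers
    split: np.ndarray  # (n_images,) str in {train, calib, test}
    subcluster: np.ndarray  # (n_images,) int, -1 where absent

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.case_ids = np.asarray(self.case_ids, dtype=object)
        self.split = np.asarray(self.split, dtype=object)
        self.subcluster = np.asarray(self.subcluster, dtype=np.int64)
        n = self.features.shape[0]
        for name in ("labels", "case_ids", "split", "subcluster"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match features ({n} rows)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    # -- selection ---------------------------------------------------------

    @property
    def n_images(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def subset(self, mask: np.ndarray) -> "EmbeddingDataset":
        return EmbeddingDataset(
            self.features[mask],
            self.labels[mask],
            self.case_ids[mask],
            self.split[mask],
            self.subcluster[mask],
        )

    def split_mask(self, tag: str) -> np.ndarray:
        return self.split == tag

    def select(self, tag: str) -> "EmbeddingDataset":
        return self.subset(self.split_mask(tag))

    def y(self) -> np.ndarray:
        """Integer labels: 0 = ACP (positive), 1 = NOTACP."""
        return np.where(self.labels == ACP, 0, 1)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "case_id": self.case_ids,
            "label": self.labels,
            "split": self.split,
            "subcluster": self.subcluster,
        }
        frame = pd.DataFrame(cols)
        feat = pd.DataFrame(
            self.features, columns=[f"f_{j}" for j in range(self.dim)], index=frame.index
        )
        return pd.concat([frame, feat], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EmbeddingDataset":
        feat_cols = [c for c in frame.columns if c.startswith("f_")]
        return cls(
            frame[feat_cols].to_numpy(dtype=np.float64),
            frame["label"].astype(str).to_numpy(dtype=object),
            frame["case_id"].astype(str).to_numpy(dtype=object),
            frame["split"].astype(str).to_numpy(dtype=object),
            frame["subcluster"].to_numpy(dtype=np.int64),
        )

    def write_csv(self, path: str | Path, config: Optional[SyntheticConfig] = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if config is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(config.model_dump(), indent=2) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "EmbeddingDataset":
        return cls.from_frame(pd.read_csv(path))


def _validate_patient_splits(ds: EmbeddingDataset) -> None:
    """Patient-level split hygiene: no patient in two splits; one image per test patient."""
    by_patient: dict[str, set[str]] = {}
    for cid, sp in zip(ds.case_ids, ds.split):
        by_patient.setdefault(cid, set()).add(sp)
    offenders = [cid for cid, tags in by_patient.items() if len(tags) > 1]
    if offenders:
        raise ValueError(f"patients appear in multiple splits: {offenders[:5]}")
    test = ds.select(TEST)
    ids, counts = np.unique(test.case_ids.astype(str), return_counts=True)
    if np.any(counts != 1):
        raise ValueError("every test patient must contribute exactly one image")


def generate_embeddings(config: SyntheticConfig) -> EmbeddingDataset:
    """Draw a synthetic embedding cohort from the hierarchical Gaussian model.

    Deterministic given ``config.seed``. With the default counts the result
    has 53 training patients x 3 images = 159 training rows and 33 test rows.
    """
    rng = np.random.default_rng(config.seed)
    d = config.dim

    direction = rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    mu_pos = 0.5 * config.separation * direction
    mu_neg = -0.5 * config.separation * direction

    sub_means = mu_neg + config.subcluster_sd * rng.standard_normal(
        (config.n_neg_subclusters, d)
    )

    # cyclic assignment over a shuffled negative-patient order uses every subcluster
    n_neg = config.n_train_neg + config.n_test_neg
    order = rng.permutation(n_neg)
    neg_sub = np.empty(n_neg, dtype=np.int64)
    neg_sub[order] = np.arange(n_neg) % config.n_neg_subclusters

    rows_f, rows_lab, rows_cid, rows_split, rows_sub = [], [], [], [], []

    def add_patient(cid: str, label: str, mean: np.ndarray, n_img: int, split: str, sub: int) -> None:
        pmean = mean + config.between_patient_sd * rng.standard_normal(d)
        imgs = pmean + config.within_patient_sd * rng.standard_normal((n_img, d))
        rows_f.append(imgs)
        rows_lab.extend([label] * n_img)
        rows_cid.extend([cid] * n_img)
        rows_split.extend([split] * n_img)
        rows_sub.extend([sub] * n_img)

    k = config.images_per_train_patient
    for i in range(config.n_train_pos):
        add_patient(f"ACP-TR{i:03d}", ACP, mu_pos, k, TRAIN, -1)
    for i in range(config.n_train_neg):
        sub = int(neg_sub[i])
        add_patient(f"NOT-TR{i:03d}", NOTACP, sub_means[sub], k, TRAIN, sub)
    for i in range(config.n_test_pos):
        add_patient(f"ACP-TE{i:03d}", ACP, mu_pos, 1, TEST, -1)
    for i in range(config.n_test_neg):
        sub = int(neg_sub[config.n_train_neg + i])
        add_patient(f"NOT-TE{i:03d}", NOTACP, sub_means[sub], 1, TEST, sub)

    ds = EmbeddingDataset(
        np.vstack(rows_f),
        np.array(rows_lab, dtype=object),
        np.array(rows_cid, dtype=object),
        np.array(rows_split, dtype=object),
        np.array(rows_sub, dtype=np.int64),
    )
    _validate_patient_splits(ds)
    return ds


def augment_embeddings(
    dataset: EmbeddingDataset,
    target_per_class: int,
    jitter_sd: float,
    seed: int,
) -> EmbeddingDataset:
    """Expand the training split to ``target_per_class`` rows per class.

    Extra rows are resampled (with replacement) training rows plus additive
    Gaussian jitter; they keep their source patient's ``case_id``. Splits
    other than ``train`` pass through untouched. No downsampling: a target
    below an existing per-class count is an error.
    """
    rng = np.random.default_rng(seed)
    train_mask = dataset.split_mask(TRAIN)
    keep = dataset.subset(~train_mask)
    train = dataset.subset(train_mask)

    parts = [keep, train]
    for label in (ACP, NOTACP):
        cls_idx = np.flatnonzero(train.labels == label)
        if cls_idx.size == 0:
            raise ValueError(f"training split has no {label} rows to augment")
        n_extra = target_per_class - cls_idx.size
        if n_extra < 0:
            raise ValueError(
                f"target_per_class={target_per_class} is below the existing "
                f"{label} training count ({cls_idx.size}); downsampling is not supported"
            )
        if n_extra == 0:
            continue
        src = rng.choice(cls_idx, size=n_extra, replace=True)
        feats = train.features[src] + jitter_sd * rng.standard_normal(
            (n_extra, train.dim)
        )
        parts.append(
            EmbeddingDataset(
                feats,
                train.labels[src],
                train.case_ids[src],
                np.full(n_extra, TRAIN, dtype=object),
                train.subcluster[src],
            )
        )
    return _concat(parts)


def hold_out_calibration_patients(
    dataset: EmbeddingDataset, fraction: float, seed: int
) -> EmbeddingDataset:
    """Re-tag a fraction of training patients per class as ``calib``.

    Calibration patients supply the reference predictive distributions for
    the KS-ratio decision branch; they are excluded from model fitting so
    the references reflect out-of-sample predictive spread. At least one
    patient per class is carved whenever fraction > 0.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("calibration fraction must be in [0, 1)")
    if fraction == 0.0:
        return dataset
    rng = np.random.default_rng(seed)
    split = dataset.split.copy()
    for label in (ACP, NOTACP):
        mask = (dataset.split == TRAIN) & (dataset.labels == label)
        patients = np.unique(dataset.case_ids[mask].astype(str))
        n_cal = max(1, int(round(fraction * patients.size)))
        if n_cal >= patients.size:
            raise ValueError(
                f"calibration fraction {fraction} would consume all {label} training patients"
            )
        chosen = rng.choice(patients, size=n_cal, replace=False)
        split[np.isin(dataset.case_ids.astype(str), chosen)] = CALIB
    return EmbeddingDataset(
        dataset.features, dataset.labels, dataset.case_ids, split, dataset.subcluster
    )


def _concat(parts: list[EmbeddingDataset]) -> EmbeddingDataset:
    return EmbeddingDataset(
        np.vstack([p.features for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.case_ids for p in parts]),
        np.concatenate([p.split for p in parts]),
        np.concatenate([p.subcluster for p in parts]),
    )
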