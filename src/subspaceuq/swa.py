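"""Stochastic weight averaging and the PCA subspace of the optimizer trajectory.

Every ``collect_every`` epochs the flattened head parameters are folded into
a running average (the SWA solution) and the deviation of the current
snapshot from that average is recorded. The top principal directions of the
deviation matrix span a low-dimensional subspace of parameter space in which
the calibration curve lives.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


@dataclasses.dataclass
class SWATrajectory:
    """Running SWA state: the mean so far and the recorded deviation rows."""

    running_mean: np.ndarray
    n_collected: int = 0
    deviation_rows: list[np.ndarray] = dataclasses.field(default_factory=list)
    collect_every: int = 10

    @classmethod
    def empty(cls, n_params: int, collect_every: int = 10) -> "SWATrajectory":
        return cls(np.zeros(n_params), 0, [], collect_every)

    def deviation_matrix(self) -> np.ndarray:
        if not self.deviation_rows:
            raise ValueError("no deviation rows collected")
        return np.vstack(self.deviation_rows)


def swa_update(mean: np.ndarray, new_snapshot: np.ndarray, n_prev: int) -> np.ndarray:
    """Fold one snapshot into the running average: (n*mean + snap) / (n+1)."""
    mean = np.asarray(mean, dtype=np.float64)
    new_snapshot = np.asarray(new_snapshot, dtype=np.float64)
    if mean.shape != new_snapshot.shape:
        raise ValueError("mean and snapshot have mismatched lengths")
    if n_prev < 0:
        raise ValueError("n_prev must be non-negative")
    return (n_prev * mean + new_snapshot) / (n_prev + 1)


def collect(trajectory: SWATrajectory, snapshot: np.ndarray, epoch: int) -> SWATrajectory:
    """Collect a snapshot at the end of ``epoch`` (1-based).

    On multiples of ``collect_every`` the running mean is updated and the
    deviation of the snapshot from the updated mean is appended; other
    epochs leave the trajectory unchanged.
    """
    if epoch < 1:
        raise ValueError("epoch must be >= 1")
    if epoch % trajectory.collect_every != 0:
        return trajectory
    new_mean = swa_update(trajectory.running_mean, snapshot, trajectory.n_collected)
    return SWATrajectory(
        running_mean=new_mean,
        n_collected=trajectory.n_collected + 1,
        deviation_rows=trajectory.deviation_rows + [np.asarray(snapshot) - new_mean],
        collect_every=trajectory.collect_every,
    )


def collect_from_snapshots(
    snapshots: list[np.ndarray], collect_every: int = 10
) -> SWATrajectory:
    """Run :func:`collect` over a full per-epoch snapshot list."""
    if not snapshots:
        raise ValueError("snapshot list is empty")
    traj = SWATrajectory.empty(len(snapshots[0]), collect_every)
    for epoch, snap in enumerate(snapshots, start=1):
        traj = collect(traj, snap, epoch)
    return traj


@dataclasses.dataclass
class SubspaceBasis:
    """Orthonormal basis of the trajectory subspace, anchored at the SWA mean."""

    mean: np.ndarray
    basis: np.ndarray  # (rank, n_params), rows orthonormal
    singular_values: np.ndarray  # (rank,), non-increasing

    def __post_init__(self) -> None:
        if self.basis.ndim != 2 or self.basis.shape[1] != self.mean.shape[0]:
            raise ValueError("basis shape inconsistent with mean")
        gram = self.basis @ self.basis.T
        if not np.allclose(gram, np.eye(self.rank), atol=1e-8):
            raise ValueError("basis rows are not orthonormal")

    @property
    def rank(self) -> int:
        return self.basis.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "basis": self.basis.tolist(),
                    "singular_values": self.singular_values.tolist(),
                }
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SubspaceBasis":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["mean"], dtype=np.float64),
            np.asarray(payload["basis"], dtype=np.float64),
            np.asarray(payload["singular_values"], dtype=np.float64),
        )


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: largest-|.| entry of each row positive."""
    out = basis.copy()
    for i, row in enumerate(out):
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            out[i] = -row
    return out


def pca_subspace(
    trajectory: SWATrajectory,
    rank: int,
    mean: np.ndarray | None = None,
    extra_rows: np.ndarray | None = None,
    scale_by_singular_values: bool = False,
) -> SubspaceBasis:
    """Top principal directions of the deviation matrix.

    ``mean`` overrides the anchor point (default: the trajectory's final
    running mean); ``extra_rows`` appends additional deviation rows before
    the decomposition (used to pool two training runs and guarantee the
    direction between their SWA solutions is representable).

    With ``scale_by_singular_values`` the stored singular values are meant
    to rescale subspace coordinates downstream; the basis rows themselves
    stay orthonormal either way.
    """
    dev = trajectory.deviation_matrix()
    if extra_rows is not None:
        dev = np.vstack([dev, np.atleast_2d(extra_rows)])
    if rank < 1 or rank > min(dev.shape):
        raise ValueError(
            f"rank must be in [1, {min(dev.shape)}] for a {dev.shape} deviation matrix"
        )
    if not np.any(dev):
        raise ValueError("all deviation rows are zero: degenerate subspace")
    _, s, vt = np.linalg.svd(dev, full_matrices=False)
    basis = _fix_signs(vt[:rank])
    anchor = np.asarray(mean if mean is not None else trajectory.running_mean, dtype=np.float64)
    sv = s[:rank].copy()
    if scale_by_singular_values:
        # normalized so coordinates stay O(1): s_k / sqrt(n_rows - 1)
        sv = sv / np.sqrt(max(dev.shape[0] - 1, 1))
    return SubspaceBasis(mean=anchor, basis=basis, singular_values=sv)


def to_full(basis: SubspaceBasis, z: np.ndarray) -> np.ndarray:
    """Map subspace coordinates back to a flattened parameter vector."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (basis.rank,):
        raise ValueError(f"expected coordinates of length {basis.rank}, got {z.shape}")
    return basis.mean + z @ basis.basis


def project(basis: SubspaceBasis, w: np.ndarray) -> np.ndarray:
    """Subspace coordinates of a full parameter vector: basis @ (w - mean)."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != basis.mean.shape:
        raise ValueError("parameter vector length mismatch")
    return basis.basis @ (w - basis.mean)
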