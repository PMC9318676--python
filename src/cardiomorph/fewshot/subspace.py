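"""Adaptive subspace classifier: class subspaces from support features,
residual-distance scoring, the Grassmannian projection-metric regularizer,
and the episodic loss.

Two routes exist by design. The numpy functions here are the inference-time
contract (orthonormal bases via SVD, residual distances without ever
materializing a D×D projection matrix). The training path in
:mod:`cardiomorph.fewshot.training` computes the same quantities through the
autodiff engine via Gram-matrix solves; agreement between the two routes is
asserted in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassSubspace",
    "build_class_subspace",
    "subspace_distance",
    "class_probabilities",
    "subspace_overlap",
    "projection_metric_sq",
    "episode_loss",
]


@dataclass
class ClassSubspace:
    """Support-mean offset plus an orthonormal basis of the centred span."""

    class_id: int
    mean: np.ndarray  # (D,)
    basis: np.ndarray  # (D, r), orthonormal columns; r may be 0 (degenerate)

    @property
    def rank(self) -> int:
        return self.basis.shape[1]


def build_class_subspace(features: np.ndarray, rank: int,
                         class_id: int = -1) -> ClassSubspace:
    """Mean and leading left-singular subspace of the centred support features.

    ``features`` is (k_shot, D) with k_shot ≥ 2 and rank ≤ k_shot − 1. If the
    requested rank exceeds the numerical rank of the centred matrix, the basis
    is truncated (never padded) with a warning.
    """
    features = np.asarray(features, dtype=float)
    k, d = features.shape
    if k < 2:
        raise ValueError("need at least two support features")
    if not (1 <= rank <= k - 1):
        raise ValueError(f"rank must be in [1, {k - 1}]")
    mean = features.mean(axis=0)
    centered = (features - mean).T  # (D, k)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    numerical_rank = int((s > tol).sum())
    if numerical_rank < rank:
        warnings.warn(
            f"support features span only {numerical_rank} dimensions; "
            f"truncating requested rank {rank}",
            stacklevel=2,
        )
        rank = numerical_rank
    return ClassSubspace(class_id, mean, u[:, :rank])


def subspace_distance(query_feature: np.ndarray, subspace: ClassSubspace) -> float:
    """−‖residual‖² of the query offset after projection onto the subspace.

    Computed as v − P(Pᵀv), never forming PPᵀ; with an empty basis this
    reduces to −‖query − mean‖².
    """
    v = np.asarray(query_feature, dtype=float) - subspace.mean
    if v.shape != subspace.mean.shape:
        raise ValueError("feature dimension mismatch")
    if subspace.rank:
        v = v - subspace.basis @ (subspace.basis.T @ v)
    return -float(v @ v)


def class_probabilities(distances: np.ndarray) -> np.ndarray:
    """Softmax over per-class distances (shift-invariant, stable)."""
    d = np.asarray(distances, dtype=float)
    e = np.exp(d - d.max())
    return e / e.sum()


def subspace_overlap(a: ClassSubspace, b: ClassSubspace) -> float:
    """‖PᵢᵀPⱼ‖²_F — the overlap term minimized by the regularizer."""
    if a.rank != b.rank:
        raise ValueError("subspace ranks differ")
    return float(np.sum((a.basis.T @ b.basis) ** 2))


def projection_metric_sq(a: ClassSubspace, b: ClassSubspace) -> float:
    """Squared Grassmannian projection metric δ² = 2r − 2‖PᵢᵀPⱼ‖²_F."""
    return 2.0 * a.rank - 2.0 * subspace_overlap(a, b)


def episode_loss(probabilities: np.ndarray, true_labels: np.ndarray,
                 subspaces: list[ClassSubspace], lambda_reg: float) -> float:
    """Mean negative log-probability of the true class plus λ × the sum of
    pairwise subspace overlaps over ordered pairs i ≠ j (each unordered pair
    counts twice; the overlap is symmetric)."""
    probabilities = np.asarray(probabilities, dtype=float)
    true_labels = np.asarray(true_labels)
    ce = -np.mean(np.log(probabilities[np.arange(len(true_labels)), true_labels]))
    reg = 0.0
    for i, si in enumerate(subspaces):
        for j, sj in enumerate(subspaces):
            if i != j:
                reg += subspace_overlap(si, sj)
    return float(ce + lambda_reg * reg)
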