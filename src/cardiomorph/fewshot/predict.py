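"""Evaluation-time prediction: episodic classification, patient-level
majority voting, and run-level ensembling."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .encoder import Conv4Encoder
from .episodes import FewShotConfig, LabeledImage, group_by_class
from .subspace import (ClassSubspace, build_class_subspace, class_probabilities,
                       subspace_distance)

__all__ = [
    "encode_images",
    "classify_features",
    "predict_majority_vote",
    "ensemble_predict",
    "accuracy",
    "confusion_matrix",
]


def encode_images(encoder: Conv4Encoder, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Deterministic evaluation-mode features for a (B, H, W, 3) stack."""
    chunks = [encoder(images[i:i + batch_size], training=False).data
              for i in range(0, len(images), batch_size)]
    return np.concatenate(chunks, axis=0)


def classify_features(query_features: np.ndarray,
                      subspaces: list[ClassSubspace]) -> np.ndarray:
    """Class index per query: argmax of the softmaxed residual distances."""
    out = np.empty(len(query_features), dtype=int)
    for i, f in enumerate(query_features):
        d = np.array([subspace_distance(f, s) for s in subspaces])
        out[i] = int(np.argmax(class_probabilities(d)))
    return out


def _build_subspaces(features: np.ndarray, groups: dict[int, list[int]],
                     rank: int) -> list[ClassSubspace]:
    return [build_class_subspace(features[groups[c]], rank, class_id=c)
            for c in sorted(groups)]


def predict_majority_vote(
    encoder: Conv4Encoder,
    support_items: list[LabeledImage],
    query_items: list[LabeledImage],
    config: FewShotConfig,
    n_episodes: int = 100,
    rng: np.random.Generator | int = 0,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Per-patient labels by majority vote over evaluation episodes.

    Each episode draws k_shot support items per class from the support pool
    and a random batch of n_way × m_query queries, classifies them against
    the episode's subspaces, and adds one vote per query to its patient.
    Patients never drawn (possible for small n_episodes) are classified once
    against subspaces built from the full support pool. Ties break toward
    the lowest class index.

    Returns the label map and a votes table (patient_id, predicted_class,
    one vote-count column per class).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    support_groups = group_by_class(support_items)
    classes = sorted(support_groups)
    if len(classes) != config.n_way:
        raise ValueError(
            f"support pool covers {len(classes)} classes, need {config.n_way}")
    for c in classes:
        if len(support_groups[c]) < config.k_shot:
            raise ValueError(
                f"class {c} has only {len(support_groups[c])} support items, "
                f"need {config.k_shot}")

    support_feats = encode_images(
        encoder, np.stack([s.pixels for s in support_items]).astype(np.float64))
    query_feats = encode_images(
        encoder, np.stack([q.pixels for q in query_items]).astype(np.float64))
    support_idx = {c: [i for i, s in enumerate(support_items) if s.label == c]
                   for c in classes}

    votes: dict[str, Counter] = {q.patient_id: Counter() for q in query_items}
    batch = min(config.n_way * config.m_query, len(query_items))
    for _ in range(n_episodes):
        groups = {c: list(rng.choice(support_idx[c], size=config.k_shot,
                                     replace=False))
                  for c in classes}
        subspaces = _build_subspaces(support_feats, groups,
                                     config.subspace_rank)
        chosen = rng.choice(len(query_items), size=batch, replace=False)
        preds = classify_features(query_feats[chosen], subspaces)
        for qi, pred in zip(chosen, preds):
            votes[query_items[qi].patient_id][int(pred)] += 1

    unseen = [pid for pid, v in votes.items() if not v]
    if unseen:
        subspaces = _build_subspaces(support_feats, support_idx,
                                     config.subspace_rank)
        for qi, item in enumerate(query_items):
            if item.patient_id in unseen:
                pred = classify_features(query_feats[qi:qi + 1], subspaces)[0]
                votes[item.patient_id][int(pred)] += 1

    labels: dict[str, int] = {}
    rows = []
    for pid in sorted(votes):
        counts = np.zeros(config.n_way, dtype=int)
        for cls, n in votes[pid].items():
            counts[cls] = n
        label = int(np.argmax(counts))  # argmax -> lowest index on ties
        labels[pid] = label
        rows.append({"patient_id": pid, "predicted_class": label,
                     **{f"votes_{c}": int(counts[c])
                        for c in range(config.n_way)}})
    return labels, pd.DataFrame(rows)


def ensemble_predict(per_run_labels: list[dict[str, int]]) -> dict[str, int]:
    """Modal label per patient across runs; ties go to the lowest class index."""
    if not per_run_labels:
        raise ValueError("need at least one run")
    patients = set(per_run_labels[0])
    for run in per_run_labels[1:]:
        if set(run) != patients:
            raise ValueError("runs cover different patient sets")
    out: dict[str, int] = {}
    for pid in sorted(patients):
        preds = [run[pid] for run in per_run_labels]
        n_classes = max(preds) + 1
        counts = np.bincount(preds, minlength=n_classes)
        out[pid] = int(np.argmax(counts))
    return out


def accuracy(truth: dict[str, int], predicted: dict[str, int]) -> float:
    if set(truth) != set(predicted):
        raise ValueError("patient sets differ")
    return float(np.mean([predicted[p] == truth[p] for p in truth]))


def confusion_matrix(truth: dict[str, int], predicted: dict[str, int],
                     class_names: list[str] | None = None) -> pd.DataFrame:
    """Rows = true class, columns = predicted class."""
    if set(truth) != set(predicted):
        raise ValueError("patient sets differ")
    n = max(max(truth.values()), max(predicted.values())) + 1
    names = class_names or [str(i) for i in range(n)]
    mat = np.zeros((len(names), len(names)), dtype=int)
    for pid in truth:
        mat[truth[pid], predicted[pid]] += 1
    return pd.DataFrame(mat, index=names, columns=names)
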