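"""Episode construction and image-level augmentation for episodic training."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FewShotConfig",
    "LabeledImage",
    "Episode",
    "group_by_class",
    "sample_episode",
    "coarse_dropout_augment",
    "downsample_image",
]


@dataclass(frozen=True)
class FewShotConfig:
    """Episodic-training hyperparameters (defaults follow the published
    protocol: 5-way, 5-shot, 5-query, 100 episodes/epoch, 10 epochs,
    Adam at 1e-3, λ = 0.03)."""

    n_way: int = 5
    k_shot: int = 5
    m_query: int = 5
    episodes_per_epoch: int = 100
    epochs: int = 10
    learning_rate: float = 1e-3
    lambda_reg: float = 0.03
    subspace_rank: int = 4
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.subspace_rank <= self.k_shot - 1):
            raise ValueError("subspace_rank must be in [1, k_shot - 1]")


@dataclass(frozen=True)
class LabeledImage:
    """One thickness image with its class label and owning patient."""

    pixels: np.ndarray
    label: int
    patient_id: str


@dataclass
class Episode:
    """Support tensor (n_way, k_shot, H, W, 3) plus a flat query batch."""

    support: np.ndarray
    query: np.ndarray  # (n_way * m_query, H, W, 3)
    query_labels: np.ndarray  # class indices into the episode's ways
    query_patients: list[str] = field(default_factory=list)


def group_by_class(items: list[LabeledImage]) -> dict[int, list[LabeledImage]]:
    groups: dict[int, list[LabeledImage]] = {}
    for item in items:
        groups.setdefault(item.label, []).append(item)
    return groups


def sample_episode(items: list[LabeledImage], config: FewShotConfig,
                   rng: np.random.Generator) -> Episode:
    """Draw one episode: per class a uniform random permutation assigns the
    first k_shot items to the support set and the next m_query to the query
    set (disjoint by construction)."""
    groups = group_by_class(items)
    classes = sorted(groups)
    if len(classes) < config.n_way:
        raise ValueError(
            f"need {config.n_way} classes, dataset has {len(classes)}")
    need = config.k_shot + config.m_query
    support, query, labels, patients = [], [], [], []
    for way, cls in enumerate(classes[: config.n_way]):
        pool = groups[cls]
        if len(pool) < need:
            raise ValueError(
                f"class {cls} has {len(pool)} items, episode needs {need}")
        perm = rng.permutation(len(pool))
        chosen = [pool[i] for i in perm[:need]]
        support.append(np.stack([c.pixels for c in chosen[: config.k_shot]]))
        for c in chosen[config.k_shot:]:
            query.append(c.pixels)
            labels.append(way)
            patients.append(c.patient_id)
    return Episode(
        support=np.stack(support),
        query=np.stack(query),
        query_labels=np.asarray(labels),
        query_patients=patients,
    )


def coarse_dropout_augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Zero out 4–8 randomly chosen pixel positions across all channels.

    Returns a copy; the input is untouched.
    """
    out = np.array(image, copy=True)
    h, w = out.shape[:2]
    count = int(rng.integers(4, 9))
    flat = rng.choice(h * w, size=count, replace=False)
    rows, cols = np.unravel_index(flat, (h, w))
    out[rows, cols] = 0
    return out


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample of an (H, W, C) image by an integer factor.

    Used to shrink thickness images for CPU-budget training runs.
    """
    if factor == 1:
        return image
    h, w, c = image.shape
    if h % factor or w % factor:
        raise ValueError("image sides must be divisible by the factor")
    blocks = image.reshape(h // factor, factor, w // factor, factor, c)
    return blocks.mean(axis=(1, 3)).astype(image.dtype)
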