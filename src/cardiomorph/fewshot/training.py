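"""Episodic training of the encoder with the subspace objective.

The training objective mirrors the numpy inference route but is built from
autodiff primitives so that gradients flow through the subspace construction:
the projection onto a class's centred support span is computed through the
(ridge-stabilized) Gram matrix, Pv = Aᵀ(AAᵀ + εI)⁻¹Av, which spans the same
subspace as the truncated SVD basis at the default rank k_shot − 1. The
pairwise regularizer ‖PᵢPᵢᵀ − PⱼPⱼᵀ‖-style overlap is likewise reduced to
k×k solves: tr(Gᵢ⁻¹ Cᵢⱼ Gⱼ⁻¹ Cᵢⱼᵀ) with Cᵢⱼ = AᵢAⱼᵀ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, cross_entropy_mean, solve
from .encoder import Conv4Encoder
from .episodes import (FewShotConfig, LabeledImage, coarse_dropout_augment,
                       sample_episode)
from .layers import Adam

__all__ = ["TrainResult", "episode_objective", "train"]

_RIDGE_REL = 1e-7  # relative Gram ridge; the centred Gram is rank-deficient


@dataclass
class TrainResult:
    encoder: Conv4Encoder
    history: list[dict]  # per-epoch: epoch, mean_loss, mean_query_accuracy


def _gram(a: Tensor) -> Tensor:
    g = a @ a.T
    k = g.shape[0]
    tr = float(np.trace(g.data))
    return g + Tensor(np.eye(k) * (_RIDGE_REL * tr / k + 1e-12))


def episode_objective(feats: Tensor, config: FewShotConfig
                      ) -> tuple[Tensor, np.ndarray]:
    """Loss tensor and raw query scores for one episode.

    ``feats`` rows are ordered class-major: n_way × k_shot support rows,
    then n_way × m_query query rows.
    """
    n, k, m = config.n_way, config.k_shot, config.m_query
    nk = n * k
    nm = n * m
    feats = feats.astype(np.float64)  # subspace head in double precision
    queries = feats.rows(np.arange(nk, nk + nm))  # (NM, D)

    centered, grams, dists = [], [], []
    for c in range(n):
        s = feats.rows(np.arange(c * k, (c + 1) * k))  # (k, D)
        mu = s.mean(axis=0, keepdims=True)
        a = s - mu
        g = _gram(a)
        v = queries - mu  # (NM, D)
        w = solve(g, a @ v.T)  # (k, NM)
        r = v.T - a.T @ w  # residual, (D, NM)
        dists.append((-(r * r).sum(axis=0)).reshape(nm, 1))
        centered.append(a)
        grams.append(g)

    scores = concat(dists, axis=1)  # (NM, n_way)
    labels = np.repeat(np.arange(n), m)
    loss = cross_entropy_mean(scores, labels)

    if config.lambda_reg:
        reg = None
        for i in range(n):
            for j in range(i + 1, n):
                cij = centered[i] @ centered[j].T
                wi = solve(grams[i], cij)
                wj = solve(grams[j], cij.T)
                term = (wi * wj.T).sum()
                reg = term if reg is None else reg + term
        # ordered pairs i != j: each unordered pair counts twice
        loss = loss + reg * (2.0 * config.lambda_reg)
    return loss, scores.data.copy()


def _augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.stack([coarse_dropout_augment(img, rng) for img in batch])


def train(dataset: list[LabeledImage], encoder: Conv4Encoder,
          config: FewShotConfig) -> TrainResult:
    """Episodic training: one Adam step per episode, fully seeded.

    History records the per-epoch mean loss and mean query accuracy; the same
    seed reproduces it bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(encoder.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        losses, accs = [], []
        for _ in range(config.episodes_per_epoch):
            episode = sample_episode(dataset, config, rng)
            sup = episode.support.reshape((-1,) + episode.support.shape[2:])
            batch = np.concatenate([sup, episode.query]).astype(np.float64)
            if config.augment:
                batch = _augment_batch(batch, rng)
            feats = encoder(batch, training=True, rng=rng)
            loss, scores = episode_objective(feats, config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(float(np.mean(
                scores.argmax(axis=1) == episode.query_labels)))
        history.append({
            "epoch": epoch + 1,
            "mean_loss": float(np.mean(losses)),
            "mean_query_accuracy": float(np.mean(accs)),
        })
    return TrainResult(encoder=encoder, history=history)
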