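"""Conv4 feature encoder: four conv/norm/ReLU/pool blocks, then flatten.

Implements the encoder contract used by the subspace classifier: a
parameterized map from an image batch to fixed-dimension feature vectors,
deterministic in evaluation mode, with an optional dropout (rate 0.5) applied
to the flattened features in training mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, dropout
from .layers import ConvBlock

__all__ = ["Conv4Spec", "Conv4Encoder", "conv4_encoder"]


@dataclass(frozen=True)
class Conv4Spec:
    in_channels: int = 3
    hidden_channels: int = 8  # sized for single-CPU training budgets
    dropout_rate: float = 0.0  # 0.5 in the dropout scenario
    init_seed: int = 0


class Conv4Encoder:
    def __init__(self, spec: Conv4Spec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        h = spec.hidden_channels
        self.blocks = [
            ConvBlock(spec.in_channels, h, rng),
            ConvBlock(h, h, rng),
            ConvBlock(h, h, rng),
            ConvBlock(h, h, rng),
        ]

    def __call__(self, x: np.ndarray | Tensor, *, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Encode a (B, H, W, 3) image batch into (B, D) features.

        H and W must be divisible by 16 (four 2× poolings).
        """
        if not isinstance(x, Tensor):
            x = np.asarray(x)
            if x.ndim != 4 or x.shape[-1] != self.spec.in_channels:
                raise ValueError("expected a (B, H, W, C) batch")
            x = Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2),
                                            dtype=np.float32) / np.float32(255.0))
        out = x
        for block in self.blocks:
            out = block(out, training)
        b = out.shape[0]
        feats = out.reshape(b, -1)
        if self.spec.dropout_rate > 0 and training:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            feats = dropout(feats, self.spec.dropout_rate, rng, training=True)
        return feats

    def feature_dim(self, image_shape: tuple[int, int]) -> int:
        h, w = image_shape
        if h % 16 or w % 16:
            raise ValueError("image sides must be divisible by 16")
        return (h // 16) * (w // 16) * self.spec.hidden_channels

    def parameters(self) -> list[Tensor]:
        return [p for block in self.blocks for p in block.parameters()]

    # -- checkpointing (text-serializable) ------------------------------
    def state_dict(self) -> dict:
        state: dict = {"spec": self.spec.__dict__ | {}}
        for i, block in enumerate(self.blocks):
            state[f"block{i}"] = {
                "conv.weight": block.conv.weight.data.tolist(),
                "conv.bias": block.conv.bias.data.tolist(),
                "norm.gamma": block.norm.gamma.data.tolist(),
                "norm.beta": block.norm.beta.data.tolist(),
                "norm.running_mean": block.norm.running["mean"].tolist(),
                "norm.running_var": block.norm.running["var"].tolist(),
            }
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, block in enumerate(self.blocks):
            s = state[f"block{i}"]
            block.conv.weight.data = np.asarray(s["conv.weight"], dtype=np.float32)
            block.conv.bias.data = np.asarray(s["conv.bias"], dtype=np.float32)
            block.norm.gamma.data = np.asarray(s["norm.gamma"], dtype=np.float32)
            block.norm.beta.data = np.asarray(s["norm.beta"], dtype=np.float32)
            block.norm.running["mean"] = np.asarray(s["norm.running_mean"], dtype=np.float32)
            block.norm.running["var"] = np.asarray(s["norm.running_var"], dtype=np.float32)

    @classmethod
    def from_state_dict(cls, state: dict) -> "Conv4Encoder":
        enc = cls(Conv4Spec(**state["spec"]))
        enc.load_state_dict(state)
        return enc


def conv4_encoder(spec: Conv4Spec | None = None) -> Conv4Encoder:
    return Conv4Encoder(spec or Conv4Spec())
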