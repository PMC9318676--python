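"""Pre- and post-processing operators around segmentation maps.

Everything here works on in-memory numpy arrays: square zero-padding,
resizing, channel triplication, probability-map ensembling, connected
component cleanup of predicted label maps, and the Jaccard loss used for
segmentation training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "MaskPair",
    "auto_zero_pad",
    "resize_image",
    "triplicate_channels",
    "ensemble_average",
    "postprocess_mask",
    "jaccard_loss",
]

N_CLASSES = 4  # background, RV, MYO, LV


@dataclass(frozen=True)
class MaskPair:
    """A ground-truth / prediction pair of binary masks of identical shape."""

    ground_truth: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.ground_truth)
        p = np.asarray(self.prediction)
        if g.shape != p.shape:
            raise ValueError(
                f"mask shapes differ: {g.shape} vs {p.shape}"
            )


def auto_zero_pad(image: np.ndarray) -> np.ndarray:
    """Zero-pad a 2D (optionally multi-channel) image to a square.

    The pad is split as evenly as possible between the two sides of the
    short axis, with the extra pixel (odd difference) on the trailing side.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2D image, optionally with channels")
    rows, cols = image.shape[:2]
    side = max(rows, cols)
    pad_r = side - rows
    pad_c = side - cols
    pad = [(pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)]
    if image.ndim == 3:
        pad.append((0, 0))
    return np.pad(image, pad, mode="constant")


def resize_image(
    image: np.ndarray, target: tuple[int, int], mode: str = "nearest"
) -> np.ndarray:
    """Resize to ``target`` (rows, cols).

    ``nearest`` preserves the value set (use for label maps); ``bilinear``
    preserves the value range (use for intensity images).
    """
    if mode not in ("nearest", "bilinear"):
        raise ValueError(f"unknown mode {mode!r}")
    image = np.asarray(image)
    tr, tc = target
    if tr <= 0 or tc <= 0:
        raise ValueError("target size must be positive")
    if image.shape[:2] == (tr, tc):
        return image.copy()
    order = 0 if mode == "nearest" else 1
    out_shape = (tr, tc) + image.shape[2:]
    out = _sk_resize(
        image.astype(float),
        out_shape,
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    if np.issubdtype(image.dtype, np.integer) and mode == "nearest":
        return out.astype(image.dtype)
    return out


def triplicate_channels(gray: np.ndarray) -> np.ndarray:
    """Duplicate a single-channel image into three identical channels."""
    gray = np.asarray(gray)
    if gray.ndim == 3 and gray.shape[2] == 1:
        gray = gray[:, :, 0]
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    return np.stack([gray, gray, gray], axis=-1)


def ensemble_average(prob_stacks: list[np.ndarray]) -> np.ndarray:
    """Average per-pixel class-probability stacks and take the per-pixel argmax.

    Softmax of the averaged probabilities would yield the same argmax, so the
    argmax is taken directly on the mean.
    """
    if len(prob_stacks) == 0:
        raise ValueError("need at least one probability stack")
    first = np.asarray(prob_stacks[0], dtype=float)
    for s in prob_stacks[1:]:
        if np.asarray(s).shape != first.shape:
            raise ValueError("probability stacks must share one shape")
    mean = np.mean([np.asarray(s, dtype=float) for s in prob_stacks], axis=0)
    return np.argmax(mean, axis=-1).astype(np.uint8)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    # 4-connectivity: "largest contour" read as largest connected component
    labeled, n = ndimage.label(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return labeled == keep


def postprocess_mask(label_map: np.ndarray) -> np.ndarray:
    """Clean a predicted label map class by class.

    Per non-background class: keep only the largest 4-connected component
    (for the RV this removes spurious double contours), then fill interior
    holes — but only pixels that are background in the input, so one class
    never swallows another (the myocardial annulus encloses the LV cavity).
    """
    label_map = np.asarray(label_map)
    if not np.isin(label_map, [0, 1, 2, 3]).all():
        raise ValueError("labels must be in {0,1,2,3}")
    out = np.zeros_like(label_map)
    background = label_map == 0
    for cls in (1, 2, 3):
        mask = label_map == cls
        if not mask.any():
            continue
        mask = _largest_component(mask)
        filled = ndimage.binary_fill_holes(mask)
        mask = mask | (filled & background & (out == 0))
        out[mask] = cls
    return out


def jaccard_loss(pair: MaskPair) -> float:
    """1 - |G∩P| / (|G| + |P| - |G∩P|), with the empty/empty case defined as 0.

    Accepts binary masks or a probability-valued prediction (soft variant via
    elementwise products and sums).
    """
    g = np.asarray(pair.ground_truth, dtype=float)
    p = np.asarray(pair.prediction, dtype=float)
    inter = float((g * p).sum())
    union = float(g.sum() + p.sum() - inter)
    if union == 0.0:
        return 0.0
    return 1.0 - inter / union
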