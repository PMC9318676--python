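"""Collapse multi-slice ED/ES label maps into one 128×64×3 thickness image.

Each of the first N basal slices contributes a fixed per-slice intensity to
the channel of every structure it contains (RV→red, MYO→green, LV→blue);
the per-slice intensities for a given N sum to 255, so a pixel covered by a
structure in all N slices saturates and brighter pixels mean the structure
spans more slices. The encoded ED frame is cropped, resized to 64×64 and
stacked on top of the ES frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .synthetic import PatientFrames

__all__ = [
    "SLICE_INTENSITY_TABLES",
    "CropSpec",
    "ThicknessImage",
    "select_slices",
    "encode_frame",
    "crop_and_resize",
    "encode_patient",
    "default_slice_count",
]

#: Per-slice intensities, basal first, for each supported slice count N.
#: Each table sums to exactly 255. N > 6 is unsupported.
SLICE_INTENSITY_TABLES: dict[int, tuple[int, ...]] = {
    1: (255,),
    2: (85, 170),
    3: (21, 87, 147),
    4: (16, 51, 85, 103),
    5: (15, 29, 51, 67, 93),
    6: (14, 26, 38, 49, 59, 69),
}

# label value -> output channel: RV->R, MYO->G, LV->B
_CHANNEL_OF_LABEL = {1: 0, 2: 1, 3: 2}


@dataclass(frozen=True)
class CropSpec:
    """Square crop window applied to the encoded 256×256 frame.

    ``mode="center"`` centres the window on the image centre; ``"centroid"``
    centres it on the centroid of nonzero pixels (falling back to the image
    centre for an empty frame). The window is clipped to stay inside the
    image.
    """

    size: int = 128
    mode: str = "center"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("crop size must be positive")
        if self.mode not in ("center", "centroid"):
            raise ValueError(f"unknown crop mode {self.mode!r}")


@dataclass
class ThicknessImage:
    """Per-patient 128×64×3 encoding; rows 0–63 are ED, rows 64–127 ES."""

    patient_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != (128, 64, 3):
            raise ValueError(
                f"thickness image must be 128x64x3, got {self.pixels.shape}"
            )


def select_slices(frame_slices: list[np.ndarray], n: int,
                  patient_id: str = "<unknown>") -> list[np.ndarray]:
    """First ``n`` slices in basal→apical order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(frame_slices) < n:
        raise ValueError(
            f"patient {patient_id}: needs {n} slices, frame has "
            f"{len(frame_slices)}"
        )
    return list(frame_slices[:n])


def encode_frame(
    slices: list[np.ndarray],
    table: dict[int, tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Accumulate per-slice intensities into one H×W×3 image.

    Slice k (basal first) adds ``table[N][k]`` to the channel of each
    structure present at a pixel; with valid label maps no channel can
    exceed 255 because each table sums to 255.
    """
    table = table if table is not None else SLICE_INTENSITY_TABLES
    n = len(slices)
    if n not in table:
        raise ValueError(f"no intensity table for {n} slices")
    values = table[n]
    shape = slices[0].shape
    out = np.zeros(shape + (3,), dtype=np.int32)
    for k, label_map in enumerate(slices):
        if label_map.shape != shape:
            raise ValueError("slices must share one shape")
        for label, channel in _CHANNEL_OF_LABEL.items():
            out[:, :, channel] += np.where(label_map == label, values[k], 0)
    return out


def _window(image: np.ndarray, spec: CropSpec) -> tuple[int, int]:
    rows, cols = image.shape[:2]
    if spec.size > rows or spec.size > cols:
        raise ValueError("crop window larger than image")
    if spec.mode == "centroid":
        nz = np.nonzero(image.sum(axis=-1) if image.ndim == 3 else image)
        if len(nz[0]):
            cr, cc = float(nz[0].mean()), float(nz[1].mean())
        else:
            cr, cc = rows / 2.0, cols / 2.0
    else:
        cr, cc = rows / 2.0, cols / 2.0
    r0 = int(round(cr - spec.size / 2.0))
    c0 = int(round(cc - spec.size / 2.0))
    r0 = min(max(r0, 0), rows - spec.size)
    c0 = min(max(c0, 0), cols - spec.size)
    return r0, c0


def crop_and_resize(image: np.ndarray, crop_spec: CropSpec = CropSpec()) -> np.ndarray:
    """Crop the spec'd square window, bilinearly resize to 64×64 and round
    half-up to integers (accumulated intensities stay graded at 4× scale-down,
    which nearest-neighbour resizing would destroy)."""
    r0, c0 = _window(image, crop_spec)
    win = image[r0:r0 + crop_spec.size, c0:c0 + crop_spec.size]
    if win.size == 0:
        raise ValueError("empty crop window")
    resized = _sk_resize(
        win.astype(float), (64, 64) + image.shape[2:],
        order=1, preserve_range=True, anti_aliasing=False,
    )
    return np.floor(resized + 0.5).astype(np.int32)


def encode_patient(
    patient: PatientFrames,
    n_slices: int,
    table: dict[int, tuple[int, ...]] | None = None,
    crop_spec: CropSpec = CropSpec(),
) -> ThicknessImage:
    """Encode both frames of one patient and join them vertically (ED on top)."""
    halves = []
    for frame in (patient.ed_slices, patient.es_slices):
        chosen = select_slices(frame, n_slices, patient.patient_id)
        encoded = encode_frame(chosen, table)
        halves.append(crop_and_resize(encoded, crop_spec))
    pixels = np.vstack(halves).astype(np.uint8)
    return ThicknessImage(patient.patient_id, pixels)


def default_slice_count(patients: list[PatientFrames], cap: int = 6) -> int:
    """Dataset-level N: the minimum slice count over all patients and frames,
    capped at ``cap``."""
    if not patients:
        raise ValueError("empty dataset")
    n = min(min(len(p.ed_slices), len(p.es_slices)) for p in patients)
    return min(n, cap)
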