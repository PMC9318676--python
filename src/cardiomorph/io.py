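"""File I/O: NIfTI label volumes, thickness PNGs, CSV tables, checkpoints
and run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .fewshot.encoder import Conv4Encoder
from .fewshot.episodes import FewShotConfig
from .synthetic import CONDITIONS, PatientFrames
from .thickness import ThicknessImage

__all__ = [
    "RunConfig",
    "write_patient_niftis",
    "read_patient_niftis",
    "list_patient_ids",
    "write_labels_csv",
    "read_labels_csv",
    "write_thickness_png",
    "read_thickness_png",
    "save_checkpoint",
    "load_checkpoint",
]

_FRAMES = ("ED", "ES")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; written next to its outputs."""

    seed: int = 0
    input_dir: str = ""
    output_dir: str = ""
    n_slices: int | None = None  # None: dataset minimum capped at 6
    crop_size: int = 128
    crop_mode: str = "center"
    downsample: int = 1
    fewshot: dict = field(default_factory=lambda: asdict(FewShotConfig()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def fewshot_config(self) -> FewShotConfig:
        return FewShotConfig(**self.fewshot)


# ---------------------------------------------------------------------------
# NIfTI label volumes (one 3D volume per frame; slices on the third axis,
# index 0 = basal)

def write_patient_niftis(patient: PatientFrames, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, slices in zip(_FRAMES, (patient.ed_slices, patient.es_slices)):
        volume = np.stack(slices, axis=2).astype(np.uint8)
        img = nib.Nifti1Image(volume, affine=np.eye(4))
        nib.save(img, directory / f"{patient.patient_id}_{name}.nii.gz")


def read_patient_niftis(directory: str | Path, patient_id: str,
                        condition: str | None = None) -> PatientFrames:
    """Load the two per-frame label volumes of one patient.

    Validates that labels are integers in {0,1,2,3}; errors name the missing
    frame or the offending slice and value.
    """
    directory = Path(directory)
    frames = {}
    for name in _FRAMES:
        path = directory / f"{patient_id}_{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(
                f"patient {patient_id}: missing {name} frame file {path}")
        data = np.asanyarray(nib.load(path).dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError(
                    f"patient {patient_id} {name}: non-integer label values")
            data = np.round(data).astype(np.int64)
        slices = []
        for k in range(data.shape[2]):
            sl = data[:, :, k]
            bad = np.setdiff1d(np.unique(sl), [0, 1, 2, 3])
            if bad.size:
                raise ValueError(
                    f"patient {patient_id} {name} slice {k}: "
                    f"invalid label value(s) {bad.tolist()}")
            slices.append(sl.astype(np.uint8))
        frames[name] = slices
    return PatientFrames(patient_id, condition, frames["ED"], frames["ES"])


def list_patient_ids(directory: str | Path) -> list[str]:
    directory = Path(directory)
    ids = {p.name[: -len("_ED.nii.gz")]
           for p in directory.glob("*_ED.nii.gz")}
    return sorted(ids)


# ---------------------------------------------------------------------------
# labels CSV (patient_id, condition)

def write_labels_csv(labels: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"patient_id": pid, "condition": cond}
         for pid, cond in sorted(labels.items())])
    df.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition name(s): {sorted(bad)}")
    return dict(zip(df["patient_id"].astype(str), df["condition"]))


# ---------------------------------------------------------------------------
# thickness PNGs (8-bit RGB, bit-exact round trip)

def write_thickness_png(image: ThicknessImage, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{image.patient_id}_thickness.png"
    Image.fromarray(image.pixels.astype(np.uint8), mode="RGB").save(path)
    return path


def read_thickness_png(path: str | Path) -> ThicknessImage:
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("RGB"))
    patient_id = path.name[: -len("_thickness.png")]
    return ThicknessImage(patient_id, pixels)


# ---------------------------------------------------------------------------
# encoder checkpoints (JSON text; floats survive round trips exactly)

_CHECKPOINT_VERSION = 1


def save_checkpoint(encoder: Conv4Encoder, config: FewShotConfig,
                    path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "format_version": _CHECKPOINT_VERSION,
        "fewshot_config": asdict(config),
        "encoder": encoder.state_dict(),
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[Conv4Encoder, FewShotConfig, dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version in {path}")
    encoder = Conv4Encoder.from_state_dict(payload["encoder"])
    config = FewShotConfig(**payload["fewshot_config"])
    return encoder, config, payload.get("extra", {})
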