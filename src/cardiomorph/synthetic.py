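"""Synthetic multi-slice ED/ES cardiac label maps for five morphology groups.

The generator rasterizes a minimal disc / annulus / crescent anatomy per
short-axis slice: an LV blood-pool disc (label 3), a myocardial annulus
around it (label 2) and an RV crescent hugging the annulus (label 1), on a
zero background. Slices taper from base to apex; ES frames are derived from
ED frames by contracting the cavity radii. Morphology groups differ in LV
cavity size, wall thickness, RV size and ED→ES contraction, which gives a
labeled dataset with recoverable class structure for the downstream
encoder/classifier without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONDITIONS",
    "SliceGeometry",
    "ConditionProfile",
    "PatientFrames",
    "default_profiles",
    "apical_gradient_profiles",
    "make_slice_label_map",
    "make_patient",
    "make_dataset",
    "make_probability_maps",
]

#: Condition group names, in canonical (alphabetical) label order.
CONDITIONS = ("ARV", "DCM", "HCM", "MINF", "NOR")

BACKGROUND, RV, MYO, LV = 0, 1, 2, 3


@dataclass(frozen=True)
class SliceGeometry:
    """Anatomy of one short-axis slice, in pixels.

    ``rv_extent`` is the radial depth of the RV crescent beyond the
    epicardial border; ``rv_angular_span`` its angular width (radians),
    centred on the image-left direction.
    """

    center: tuple[float, float]
    lv_radius: float
    myo_thickness: float
    rv_extent: float
    rv_angular_span: float = 0.6 * math.pi

    def outer_radius(self) -> float:
        return self.lv_radius + self.myo_thickness + self.rv_extent

    def validate(self, shape: tuple[int, int]) -> None:
        if self.lv_radius < 0 or self.myo_thickness < 0 or self.rv_extent < 0:
            raise ValueError("geometry radii must be non-negative")
        r, c = self.center
        out = self.outer_radius()
        if r - out < 0 or c - out < 0 or r + out > shape[0] or c + out > shape[1]:
            raise ValueError(
                f"geometry (outer radius {out:.1f} at {self.center}) exceeds "
                f"image bounds {shape}"
            )


@dataclass(frozen=True)
class ConditionProfile:
    """Sampling distributions for one condition group (ED state, pixels)."""

    condition: str
    lv_radius: tuple[float, float]  # (mean, sd)
    myo_thickness: tuple[float, float]
    rv_extent: tuple[float, float]
    es_contraction_factor: float  # mean cavity-radius scale at ES, in (0, 1]
    es_contraction_spread: float = 0.0  # per-patient sd of the factor
    #: optional contraction factor at the apex; when set, the factor grades
    #: linearly from basal to apical slices (regional wall-motion abnormality)
    es_contraction_apical: float | None = None
    #: multiplier on myo_thickness reached at the apex (apical hypertrophy
    #: grades in linearly; 1.0 = uniform wall)
    myo_apical_scale: float = 1.0
    apical_taper: float = 0.07  # per-slice fractional shrink, base -> apex
    center_jitter: float = 4.0
    #: sd of independent per-slice multiplicative jitter on each radius;
    #: 0 keeps slice areas strictly monotone from base to apex
    slice_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.es_contraction_factor <= 1.0):
            raise ValueError("es_contraction_factor must be in (0, 1]")


@dataclass
class PatientFrames:
    """Ordered basal→apical ED and ES label-map stacks for one patient."""

    patient_id: str
    condition: str | None
    ed_slices: list[np.ndarray]
    es_slices: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.ed_slices) < 1 or len(self.es_slices) < 1:
            raise ValueError("each frame needs at least one slice")
        shapes = {s.shape for s in self.ed_slices} | {s.shape for s in self.es_slices}
        if len(shapes) != 1:
            raise ValueError("all slices of a patient must share one shape")
        for s in self.ed_slices + self.es_slices:
            if not np.isin(s, [0, 1, 2, 3]).all():
                raise ValueError("label maps must be valued in {0,1,2,3}")


def default_profiles() -> dict[str, ConditionProfile]:
    """Default per-condition profiles.

    Chosen so that each pair of groups is separated by at least one of
    (LV area, MYO area, RV area, ED→ES LV area ratio): DCM has the largest,
    barely contracting LV; HCM the thickest wall; MINF a normal-sized LV
    with weak contraction; ARV the largest RV; NOR is the reference.
    """
    return {
        "NOR": ConditionProfile("NOR", (20, 2.0), (8, 1.0), (12, 2.0), 0.60, 0.04),
        "DCM": ConditionProfile("DCM", (30, 2.5), (6, 1.0), (12, 2.0), 0.92, 0.03),
        "HCM": ConditionProfile("HCM", (17, 2.0), (10, 1.2), (10, 2.0), 0.60, 0.04,
                                myo_apical_scale=2.2),
        "MINF": ConditionProfile("MINF", (21, 2.0), (8, 1.0), (12, 2.0), 0.65, 0.04,
                                 es_contraction_apical=1.0),
        "ARV": ConditionProfile("ARV", (20, 2.0), (8, 1.0), (22, 2.5), 0.78, 0.04),
    }


def apical_gradient_profiles() -> dict[str, ConditionProfile]:
    """Profiles whose five classes differ only in apically-graded features
    (contraction failure and/or wall thickening toward the apex).

    With a single basal slice the classes are indistinguishable by
    construction; every additional slice adds signal, so classification
    accuracy grows with the number of encoded slices. Used to exercise the
    slice-count information property.
    """
    base = dict(lv_radius=(20.0, 1.5), myo_thickness=(8.0, 1.0),
                rv_extent=(12.0, 1.5), es_contraction_factor=0.60,
                es_contraction_spread=0.03)
    return {
        "NOR": ConditionProfile("NOR", **base),
        "MINF": ConditionProfile("MINF", **base, es_contraction_apical=1.0),
        "DCM": ConditionProfile("DCM", **base, es_contraction_apical=0.82),
        "HCM": ConditionProfile("HCM", **base, myo_apical_scale=2.2),
        "ARV": ConditionProfile("ARV", **base, es_contraction_apical=1.0,
                                myo_apical_scale=2.2),
    }


def make_slice_label_map(
    geometry: SliceGeometry, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize one slice geometry into an integer label map.

    LV disc = 3, myocardial annulus = 2, RV crescent = 1, background = 0;
    the regions are mutually exclusive by construction.
    """
    geometry.validate(shape)
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dr = rr - geometry.center[0]
    dc = cc - geometry.center[1]
    dist = np.hypot(dr, dc)

    out = np.zeros(shape, dtype=np.uint8)
    lv_r = geometry.lv_radius
    epi_r = lv_r + geometry.myo_thickness
    if lv_r > 0:
        out[dist <= lv_r] = LV
    if geometry.myo_thickness > 0:
        out[(dist > lv_r) & (dist <= epi_r)] = MYO
    if geometry.rv_extent > 0:
        angle = np.arctan2(dr, -dc)  # 0 rad points to image left
        in_span = np.abs(angle) <= geometry.rv_angular_span / 2.0
        rv = (dist > epi_r) & (dist <= epi_r + geometry.rv_extent) & in_span
        out[rv] = RV
    return out


def _draw_ed_geometry(
    profile: ConditionProfile,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> SliceGeometry:
    center = (
        shape[0] / 2.0 + rng.uniform(-profile.center_jitter, profile.center_jitter),
        shape[1] / 2.0 + rng.uniform(-profile.center_jitter, profile.center_jitter),
    )
    lv = max(3.0, rng.normal(*profile.lv_radius))
    myo = max(1.0, rng.normal(*profile.myo_thickness))
    rv = max(0.0, rng.normal(*profile.rv_extent))
    return SliceGeometry(center, lv, myo, rv)


def _taper(geom: SliceGeometry, factor: float) -> SliceGeometry:
    return replace(
        geom,
        lv_radius=geom.lv_radius * factor,
        myo_thickness=max(1.0, geom.myo_thickness * factor),
        rv_extent=geom.rv_extent * factor,
    )


def _contract(geom: SliceGeometry, factor: float) -> SliceGeometry:
    """ES geometry from ED: cavity radii scale down, the wall thickens so the
    myocardial ring area is roughly conserved."""
    lv_es = geom.lv_radius * factor
    epi_ed = geom.lv_radius + geom.myo_thickness
    # conserve annulus area: epi_es^2 - lv_es^2 == epi_ed^2 - lv_ed^2
    epi_es = math.sqrt(max(epi_ed**2 - geom.lv_radius**2 + lv_es**2, lv_es**2 + 1.0))
    return replace(
        geom,
        lv_radius=lv_es,
        myo_thickness=max(1.0, epi_es - lv_es),
        rv_extent=geom.rv_extent * factor,
    )


def _jitter(geom: SliceGeometry, sd: float,
            rng: np.random.Generator) -> SliceGeometry:
    f = 1.0 + rng.normal(0.0, sd, size=3)
    return replace(
        geom,
        lv_radius=max(2.0, geom.lv_radius * max(f[0], 0.2)),
        myo_thickness=max(1.0, geom.myo_thickness * max(f[1], 0.2)),
        rv_extent=max(0.0, geom.rv_extent * max(f[2], 0.2)),
    )


def make_patient(
    profile: ConditionProfile,
    n_slices: int,
    shape: tuple[int, int] = (256, 256),
    seed: int | np.random.Generator = 0,
    patient_id: str | None = None,
) -> PatientFrames:
    """Generate one patient: ``n_slices`` tapered ED slices plus ES slices
    derived from them by cavity contraction. Deterministic for a fixed seed."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = _draw_ed_geometry(profile, shape, rng)
    offset = rng.normal(0.0, profile.es_contraction_spread)
    basal = float(np.clip(profile.es_contraction_factor + offset, 0.05, 1.0))
    apical = basal if profile.es_contraction_apical is None else float(
        np.clip(profile.es_contraction_apical + offset, 0.05, 1.0))
    ed, es = [], []
    for i in range(n_slices):
        factor = max(1.0 - profile.apical_taper * i, 0.05)
        frac = i / max(n_slices - 1, 1)
        contraction = basal + (apical - basal) * frac
        geom_ed = _taper(base, factor)
        if profile.myo_apical_scale != 1.0:
            geom_ed = replace(geom_ed, myo_thickness=geom_ed.myo_thickness * (
                1.0 + (profile.myo_apical_scale - 1.0) * frac))
        geom_es = _contract(geom_ed, contraction)
        if profile.slice_noise > 0:
            geom_ed = _jitter(geom_ed, profile.slice_noise, rng)
            geom_es = _jitter(geom_es, profile.slice_noise, rng)
        ed.append(make_slice_label_map(geom_ed, shape))
        es.append(make_slice_label_map(geom_es, shape))
    pid = patient_id if patient_id is not None else f"{profile.condition}_000"
    return PatientFrames(pid, profile.condition, ed, es)


def make_dataset(
    n_per_class: int,
    n_slices: int | tuple[int, int] = (6, 10),
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    profiles: dict[str, ConditionProfile] | None = None,
) -> list[PatientFrames]:
    """Balanced labeled dataset: ``n_per_class`` patients for each of the five
    condition groups, unique patient IDs, reproducible under ``seed``.

    ``n_slices`` may be a fixed count or an inclusive (low, high) range
    sampled per patient.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    patients: list[PatientFrames] = []
    for condition in CONDITIONS:
        profile = profiles[condition]
        for i in range(n_per_class):
            if isinstance(n_slices, tuple):
                k = int(rng.integers(n_slices[0], n_slices[1] + 1))
            else:
                k = int(n_slices)
            patients.append(
                make_patient(profile, k, shape, rng, patient_id=f"{condition}_{i:03d}")
            )
    return patients


def make_probability_maps(
    label_map: np.ndarray,
    noise_level: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Turn a label map into an H×W×4 stack of per-pixel class probabilities.

    Each pixel starts as the one-hot vector of its label; with probability
    ``noise_level`` a pixel's vector is replaced by a random draw from the
    flat Dirichlet on the 4-simplex (so single noisy maps make argmax errors
    that ensemble averaging can repair). At ``noise_level=0`` the argmax
    reproduces the input exactly.
    """
    if not (0.0 <= noise_level < 1.0):
        raise ValueError("noise_level must be in [0, 1)")
    label_map = np.asarray(label_map)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = np.zeros(label_map.shape + (4,), dtype=float)
    idx = np.indices(label_map.shape)
    probs[idx[0], idx[1], label_map] = 1.0
    if noise_level > 0:
        noisy = rng.random(label_map.shape) < noise_level
        n = int(noisy.sum())
        if n:
            probs[noisy] = rng.dirichlet(np.ones(4), size=n)
    return probs
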