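"""Shared fixtures. Thread pinning must happen before numpy is imported so
that BLAS reduction order — and therefore every seeded training trajectory —
is identical across machines."""

import os

os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np  # noqa: E402
import pytest  # noqa: E402

from cardiomorph.synthetic import (SliceGeometry, default_profiles,  # noqa: E402
                                   make_patient)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def centered_geometry():
    return SliceGeometry(center=(128.0, 128.0), lv_radius=20.0,
                         myo_thickness=8.0, rv_extent=12.0)


@pytest.fixture
def nor_patient():
    return make_patient(default_profiles()["NOR"], 6, (256, 256), seed=42,
                        patient_id="NOR_042")
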