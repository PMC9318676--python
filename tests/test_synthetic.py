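import math
from itertools import combinations

import numpy as np
import pytest

from cardiomorph.synthetic import (CONDITIONS, ConditionProfile, SliceGeometry,
                                   apical_gradient_profiles, default_profiles,
                                   make_dataset, make_patient,
                                   make_probability_maps, make_slice_label_map)


class TestMakeSliceLabelMap:
    def test_empty_geometry_all_background(self):
        geom = SliceGeometry((32, 32), lv_radius=0.0, myo_thickness=0.0,
                             rv_extent=0.0)
        out = make_slice_label_map(geom, (64, 64))
        assert not out.any()

    def test_disc_area_matches_analytic(self):
        geom = SliceGeometry((32, 32), lv_radius=10.0, myo_thickness=3.0,
                             rv_extent=0.0)
        out = make_slice_label_map(geom, (64, 64))
        lv_area = int((out == 3).sum())
        assert abs(lv_area - math.pi * 100) / (math.pi * 100) < 0.05

    def test_label_set_contract(self, centered_geometry):
        out = make_slice_label_map(centered_geometry, (256, 256))
        assert set(np.unique(out)) <= {0, 1, 2, 3}

    def test_regions_mutually_exclusive_by_radius(self, centered_geometry):
        out = make_slice_label_map(centered_geometry, (256, 256))
        rr, cc = np.mgrid[0:256, 0:256]
        d = np.hypot(rr - 128, cc - 128)
        assert (out[d <= 19.5] == 3).all()
        ring = (d > 20.5) & (d <= 27.5)
        assert (out[ring] == 2).all()

    def test_out_of_bounds_rejected(self):
        geom = SliceGeometry((10, 10), lv_radius=20.0, myo_thickness=2.0,
                             rv_extent=0.0)
        with pytest.raises(ValueError, match="bounds"):
            make_slice_label_map(geom, (64, 64))

    def test_negative_radius_rejected(self):
        geom = SliceGeometry((32, 32), lv_radius=-1.0, myo_thickness=1.0,
                             rv_extent=0.0)
        with pytest.raises(ValueError):
            make_slice_label_map(geom, (64, 64))


class TestMakePatient:
    def test_deterministic(self):
        prof = default_profiles()["HCM"]
        a = make_patient(prof, 6, (256, 256), seed=9)
        b = make_patient(prof, 6, (256, 256), seed=9)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.ed_slices + a.es_slices,
                                   b.ed_slices + b.es_slices))

    def test_lv_area_non_increasing_basal_to_apical(self, nor_patient):
        areas = [(s == 3).sum() for s in nor_patient.ed_slices]
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        assert areas[0] > areas[-1]

    def test_es_smaller_than_ed(self, nor_patient):
        ed = sum((s == 3).sum() for s in nor_patient.ed_slices)
        es = sum((s == 3).sum() for s in nor_patient.es_slices)
        assert es < ed

    def test_dcm_larger_than_nor_on_average(self):
        profs = default_profiles()
        dcm = [make_patient(profs["DCM"], 4, seed=s) for s in range(20)]
        nor = [make_patient(profs["NOR"], 4, seed=s) for s in range(20)]
        area = lambda ps: np.mean(
            [sum((s == 3).sum() for s in p.ed_slices) for p in ps])
        assert area(dcm) > area(nor)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            make_patient(default_profiles()["NOR"], 0)

    def test_bad_contraction_rejected(self):
        with pytest.raises(ValueError):
            ConditionProfile("X", (20, 1), (8, 1), (12, 1), 1.5)


class TestMakeDataset:
    def test_balanced_counts(self):
        ds = make_dataset(4, 6, seed=0)
        assert len(ds) == 20
        for cond in CONDITIONS:
            assert sum(p.condition == cond for p in ds) == 4

    def test_unique_ids(self):
        ds = make_dataset(5, 6, seed=0)
        assert len({p.patient_id for p in ds}) == len(ds)

    def test_reproducible(self):
        a = make_dataset(2, 6, seed=3)
        b = make_dataset(2, 6, seed=3)
        for pa, pb in zip(a, b):
            assert pa.patient_id == pb.patient_id
            assert all(np.array_equal(x, y)
                       for x, y in zip(pa.ed_slices, pb.ed_slices))

    def test_disjoint_seeds_differ(self):
        a = make_dataset(2, 6, seed=0)
        b = make_dataset(2, 6, seed=1)
        assert any(not np.array_equal(x.ed_slices[0], y.ed_slices[0])
                   for x, y in zip(a, b))

    def test_slice_range_sampling(self):
        ds = make_dataset(6, (6, 10), seed=0)
        counts = {len(p.ed_slices) for p in ds}
        assert counts <= set(range(6, 11))
        assert len(counts) > 1
        for p in ds:
            assert len(p.ed_slices) == len(p.es_slices)

    def test_supports_five_shot_five_query_split(self):
        # 20 per class covers a 5-shot/5-query episode with room to spare
        ds = make_dataset(20, 6, seed=0)
        per_class = {c: sum(p.condition == c for p in ds) for c in CONDITIONS}
        assert all(v == 20 >= 5 + 5 for v in per_class.values())


class TestClassSeparability:
    def _features(self, patients):
        feats = {}
        for p in patients:
            lv = sum((s == 3).sum() for s in p.ed_slices)
            myo = sum((s == 2).sum() for s in p.ed_slices)
            rv = sum((s == 1).sum() for s in p.ed_slices)
            ratio = sum((s == 3).sum() for s in p.es_slices) / lv
            feats.setdefault(p.condition, []).append([lv, myo, rv, ratio])
        return {c: np.array(v) for c, v in feats.items()}

    def test_pairwise_separation_exceeds_pooled_sd(self):
        feats = self._features(make_dataset(20, 6, seed=0))
        for a, b in combinations(CONDITIONS, 2):
            va, vb = feats[a], feats[b]
            pooled = np.sqrt((va.var(axis=0) + vb.var(axis=0)) / 2)
            gap = np.abs(va.mean(axis=0) - vb.mean(axis=0)) / pooled
            assert gap.max() > 1.0, f"{a} vs {b} inseparable: {gap}"

    def test_condition_invariants(self):
        profs = default_profiles()
        assert max(profs, key=lambda c: profs[c].lv_radius[0]) == "DCM"
        assert max(profs, key=lambda c: profs[c].myo_thickness[0]) == "HCM"
        assert max(profs, key=lambda c: profs[c].rv_extent[0]) == "ARV"
        assert profs["DCM"].es_contraction_factor > 0.9  # barely contracts

    def test_minf_ejection_fraction_below_forty_percent(self):
        prof = default_profiles()["MINF"]
        efs = []
        for s in range(20):
            p = make_patient(prof, 6, seed=s)
            edv = sum((sl == 3).sum() for sl in p.ed_slices)
            esv = sum((sl == 3).sum() for sl in p.es_slices)
            efs.append(1 - esv / edv)
        assert np.mean(efs) < 0.40

    def test_apical_gradient_profiles_share_basal_distribution(self):
        profs = apical_gradient_profiles()
        base = profs["NOR"]
        for p in profs.values():
            assert p.lv_radius == base.lv_radius
            assert p.myo_thickness == base.myo_thickness
            assert p.es_contraction_factor == base.es_contraction_factor


class TestMakeProbabilityMaps:
    def test_noiseless_argmax_reproduces_labels(self):
        label = np.random.default_rng(0).integers(0, 4, (16, 16))
        probs = make_probability_maps(label, 0.0)
        assert np.array_equal(np.argmax(probs, axis=-1), label)

    def test_simplex_normalization(self):
        label = np.random.default_rng(0).integers(0, 4, (16, 16))
        probs = make_probability_maps(label, 0.5, seed=2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_deterministic_under_seed(self):
        label = np.random.default_rng(0).integers(0, 4, (16, 16))
        a = make_probability_maps(label, 0.3, seed=5)
        b = make_probability_maps(label, 0.3, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            make_probability_maps(np.zeros((4, 4), dtype=int), 1.0)
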