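import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomorph.segops import (MaskPair, auto_zero_pad, ensemble_average,
                                jaccard_loss, postprocess_mask, resize_image,
                                triplicate_channels)
from cardiomorph.synthetic import make_probability_maps


class TestAutoZeroPad:
    def test_square_unchanged(self):
        img = np.arange(100).reshape(10, 10)
        assert np.array_equal(auto_zero_pad(img), img)

    def test_even_split(self):
        img = np.ones((8, 6))
        out = auto_zero_pad(img)
        assert out.shape == (8, 8)
        assert np.array_equal(out[:, 0], np.zeros(8))
        assert np.array_equal(out[:, 7], np.zeros(8))
        assert np.array_equal(out[:, 1:7], img)

    def test_odd_split_trailing_extra(self):
        img = np.ones((8, 5))
        out = auto_zero_pad(img)
        assert out.shape == (8, 8)
        assert np.array_equal(out[:, 0], np.zeros(8))  # one leading
        assert np.array_equal(out[:, 6:], np.zeros((8, 2)))  # two trailing
        assert np.array_equal(out[:, 1:6], img)

    def test_rows_padded_too(self):
        out = auto_zero_pad(np.ones((3, 7)))
        assert out.shape == (7, 7)
        assert out.sum() == 21

    def test_channels_preserved(self):
        out = auto_zero_pad(np.ones((4, 6, 3)))
        assert out.shape == (6, 6, 3)

    @given(rows=st.integers(1, 40), cols=st.integers(1, 40))
    @settings(max_examples=30, deadline=None)
    def test_always_square_and_content_preserved(self, rows, cols):
        img = np.ones((rows, cols))
        out = auto_zero_pad(img)
        side = max(rows, cols)
        assert out.shape == (side, side)
        assert out.sum() == img.sum()


class TestResizeImage:
    def test_identity(self):
        img = np.random.default_rng(0).integers(0, 4, (12, 12))
        assert np.array_equal(resize_image(img, (12, 12)), img)

    def test_nearest_preserves_label_set(self):
        img = np.random.default_rng(0).integers(0, 4, (16, 16))
        out = resize_image(img, (32, 32), mode="nearest")
        assert set(np.unique(out)) <= set(np.unique(img))

    def test_constant_stays_constant(self):
        img = np.full((10, 14), 7.0)
        out = resize_image(img, (21, 9), mode="bilinear")
        assert np.allclose(out, 7.0)

    def test_bilinear_preserves_range(self):
        img = np.random.default_rng(0).random((16, 16)) * 100
        out = resize_image(img, (64, 64), mode="bilinear")
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            resize_image(np.ones((4, 4)), (8, 8), mode="cubic")


class TestTriplicateChannels:
    def test_zeros(self):
        out = triplicate_channels(np.zeros((5, 7)))
        assert out.shape == (5, 7, 3)
        assert not out.any()

    def test_channels_identical(self):
        img = np.random.default_rng(0).random((9, 9))
        out = triplicate_channels(img)
        assert np.array_equal(out[..., 0], out[..., 1])
        assert np.array_equal(out[..., 1], out[..., 2])

    def test_segmentation_input_size(self):
        out = triplicate_channels(np.zeros((256, 256)))
        assert out.shape == (256, 256, 3)

    def test_multichannel_rejected(self):
        with pytest.raises(ValueError):
            triplicate_channels(np.zeros((4, 4, 3)))


class TestEnsembleAverage:
    def test_single_stack(self):
        stack = make_probability_maps(
            np.random.default_rng(0).integers(0, 4, (8, 8)), 0.4, seed=1)
        assert np.array_equal(ensemble_average([stack]),
                              np.argmax(stack, axis=-1))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        label = rng.integers(0, 4, (12, 12))
        stacks = [make_probability_maps(label, 0.3, seed=s) for s in range(4)]
        a = ensemble_average(stacks)
        b = ensemble_average(stacks[::-1])
        assert np.array_equal(a, b)

    def test_noiseless_stacks_recover_map(self):
        label = np.random.default_rng(0).integers(0, 4, (10, 10))
        stacks = [make_probability_maps(label, 0.0, seed=s) for s in range(5)]
        assert np.array_equal(ensemble_average(stacks), label)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([np.ones((4, 4, 4)) / 4, np.ones((5, 5, 4)) / 4])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])

    def test_averaging_beats_single_stacks(self):
        # a noisy ensemble should agree with the truth better than any member
        label = np.random.default_rng(7).integers(0, 4, (64, 64))
        stacks = [make_probability_maps(label, 0.3, seed=100 + s)
                  for s in range(5)]
        single = [np.mean(np.argmax(s, axis=-1) == label) for s in stacks]
        fused = np.mean(ensemble_average(stacks) == label)
        assert fused > max(single)


class TestPostprocessMask:
    def test_hole_filled(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 3
        mask[9, 9] = 0  # interior background hole
        out = postprocess_mask(mask)
        assert out[9, 9] == 3

    def test_largest_rv_component_kept(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:12, 2:12] = 1  # large RV blob
        mask[20:23, 20:23] = 1  # small spurious blob
        out = postprocess_mask(mask)
        assert out[5, 5] == 1
        assert not out[20:23, 20:23].any()

    def test_clean_map_unchanged(self, centered_geometry):
        from cardiomorph.synthetic import make_slice_label_map
        label = make_slice_label_map(centered_geometry, (256, 256))
        assert np.array_equal(postprocess_mask(label), label)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        label = rng.integers(0, 4, (40, 40)).astype(np.uint8)
        once = postprocess_mask(label)
        assert np.array_equal(postprocess_mask(once), once)

    def test_annulus_interior_not_claimed(self):
        # myo ring around an LV disc: hole filling must not overwrite the LV
        label = np.zeros((30, 30), dtype=np.uint8)
        rr, cc = np.mgrid[0:30, 0:30]
        d = np.hypot(rr - 15, cc - 15)
        label[d <= 10] = 2
        label[d <= 6] = 3
        out = postprocess_mask(label)
        assert np.array_equal(out, label)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            postprocess_mask(np.full((4, 4), 5))


class TestJaccardLoss:
    def test_identical_nonempty(self):
        g = np.zeros((6, 6)); g[1:3, 1:3] = 1
        assert jaccard_loss(MaskPair(g, g.copy())) == 0.0

    def test_disjoint(self):
        g = np.zeros((6, 6)); g[0, 0] = 1
        p = np.zeros((6, 6)); p[5, 5] = 1
        assert jaccard_loss(MaskPair(g, p)) == 1.0

    def test_two_thirds(self):
        # |G|=|P|=2, |G∩P|=1 -> 1 - 1/3
        g = np.zeros(6); g[[0, 1]] = 1
        p = np.zeros(6); p[[1, 2]] = 1
        assert jaccard_loss(MaskPair(g, p)) == pytest.approx(2.0 / 3.0)

    def test_both_empty_is_zero(self):
        assert jaccard_loss(MaskPair(np.zeros((3, 3)), np.zeros((3, 3)))) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MaskPair(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_soft_variant_bounds(self):
        rng = np.random.default_rng(0)
        g = (rng.random((8, 8)) > 0.5).astype(float)
        p = rng.random((8, 8))
        loss = jaccard_loss(MaskPair(g, p))
        assert 0.0 <= loss <= 1.0

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_and_bounded(self, a_bits, b_bits):
        g = np.array([(a_bits >> i) & 1 for i in range(16)], dtype=float)
        p = np.array([(b_bits >> i) & 1 for i in range(16)], dtype=float)
        ab = jaccard_loss(MaskPair(g, p))
        ba = jaccard_loss(MaskPair(p, g))
        assert ab == ba
        assert 0.0 <= ab <= 1.0

    def test_monotone_in_intersection(self):
        # fixed |G|=|P|=4; loss non-increasing as overlap grows
        losses = []
        for k in range(5):
            g = np.zeros(12); g[:4] = 1
            p = np.zeros(12); p[4 - k:8 - k] = 1
            losses.append(jaccard_loss(MaskPair(g, p)))
        assert all(x >= y for x, y in zip(losses, losses[1:]))
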