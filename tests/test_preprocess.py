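"""Nyul standardization, body-mask extraction, rigid resampling, windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mr2sct as m
from mr2sct.preprocess import (DEFAULT_PERCENTILES, NyulStandardizer,
                               estimate_rigid_shift)
from mr2sct.volume import Volume


def _vol(data, spacing=(1.0, 1.0, 1.0), modality="MR"):
    return Volume(np.asarray(data, dtype=np.float32), spacing, modality=modality)


def _mask_like(v, value=1):
    return v.with_data(np.full(v.shape, value, dtype=np.uint8), "MASK")


class TestStandardScale:
    def test_uniform_image_maps_landmarks_to_percentiles(self):
        """Foreground uniform on [0, 100] with s_range (0, 100): the standard
        landmarks are (approximately) the percentiles themselves."""
        rng = np.random.default_rng(0)
        v = _vol(rng.uniform(0, 100, (20, 40, 40)))
        scale = m.compute_standard_scale([v], [_mask_like(v)],
                                         s_range=(0.0, 100.0))
        assert np.allclose(scale.standard_landmarks, DEFAULT_PERCENTILES,
                           atol=1.5)

    def test_affine_transforms_contribute_identically(self):
        rng = np.random.default_rng(1)
        a = _vol(rng.gamma(3.0, 10.0, (10, 24, 24)))
        b = a.with_data(2.0 * a.data + 50.0)
        sa = m.compute_standard_scale([a], [_mask_like(a)])
        sb = m.compute_standard_scale([b], [_mask_like(b)])
        sab = m.compute_standard_scale([a, b], [_mask_like(a), _mask_like(b)])
        # exact up to float32 storage of the transformed copy
        assert np.allclose(sa.standard_landmarks, sb.standard_landmarks,
                           atol=1e-4)
        assert np.allclose(sab.standard_landmarks, sa.standard_landmarks,
                           atol=1e-4)

    def test_matches_brute_force_percentile_oracle(self):
        """Mean of per-image affinely mapped percentile vectors, computed
        with an independent direct percentile routine."""
        rng = np.random.default_rng(2)
        vols = [_vol(rng.uniform(5, 90 + 30 * i, (10, 10, 10)))
                for i in range(3)]
        masks = [_mask_like(v) for v in vols]
        s_min, s_max = 0.0, 100.0
        scale = m.compute_standard_scale(vols, masks, s_range=(s_min, s_max))

        mapped = []
        for v in vols:
            lm = np.array([np.percentile(v.data.astype(np.float64).ravel(), p)
                           for p in DEFAULT_PERCENTILES])
            mapped.append(s_min + (lm - lm[0]) / (lm[-1] - lm[0]) * (s_max - s_min))
        expected = np.mean(mapped, axis=0)
        assert np.allclose(scale.standard_landmarks, expected, atol=1e-9)

    def test_constant_image_is_rejected_with_its_name(self):
        v = _vol(np.full((16, 16, 16), 7.0))
        with pytest.raises(ValueError, match="image 0"):
            m.compute_standard_scale([v], [_mask_like(v)])

    def test_empty_foreground_rejected(self):
        v = _vol(np.random.default_rng(0).uniform(0, 1, (8, 8, 8)))
        with pytest.raises(ValueError, match="foreground"):
            m.compute_standard_scale([v], [_mask_like(v, 0)])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        v = _vol(rng.uniform(0, 50, (8, 8, 8)))
        scale = m.compute_standard_scale([v], [_mask_like(v)])
        scale.to_json(tmp_path / "scale.json")
        back = m.StandardScale.from_json(tmp_path / "scale.json")
        assert back == scale


class TestNyulTransform:
    def test_landmarks_map_exactly_onto_standard_scale(self):
        """The image's own percentile landmarks are fixed points of the map:
        after transforming, the output percentiles equal the standard
        landmarks."""
        rng = np.random.default_rng(4)
        v = _vol(rng.uniform(0, 80, (10, 20, 20)))
        scale = m.compute_standard_scale([v], [_mask_like(v)])
        out = m.nyul_transform(v, scale, _mask_like(v))
        lm_out = np.percentile(out.data.astype(np.float64), DEFAULT_PERCENTILES)
        assert np.allclose(lm_out, scale.standard_landmarks, atol=1e-3)

    def test_gain_and_offset_removed_at_landmarks(self):
        rng = np.random.default_rng(5)
        a = _vol(rng.gamma(2.0, 15.0, (10, 20, 20)))
        b = a.with_data((2.0 * a.data + 50.0).astype(np.float32))
        scale = m.compute_standard_scale([a, b], [_mask_like(a), _mask_like(b)])
        ta = m.nyul_transform(a, scale, _mask_like(a))
        tb = m.nyul_transform(b, scale, _mask_like(b))
        for p in DEFAULT_PERCENTILES:
            assert np.isclose(np.percentile(ta.data, p),
                              np.percentile(tb.data, p), atol=1e-3)

    def test_two_segment_toy_matches_hand_interpolation(self):
        """10 voxels, 3 landmarks (p1/p50/p99): hand-computed piecewise map."""
        vals = np.array([0., 1., 2., 3., 4., 5., 6., 7., 8., 10.])
        v = _vol(vals.reshape(1, 1, 10).repeat(16, 0).repeat(16, 1))
        scale = m.StandardScale((1, 50, 99), (0.0, 30.0, 100.0), (0.0, 100.0))
        out = m.nyul_transform(v, scale, _mask_like(v))
        lm = np.percentile(v.data.astype(np.float64), [1, 50, 99])
        expected = np.empty_like(vals)
        for i, x in enumerate(vals):
            if x <= lm[1]:  # first segment (with linear extrapolation below)
                expected[i] = 0.0 + (x - lm[0]) * 30.0 / (lm[1] - lm[0])
            else:
                expected[i] = 30.0 + (x - lm[1]) * 70.0 / (lm[2] - lm[1])
        assert np.allclose(out.data[0, 0], expected, atol=1e-4)

    def test_transform_is_monotone(self):
        rng = np.random.default_rng(6)
        v = _vol(rng.uniform(0, 120, (8, 16, 16)))
        scale = m.compute_standard_scale([v], [_mask_like(v)])
        out = m.nyul_transform(v, scale, _mask_like(v))
        order = np.argsort(v.data.ravel(), kind="stable")
        assert np.all(np.diff(out.data.ravel()[order]) >= -1e-6)

    def test_constant_foreground_rejected(self):
        v = _vol(np.full((16, 16, 16), 3.0))
        scale = m.StandardScale((1, 50, 99), (0.0, 50.0, 100.0))
        with pytest.raises(ValueError, match="landmark"):
            m.nyul_transform(v, scale, _mask_like(v))


def test_nyul_collapses_cohort_landmark_spread(cohort20):
    """Mean pairwise L1 distance between per-case landmark vectors drops to
    <= 10% of its pre-standardization value (histogram alignment made
    quantitative)."""
    std = NyulStandardizer().fit([c.mr for c in cohort20],
                                 masks=[c.body_mask for c in cohort20])

    def pairwise_l1(landmarks):
        lms = np.asarray(landmarks)
        total, n = 0.0, 0
        for i in range(len(lms)):
            for j in range(i + 1, len(lms)):
                total += np.abs(lms[i] - lms[j]).mean()
                n += 1
        return total / n

    before, after = [], []
    for c in cohort20:
        fg = c.mr.data[c.body_mask.data > 0]
        before.append(np.percentile(fg, DEFAULT_PERCENTILES))
        t = std.transform(c.mr, c.body_mask)
        after.append(np.percentile(t.data[c.body_mask.data > 0],
                                   DEFAULT_PERCENTILES))
    assert pairwise_l1(after) <= 0.10 * pairwise_l1(before)


class TestBodyMask:
    def test_recovers_generator_body_mask(self, phantom):
        mask = m.extract_body_mask(phantom.ct)
        assert m.dice(mask, phantom.body_mask) >= 0.98

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            m.extract_body_mask(_vol(np.zeros((16, 16, 16)), modality="CT"))

    def test_mask_has_no_internal_holes(self, phantom):
        from scipy import ndimage
        mask = m.extract_body_mask(phantom.ct).data.astype(bool)
        outside = np.pad(~mask, 1, constant_values=True)  # flood from border
        labels, _ = ndimage.label(outside)
        border_label = labels[0, 0, 0]
        reached = (labels == border_label)[1:-1, 1:-1, 1:-1]
        assert np.array_equal(reached, ~mask)


class TestRigidResample:
    def test_identity_on_same_grid(self, phantom):
        out = m.rigid_resample(phantom.mr, phantom.mr, shift=(0.0, 0.0, 0.0))
        assert np.allclose(out.data, phantom.mr.data, atol=1e-5)

    def test_known_shift_recovered_within_one_mm(self, phantom):
        moved = m.rigid_resample(phantom.mr, phantom.mr, shift=(0.0, 3.0, -2.0))
        est = estimate_rigid_shift(moved, phantom.mr)
        assert np.allclose(est, (0.0, -3.0, 2.0), atol=1.0)

    def test_constant_volume_resamples_to_constant(self):
        c = _vol(np.full((16, 16, 16), 5.0))
        out = m.rigid_resample(c, c, shift=(0.7, -1.3, 2.9))
        assert np.allclose(out.data, 5.0)

    def test_non_overlapping_fov_rejected(self, phantom):
        with pytest.raises(ValueError, match="overlap"):
            m.rigid_resample(phantom.mr, phantom.mr, shift=(1e5, 0.0, 0.0))


class TestScaleWindow:
    def test_endpoints_and_midpoint(self):
        w = m.ScaleWindow(-1000.0, 1500.0)
        v = _vol(np.array([[[-1000.0, 1500.0, 250.0]]]), modality="CT")
        out = m.scale_to_unit(v, w)
        assert np.allclose(out.data, [[[-1.0, 1.0, 0.0]]])

    def test_scale_unscale_inverse_inside_window(self):
        rng = np.random.default_rng(7)
        w = m.ScaleWindow(-1000.0, 1500.0)
        v = _vol(rng.uniform(-1000, 1500, (8, 8, 8)), modality="CT")
        back = m.unscale_from_unit(m.scale_to_unit(v, w), w)
        assert np.allclose(back.data, v.data, atol=1e-3)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="lo < hi"):
            m.ScaleWindow(10.0, 10.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(-1000, 1500))
    def test_round_trip_property(self, x):
        w = m.ScaleWindow(-1000.0, 1500.0)
        v = _vol(np.full((1, 1, 1), x), modality="CT")
        back = m.unscale_from_unit(m.scale_to_unit(v, w), w)
        assert np.allclose(back.data, x, atol=1e-3)
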