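"""Image- and dose-similarity metrics against closed forms and oracles."""

import numpy as np
import pytest
from scipy import stats

import mr2sct as m
from mr2sct.metrics import GammaMap, gaussian_kernel2d
from mr2sct.volume import Volume

from .oracles import gamma_brute_force, ssim_sliding_window

RNG = np.random.default_rng(0)


def _vol(data, spacing=(1.0, 1.0, 1.0), modality="CT"):
    return Volume(np.asarray(data, dtype=np.float64), spacing, modality=modality)


def _full_mask(v):
    return v.with_data(np.ones(v.shape, dtype=np.uint8), "MASK")


class TestMAE:
    def test_identity_and_offset(self):
        a = _vol(RNG.normal(size=(4, 8, 8)))
        assert m.mae(a, a, _full_mask(a)) == 0.0
        b = a.with_data(a.data + 10.0)
        assert m.mae(a, b, _full_mask(a)) == pytest.approx(10.0)

    def test_three_voxel_arithmetic(self):
        a = _vol(np.array([0.0, 100.0, -50.0]).reshape(1, 1, 3))
        b = _vol(np.array([10.0, 90.0, -50.0]).reshape(1, 1, 3))
        assert m.mae(a, b, _full_mask(a)) == pytest.approx(20.0 / 3.0)

    def test_symmetry(self):
        a = _vol(RNG.normal(size=(3, 6, 6)))
        b = _vol(RNG.normal(size=(3, 6, 6)))
        assert m.mae(a, b) == pytest.approx(m.mae(b, a))

    def test_empty_mask_rejected(self):
        a = _vol(np.zeros((2, 4, 4)))
        empty = a.with_data(np.zeros(a.shape, dtype=np.uint8), "MASK")
        with pytest.raises(ValueError, match="empty"):
            m.mae(a, a, empty)


class TestSSIM:
    def test_identical_volumes_give_exactly_one(self):
        a = _vol(RNG.normal(0, 300, size=(4, 16, 16)))
        assert m.ssim(a, a, _full_mask(a)) == 1.0

    def test_constant_images_match_closed_form(self):
        p, q = 120.0, 80.0
        a = _vol(np.full((2, 16, 16), p))
        b = _vol(np.full((2, 16, 16), q))
        params = m.MetricParams()
        c1 = (params.ssim_k1 * params.data_range) ** 2
        expected = (2 * p * q + c1) / (p * p + q * q + c1)
        assert m.ssim(a, b, _full_mask(a), params) == pytest.approx(
            expected, rel=1e-6)

    def test_matches_naive_sliding_window_oracle(self):
        a = RNG.normal(0, 400, size=(4, 32, 32))
        b = a + RNG.normal(0, 150, size=(4, 32, 32))
        mask = RNG.random((4, 32, 32)) < 0.7
        mask[1] = False  # one slice without coverage must be skipped
        va, vb = _vol(a), _vol(b)
        vm = va.with_data(mask.astype(np.uint8), "MASK")
        params = m.MetricParams()
        kern = gaussian_kernel2d(params.ssim_window, params.ssim_sigma)
        c1 = (params.ssim_k1 * params.data_range) ** 2
        c2 = (params.ssim_k2 * params.data_range) ** 2
        expected = ssim_sliding_window(a, b, mask, kern, c1, c2)
        assert m.ssim(va, vb, vm, params) == pytest.approx(expected, abs=1e-8)

    def test_symmetry(self):
        a = _vol(RNG.normal(0, 200, size=(3, 16, 16)))
        b = _vol(RNG.normal(0, 200, size=(3, 16, 16)))
        assert m.ssim(a, b) == pytest.approx(m.ssim(b, a), abs=1e-12)


class TestDice:
    def _mask(self, arr):
        return Volume(np.asarray(arr, dtype=np.uint8), (1, 1, 1),
                      modality="MASK")

    def test_identical_masks(self):
        a = self._mask(RNG.random((2, 4, 4)) < 0.5)
        assert m.dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((1, 2, 4))
        b = np.zeros((1, 2, 4))
        a[0, 0] = 1
        b[0, 1] = 1
        assert m.dice(self._mask(a), self._mask(b)) == 0.0

    def test_half_overlap_arithmetic(self):
        a = np.zeros((1, 1, 8))
        b = np.zeros((1, 1, 8))
        a[0, 0, :4] = 1
        b[0, 0, 2:6] = 1
        assert m.dice(self._mask(a), self._mask(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        z = self._mask(np.zeros((1, 2, 2)))
        assert m.dice(z, z) == 1.0

    def test_non_binary_rejected(self):
        a = Volume(np.full((1, 2, 2), 2.0), (1, 1, 1), modality="MASK")
        with pytest.raises(ValueError, match="binary"):
            m.dice(a, a)


def _dose_pair(seed, shape=(6, 12, 12), spacing=(2.0, 1.5, 1.5),
               noise=0.5, prescription=45.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 1.2, shape) * prescription
    ref = Volume(base, spacing, modality="DOSE")
    ev = Volume(base + rng.normal(0.0, noise, shape), spacing, modality="DOSE")
    return m.DoseGrid(ref, prescription), m.DoseGrid(ev, prescription)


class TestGamma:
    def test_identical_doses_give_zero_gamma(self):
        ref, _ = _dose_pair(1)
        gmap = m.gamma_index(ref, ref)
        assert np.all(gmap.gamma.data[gmap.evaluated_mask] == 0.0)
        assert m.gamma_passing_rate(gmap) == 100.0

    def test_uniform_offset_of_exactly_delta_d(self):
        """On a spatially uniform field no displacement can reduce the dose
        term, so a +dD offset gives gamma == 1 everywhere."""
        shape, presc = (6, 10, 10), 45.0
        ref = m.DoseGrid(Volume(np.full(shape, 30.0), (2, 2, 2),
                                modality="DOSE"), presc)
        dd = 0.01 * presc
        ev = m.DoseGrid(Volume(np.full(shape, 30.0 + dd), (2, 2, 2),
                               modality="DOSE"), presc)
        gmap = m.gamma_index(ref, ev)
        assert np.allclose(gmap.gamma.data[gmap.evaluated_mask], 1.0,
                           atol=1e-12)
        off = m.DoseGrid(Volume(np.full(shape, 30.0 + 1.5 * dd), (2, 2, 2),
                                modality="DOSE"), presc)
        assert m.gamma_passing_rate(m.gamma_index(ref, off)) == 0.0

    def test_passing_rate_boundary_is_inclusive(self):
        """gamma <= 1 passes: [0.2, 0.9, 1.0, 1.1] -> 75%."""
        g = np.array([0.2, 0.9, 1.0, 1.1]).reshape(1, 1, 4)
        gmap = GammaMap(Volume(g, (1, 1, 1), modality="DOSE"),
                        np.ones_like(g, dtype=bool), m.GammaParams())
        assert m.gamma_passing_rate(gmap) == pytest.approx(75.0)

    def test_matches_brute_force_oracle(self):
        """Exhaustive separable-interpolation search over the identical
        lattice agrees at every voxel (small smoke version of the full
        equivalence check)."""
        for seed in range(5):
            ref, ev = _dose_pair(seed, noise=0.7)
            gmap = m.gamma_index(ref, ev, m.GammaParams(cutoff_fraction=0.10))
            oracle = gamma_brute_force(ref.volume.data, ev.volume.data,
                                       ref.volume.spacing, ref.prescription_gy)
            mask = gmap.evaluated_mask
            assert np.max(np.abs(gmap.gamma.data[mask] - oracle[mask])) < 1e-9

    def test_anti_monotone_in_criteria(self):
        """Loosening (dose_diff, dta) never decreases the passing rate."""
        ref, ev = _dose_pair(7, noise=0.6)
        base = m.gamma_passing_rate(m.gamma_index(ref, ev, m.GammaParams(
            dose_diff_pct=1.0, dta_mm=1.0)))
        for dd, dta in [(2.0, 1.0), (1.0, 2.0), (3.0, 3.0)]:
            loose = m.gamma_passing_rate(m.gamma_index(ref, ev, m.GammaParams(
                dose_diff_pct=dd, dta_mm=dta)))
            assert loose >= base

    def test_high_dose_cutoff_is_a_proper_subset(self):
        ref, ev = _dose_pair(9)
        gmap = m.gamma_index(ref, ev, m.GammaParams(cutoff_fraction=0.10))
        high = np.asarray(ref.volume.data) >= 0.60 * ref.prescription_gy
        assert 0 < (gmap.evaluated_mask & high).sum() < gmap.evaluated_mask.sum()
        m.gamma_passing_rate(gmap, cutoff_fraction=0.60)  # subset GPR defined
        with pytest.raises(ValueError, match="below"):
            m.gamma_passing_rate(gmap, cutoff_fraction=0.05)

    def test_grid_mismatch_and_empty_cutoff_rejected(self):
        ref, ev = _dose_pair(3)
        other = m.DoseGrid(Volume(np.zeros((6, 12, 13)), (2, 1.5, 1.5),
                                  modality="DOSE"), 45.0)
        with pytest.raises(ValueError, match="grid"):
            m.gamma_index(ref, other)
        low = m.DoseGrid(ref.volume.with_data(0.01 * np.asarray(ref.volume.data)),
                         45.0)
        with pytest.raises(ValueError, match="cut-off"):
            m.gamma_index(low, ev)

    def test_voxel_centre_mode(self):
        """Non-interpolated search restricts displacements to voxel centres
        and therefore never beats the interpolated gamma."""
        ref, ev = _dose_pair(11, noise=0.8)
        interp = m.gamma_index(ref, ev, m.GammaParams())
        coarse = m.gamma_index(ref, ev, m.GammaParams(interpolate=False))
        mask = interp.evaluated_mask
        assert np.all(coarse.gamma.data[mask] >= interp.gamma.data[mask] - 1e-12)


class TestPairedTTest:
    def test_symmetric_differences_give_zero_t(self):
        r = m.paired_t_test([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_textbook_arithmetic(self):
        r = m.paired_t_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert r.t_statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        assert r.degrees_of_freedom == 2

    def test_matches_scipy_on_seeded_trials(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.normal(0.3, 1.0, n)
            y = rng.normal(0.0, 1.0, n)
            ours = m.paired_t_test(x, y)
            ref = stats.ttest_rel(x, y)
            assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            m.paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            m.paired_t_test([1.0], [0.0])
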