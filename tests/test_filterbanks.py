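"""Kernel-family contracts: zero-mean derivative kernels, quadrature
selectivity, lobe geometry, orientation covariance, scale monotonicity."""

import numpy as np
import pytest

from texshape._conv import conv2
from texshape.filterbanks import (FilterBankSpec, gabor_sigma, make_bipole_lobes,
                                  make_dog_kernel, make_first_derivative_bank,
                                  make_gabor_bank, make_it_integration_bank,
                                  make_second_derivative_bank)


class TestSpec:
    def test_orientation_grid_linear_on_half_circle(self, std_spec):
        th = std_spec.orientations
        assert len(th) == std_spec.n_orientations
        assert th[0] == 0.0 and th[-1] < np.pi
        assert np.allclose(np.diff(th), np.pi / std_spec.n_orientations)

    def test_frequency_grid_logarithmic(self, std_spec):
        fr = std_spec.frequencies
        assert np.allclose(np.diff(np.log(fr)), np.log(fr[1] / fr[0]))

    @pytest.mark.parametrize("kw", [dict(n_orientations=1),
                                    dict(freq_min=0.3, freq_max=0.2),
                                    dict(freq_min=-0.1)])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            FilterBankSpec(**kw)


class TestGabor:
    def test_odd_kernel_sums_to_zero_even_dc_corrected(self, small_spec):
        bank = make_gabor_bank(small_spec)
        for even, odd in bank.kernels.values():
            assert abs(odd.weights.sum()) < 1e-6
            assert abs(even.weights.sum()) < 1e-6

    def test_orientation_is_axial(self, small_spec):
        """A kernel at theta equals the kernel rebuilt at theta + pi."""
        bank = make_gabor_bank(small_spec)
        yy, xx = np.mgrid[0:9, 0:9]
        # axial identity follows from cos(-x)=cos(x); check even kernel
        # symmetry under point reflection through the center instead
        for even, _ in bank.kernels.values():
            assert np.allclose(even.weights, even.weights[::-1, ::-1], atol=1e-12)

    def test_quadrature_orientation_selectivity(self, make_grating):
        """Amplitude to a matched grating beats the orthogonal one > 5x
        (brute-force convolution oracle on a 64x64 grating)."""
        spec = FilterBankSpec(n_orientations=2, n_frequencies=1,
                              freq_min=0.125, freq_max=0.25)
        bank = make_gabor_bank(spec)
        theta0 = 0.0
        img = make_grating(64, theta0, 0.125)
        even, odd = bank.kernels[(0, 0)]
        amp_match = np.hypot(conv2(img, even.weights), conv2(img, odd.weights))
        even2, odd2 = bank.kernels[(1, 0)]  # theta0 + pi/2
        amp_orth = np.hypot(conv2(img, even2.weights), conv2(img, odd2.weights))
        inner = (slice(16, 48),) * 2
        assert amp_match[inner].mean() > 5 * amp_orth[inner].mean()

    def test_truncated_support_rejected(self, small_spec):
        with pytest.raises(ValueError):
            make_gabor_bank(small_spec, support_half=2)


class TestBipole:
    def test_each_lobe_unit_sum_nonnegative(self, small_spec):
        bank = make_bipole_lobes(small_spec)
        for l1, l2 in bank.kernels.values():
            for lobe in (l1, l2):
                assert lobe.weights.min() >= 0
                assert abs(lobe.weights.sum() - 1.0) < 1e-9

    def test_horizontal_pair_centers_differ_only_in_x(self, small_spec):
        bank = make_bipole_lobes(small_spec)
        l1, l2 = bank.kernels[(0, 0)]  # theta = 0
        c1 = np.array(np.unravel_index(np.argmax(l1.weights), l1.weights.shape))
        c2 = np.array(np.unravel_index(np.argmax(l2.weights), l2.weights.shape))
        assert c1[0] == c2[0]      # same row
        assert c1[1] != c2[1]      # different column

    def test_lobes_mirror_through_center(self, small_spec):
        bank = make_bipole_lobes(small_spec)
        for l1, l2 in bank.kernels.values():
            assert np.allclose(l1.weights, l2.weights[::-1, ::-1], atol=1e-12)

    def test_overlapping_lobes_rejected(self):
        spec = FilterBankSpec(n_orientations=2, n_frequencies=1,
                              freq_min=0.1, freq_max=0.2, lobe_separation=0.05)
        with pytest.raises(ValueError, match="overlap"):
            make_bipole_lobes(spec)


class TestDerivativeKernels:
    @pytest.fixture(params=["second", "first"])
    def bank(self, request, small_spec):
        if request.param == "second":
            return make_second_derivative_bank(small_spec)
        return make_first_derivative_bank(small_spec)

    def test_zero_total_weight(self, bank):
        for kern in bank.kernels.values():
            assert abs(kern.weights.sum()) < 1e-6

    def test_annihilates_constants(self, bank):
        img = np.full((32, 32), 0.7)
        for kern in bank.kernels.values():
            assert np.abs(conv2(img, kern.weights)).max() < 1e-8

    def test_oriented_line_selectivity(self, small_spec):
        """Second-derivative kernel responds more to a line along its axis
        than to the perpendicular line (convolution oracle)."""
        bank = make_second_derivative_bank(small_spec)
        img_h = np.zeros((48, 48)); img_h[24, :] = 1.0
        img_v = np.zeros((48, 48)); img_v[:, 24] = 1.0
        kern = bank.kernels[(0, 1)].weights  # theta = 0 (horizontal stripes)
        assert np.abs(conv2(img_h, kern)).max() > np.abs(conv2(img_v, kern)).max()

    def test_first_derivative_sign_flips_with_step_polarity(self, small_spec):
        bank = make_first_derivative_bank(small_spec)
        step = np.zeros((48, 48)); step[:, 24:] = 1.0  # left-dark/right-bright
        # theta=pi/2 -> polarity direction phi = pi: responds positively to
        # activity increasing leftward, so this step drives it negative
        kern = bank.kernels[(2, 1)].weights
        r = conv2(step, kern)[24, 24]
        r_flipped = conv2(step[:, ::-1], kern)[24, 24]
        assert r < 0 < r_flipped
        assert np.isclose(r, -r_flipped, rtol=1e-6)


class TestDoG:
    def test_zero_sum_and_isotropy(self):
        dog = make_dog_kernel(1.5, 3.0)
        w = dog.weights
        assert abs(w.sum()) < 1e-9
        assert np.allclose(w, w.T)
        assert np.allclose(w, np.rot90(w))

    def test_impulse_response_is_center_minus_surround(self):
        """Closed form at the origin: center amplitude - surround amplitude."""
        dog = make_dog_kernel(1.5, 3.0)
        img = np.zeros((21, 21)); img[10, 10] = 1.0
        assert np.isclose(conv2(img, dog.weights)[10, 10],
                          dog.weights[dog.center[0], dog.center[1]])

    def test_requires_center_smaller_than_surround(self):
        with pytest.raises(ValueError):
            make_dog_kernel(3.0, 1.5)


class TestITBank:
    @pytest.fixture
    def it_bank(self):
        spec = FilterBankSpec(n_orientations=4, n_frequencies=1,
                              freq_min=0.02, freq_max=0.05,
                              sigmoid_sharpness=0.3)
        return make_it_integration_bank(spec, sigma_dir=20, perp_ratio=0.3)

    def test_sign_contract(self, it_bank):
        for pos, neg in it_bank.kernels.values():
            assert pos.weights.min() >= 0
            assert neg.weights.max() <= 0

    def test_zero_sharpness_limit_recovers_half_gaussian(self):
        """As sharpness -> 0 the sigmoid -> 1/2: each normalized lobe tends
        to the normalized untruncated Gaussian."""
        mk = lambda s: make_it_integration_bank(
            FilterBankSpec(4, 1, 0.02, 0.05, sigmoid_sharpness=s),
            sigma_dir=15, perp_ratio=0.5)
        soft = mk(1e-6).kernels[(0, 0)][0].weights
        assert np.allclose(soft, soft[::-1, ::-1], atol=1e-5)  # symmetric again

    def test_requires_positive_sharpness(self):
        spec = FilterBankSpec(4, 1, 0.02, 0.05, sigmoid_sharpness=0.0)
        with pytest.raises(ValueError):
            make_it_integration_bank(spec)

    def test_dipole_asymmetry(self, it_bank):
        """Signed pair prefers a +/- dipole ordered along the integration
        direction over the reversed one (convolution oracle)."""
        pos, neg = it_bank.kernels[(0, 0)]  # theta=0 -> integrates along y
        img = np.zeros((64, 64))
        img[28, 32], img[36, 32] = 1.0, -1.0   # + then - along +y
        r_fwd = np.maximum(conv2(img, pos.weights), 0).max()
        img_rev = -img
        r_rev = np.maximum(conv2(img_rev, pos.weights), 0).max()
        assert r_fwd != pytest.approx(r_rev, rel=1e-3)


class TestExports:
    def test_kernel_gallery_written(self, small_spec, tmp_path):
        from texshape.export import save_kernel_gallery
        save_kernel_gallery(tmp_path / "gallery.png", make_gabor_bank(small_spec))
        save_kernel_gallery(tmp_path / "bipole.png", make_bipole_lobes(small_spec))
        assert (tmp_path / "gallery.png").stat().st_size > 0
        assert (tmp_path / "bipole.png").stat().st_size > 0


class TestBankProperties:
    def test_orientation_covariance_on_grating(self, make_grating):
        """Rotating a grating by one orientation step moves the peak
        response to the neighboring orientation channel."""
        spec = FilterBankSpec(n_orientations=4, n_frequencies=1,
                              freq_min=0.125, freq_max=0.25)
        bank = make_gabor_bank(spec)
        step = np.pi / spec.n_orientations
        means = []
        for k, theta in enumerate([0.0, step]):
            img = make_grating(64, theta, 0.125)
            amps = []
            for i in range(4):
                even, odd = bank.kernels[(i, 0)]
                amps.append(np.hypot(conv2(img, even.weights),
                                     conv2(img, odd.weights))[16:48, 16:48].mean())
            means.append(int(np.argmax(amps)))
        assert means[1] == (means[0] + 1) % 4

    def test_kernel_support_shrinks_with_frequency(self, std_spec):
        bank = make_gabor_bank(std_spec)
        sizes = [bank.kernels[(0, j)][0].weights.shape[0]
                 for j in range(std_spec.n_frequencies)]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
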