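import numpy as np
import pytest

from irgfuse import (
    GuidedParams,
    IRGFParams,
    WienerParams,
    box_mean,
    gaussian_smooth,
    guided_filter,
    irgf,
    rgf,
    wiener_filter,
)

from oracles import box_mean_oracle, gaussian_conv_oracle, guided_oracle, wiener_oracle


class TestBoxMean:
    def test_constant_preserved(self):
        assert np.allclose(box_mean(np.full((6, 6), 3.7), 2), 3.7)

    def test_border_normalisation_by_valid_overlap(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        out = box_mean(img, 1)
        assert out[1, 1] == pytest.approx(1.0)  # 9 / 9
        assert out[0, 0] == pytest.approx(9.0 / 4.0)  # 2x2 corner window

    def test_matches_oracle(self, rng):
        img = rng.uniform(size=(10, 13))
        for r in (1, 2, 3):
            assert np.max(np.abs(box_mean(img, r) - box_mean_oracle(img, r))) < 1e-12

    def test_radius_too_large(self):
        with pytest.raises(ValueError):
            box_mean(np.ones((4, 4)), 4)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        assert np.allclose(gaussian_smooth(np.full((8, 8), 0.4), 5, 1.2), 0.4)

    def test_impulse_response_is_kernel(self):
        from irgfuse.filters import gaussian_kernel_2d

        img = np.zeros((11, 11))
        img[5, 5] = 1.0
        out = gaussian_smooth(img, 3, 1.0)
        assert np.allclose(out[4:7, 4:7], gaussian_kernel_2d(3, 1.0), atol=1e-15)

    def test_matches_brute_force_convolution(self, rng):
        img = rng.uniform(size=(5, 5))
        out = gaussian_smooth(img, 3, 1.0)
        assert np.max(np.abs(out - gaussian_conv_oracle(img, 3, 1.0))) < 1e-12

    def test_even_ksize_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.ones((4, 4)), 4, 1.0)


class TestWienerFilter:
    def test_constant_is_fixed_point(self):
        img = np.full((7, 7), 0.6)
        assert np.allclose(wiener_filter(img, WienerParams(1, 0.05)), 0.6)

    def test_small_eps_approaches_identity(self, rng):
        img = rng.uniform(size=(8, 8))
        out = wiener_filter(img, WienerParams(1, 1e-12))
        assert np.max(np.abs(out - img)) < 1e-6

    def test_matches_oracle(self, rng):
        img = rng.uniform(size=(6, 6))
        out = wiener_filter(img, WienerParams(1, 0.05))
        assert np.max(np.abs(out - wiener_oracle(img, 1, 0.05))) < 1e-12

    def test_shift_equivariance(self, rng):
        img = rng.uniform(size=(9, 9))
        p = WienerParams(2, 0.05)
        shifted = wiener_filter(img + 0.3, p)
        assert np.max(np.abs(shifted - (wiener_filter(img, p) + 0.3))) < 1e-12

    def test_output_within_window_range(self, rng):
        img = rng.uniform(size=(10, 10))
        out = wiener_filter(img, WienerParams(2, 0.05))
        from oracles import window_bounds

        for i in range(10):
            for j in range(10):
                i0, i1, j0, j1 = window_bounds(i, j, 2, 10, 10)
                patch = img[i0:i1, j0:j1]
                assert patch.min() - 1e-12 <= out[i, j] <= patch.max() + 1e-12


class TestGuidedFilter:
    def test_constant_guide_gives_double_smoothed_src(self, rng):
        src = rng.uniform(size=(8, 8))
        guide = np.full((8, 8), 0.5)
        out = guided_filter(guide, src, GuidedParams(2, 0.0025))
        expected = box_mean(box_mean(src, 2), 2)  # a == 0 everywhere
        assert np.max(np.abs(out - expected)) < 1e-12

    def test_large_epsilon_approaches_box_smoothing(self, rng):
        src = rng.uniform(size=(8, 8))
        out = guided_filter(src, src, GuidedParams(2, 1e6))
        expected = box_mean(box_mean(src, 2), 2)
        assert np.max(np.abs(out - expected)) < 1e-5

    def test_matches_oracle(self, rng):
        guide = rng.uniform(size=(8, 8))
        src = rng.uniform(size=(8, 8))
        out = guided_filter(guide, src, GuidedParams(2, 0.0025))
        assert np.max(np.abs(out - guided_oracle(guide, src, 2, 0.0025))) < 1e-10

    def test_src_shift_equivariance(self, rng):
        guide = rng.uniform(size=(8, 8))
        src = rng.uniform(size=(8, 8))
        p = GuidedParams(2, 0.01)
        shifted = guided_filter(guide, src + 0.7, p)
        assert np.max(np.abs(shifted - (guided_filter(guide, src, p) + 0.7))) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            guided_filter(np.ones((4, 4)), np.ones((5, 5)), GuidedParams())


class TestRollingGuidance:
    def test_zero_iterations_is_wiener(self, rng):
        img = rng.uniform(size=(12, 12))
        p = IRGFParams(iterations=0)
        assert np.array_equal(irgf(img, p), wiener_filter(img, p.wiener))

    def test_constant_fixed_point(self):
        img = np.full((16, 16), 0.3)
        assert np.allclose(irgf(img, IRGFParams()), 0.3, atol=1e-12)

    def test_matches_straight_line_composition(self, rng):
        img = rng.uniform(size=(16, 16))
        p = IRGFParams(sigma_s=2.0, sigma_r=0.05, iterations=4)
        h = wiener_filter(img, p.wiener)
        for _ in range(4):
            h = guided_filter(h, img, GuidedParams(2, 0.05**2))
        assert np.max(np.abs(irgf(img, p) - h)) < 1e-12

    def test_removes_texture_preserves_step_edge(self):
        # left half 0.2, right half 0.8, fine checkerboard on top of the left
        img = np.full((16, 16), 0.2)
        img[:, 8:] = 0.8
        ii, jj = np.mgrid[0:16, 0:8]
        img[:, :8] += 0.1 * ((ii + jj) % 2 * 2 - 1)
        out = irgf(img, IRGFParams(sigma_s=2.0, sigma_r=0.05, iterations=4))
        # texture attenuated: residual variation in the textured half drops
        assert np.std(out[4:12, 2:6]) < 0.6 * np.std(img[4:12, 2:6])
        # step magnitude preserved within 20%
        step_out = np.mean(out[:, 10:]) - np.mean(out[:, :6])
        assert step_out > 0.8 * 0.6

    def test_rgf_zero_iterations_is_gaussian(self, rng):
        img = rng.uniform(size=(12, 12))
        out = rgf(img, sigma_s=2.0, iterations=0)
        assert np.array_equal(out, gaussian_smooth(img, 9, 2.0))

    def test_rgf_matches_composition(self, rng):
        img = rng.uniform(size=(12, 12))
        h = gaussian_smooth(img, 9, 2.0)
        for _ in range(3):
            h = guided_filter(h, img, GuidedParams(2, 0.05**2))
        assert np.max(np.abs(rgf(img, 2.0, 0.05, 3) - h)) < 1e-12


class TestParamValidation:
    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: WienerParams(0, 0.05),
            lambda: WienerParams(3, 0.0),
            lambda: GuidedParams(0, 0.01),
            lambda: IRGFParams(sigma_s=-1.0),
            lambda: IRGFParams(iterations=-1),
        ],
    )
    def test_invalid_params_rejected(self, ctor):
        with pytest.raises(ValueError):
            ctor()
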