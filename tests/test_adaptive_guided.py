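import numpy as np
import pytest

from oracles import guided_filter_oracle
from ramanpc.adaptive_guided import (
    EPS_FLOOR,
    PUBLISHED_COEFFICIENTS,
    AdaptiveCoefficients,
    FitDataset,
    GuidedFilterParams,
    adaptive_params,
    fit_coefficients,
    guided_filter,
    summarize_sigma2,
)
from ramanpc.peak_image import VarianceMap


class TestGuidedFilter:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 120.0)
        params = GuidedFilterParams.from_radius(2, 0.12)
        np.testing.assert_allclose(guided_filter(img, params), img, atol=1e-9)

    def test_eps_to_zero_recovers_input(self, rng):
        img = rng.uniform(0, 255, (12, 12))
        params = GuidedFilterParams.from_radius(1, 1e-12)
        np.testing.assert_allclose(guided_filter(img, params), img, atol=1e-6)

    @pytest.mark.parametrize("r", [1, 2, 3])
    @pytest.mark.parametrize("eps", [0.01, 0.12])
    def test_matches_bruteforce_oracle(self, rng, r, eps):
        img = rng.uniform(0, 255, (16, 16))
        params = GuidedFilterParams.from_radius(r, eps)
        np.testing.assert_allclose(
            guided_filter(img, params), guided_filter_oracle(img, r, eps),
            atol=1e-9,
        )

    def test_output_within_input_range(self, rng):
        img = rng.uniform(50, 200, (20, 20))
        params = GuidedFilterParams.from_radius(3, 0.05)
        out = guided_filter(img, params)
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9

    def test_image_smaller_than_window_errors(self):
        params = GuidedFilterParams.from_radius(3, 0.1)
        with pytest.raises(ValueError):
            guided_filter(np.zeros((5, 5)), params)

    def test_rgb_applied_per_channel(self, rng):
        img = rng.uniform(0, 255, (10, 10, 3))
        params = GuidedFilterParams.from_radius(1, 0.1)
        out = guided_filter(img, params)
        assert out.shape == img.shape
        for c in range(3):
            np.testing.assert_allclose(out[..., c],
                                       guided_filter(img[..., c], params))


class TestWindowRule:
    @pytest.mark.parametrize("omega,width", [
        (7.2781, 7), (3.1181, 3), (2.0, 3), (0.5, 3), (5.6, 5), (6.7, 7),
    ])
    def test_width_from_omega(self, omega, width):
        assert GuidedFilterParams(omega=omega, eps=0.1).width == width

    def test_radius(self):
        assert GuidedFilterParams(omega=7.2781, eps=0.1).r == 3

    def test_positive_eps_required(self):
        with pytest.raises(ValueError):
            GuidedFilterParams(omega=3.0, eps=0.0)


class TestAdaptiveParams:
    def test_printed_intercepts(self):
        omega, eps = PUBLISHED_COEFFICIENTS.predict(0, 0, 0)
        assert omega == 3.1181
        assert eps == 44.2304

    def test_hand_arithmetic_example(self):
        p = adaptive_params(400, 100, 2000.0)
        assert p.omega == pytest.approx(7.2781, abs=1e-10)
        assert p.eps_raw == pytest.approx(24.2504, abs=1e-10)
        assert p.width == 7
        assert p.r == 3

    def test_eps_rescaled_to_unit_range(self):
        p = adaptive_params(400, 100, 2000.0)
        assert p.eps == pytest.approx(24.2504 / 255.0**2)

    def test_eps_floor(self):
        coef = AdaptiveCoefficients(a1=0, b1=0, c1=0, d1=5,
                                    a2=0, b2=0, c2=0, d2=-10.0)
        assert adaptive_params(10, 0, 0.0, coef).eps == EPS_FLOOR

    def test_n2_exceeding_n1_rejected(self):
        with pytest.raises(ValueError):
            adaptive_params(10, 11, 0.0)

    def test_affine_in_each_argument(self):
        f = PUBLISHED_COEFFICIENTS.predict
        base = np.array(f(100, 50, 500.0))
        d_n1 = (np.array(f(101, 50, 500.0)) - base)
        d_n2 = (np.array(f(100, 51, 500.0)) - base)
        d_s2 = (np.array(f(100, 50, 501.0)) - base)
        np.testing.assert_allclose(d_n1, [0.0113, -0.0797], atol=1e-12)
        np.testing.assert_allclose(d_n2, [-0.0056, 0.1210], atol=1e-12)
        np.testing.assert_allclose(d_s2, [0.0001, -0.0001], atol=1e-12)


class TestFitCoefficients:
    @staticmethod
    def _dataset(rng, coef, n, noise=0.0):
        n1 = rng.integers(50, 500, n).astype(float)
        n2 = np.minimum(rng.integers(0, 400, n).astype(float), n1)
        s2 = rng.uniform(0, 5000, n)
        omega, eps = np.array([coef.predict(a, b, c)
                               for a, b, c in zip(n1, n2, s2)]).T
        if noise:
            omega = omega + rng.normal(0, noise, n)
            eps = eps + rng.normal(0, noise, n)
        return FitDataset(n1=n1, n2=n2, sigma2=s2, omega=omega, eps=eps)

    def test_exact_recovery_noise_free(self, rng):
        truth = AdaptiveCoefficients(a1=0.02, b1=-0.01, c1=3e-4, d1=2.5,
                                     a2=-0.08, b2=0.12, c2=-1e-4, d2=44.0)
        fit = fit_coefficients(self._dataset(rng, truth, 10))
        for name in vars(truth):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name),
                                                       abs=1e-8)

    def test_three_rows_error(self, rng):
        ds = self._dataset(rng, PUBLISHED_COEFFICIENTS, 3)
        with pytest.raises(ValueError):
            fit_coefficients(ds)

    def test_duplicated_row_rank_deficient_warns(self):
        ds = FitDataset(n1=np.full(10, 100.0), n2=np.full(10, 40.0),
                        sigma2=np.full(10, 500.0), omega=np.full(10, 5.0),
                        eps=np.full(10, 30.0))
        with pytest.warns(UserWarning, match="rank"):
            fit = fit_coefficients(ds)
        # minimum-norm solution still reproduces the duplicated observation
        assert fit.predict(100, 40, 500.0)[0] == pytest.approx(5.0)
        assert fit.predict(100, 40, 500.0)[1] == pytest.approx(30.0)

    def test_n2_greater_than_n1_rejected(self):
        with pytest.raises(ValueError):
            FitDataset(n1=[10.0], n2=[11.0], sigma2=[0.0], omega=[3.0],
                       eps=[40.0])


class TestSummarizeSigma2:
    def test_all_zeros(self):
        assert summarize_sigma2(VarianceMap(np.zeros((3, 3)))) == 0.0

    def test_mean_mode(self):
        vm = VarianceMap(np.array([[0.0, 2000.0]]))
        assert summarize_sigma2(vm) == 1000.0

    def test_max_mode(self):
        vm = VarianceMap(np.array([[0.0, 2000.0]]))
        assert summarize_sigma2(vm, "max") == 2000.0

    def test_median_mode(self):
        vm = VarianceMap(np.array([[0.0, 10.0, 2000.0]]))
        assert summarize_sigma2(vm, "median") == 10.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            summarize_sigma2(VarianceMap(np.ones((2, 2))), "mode")
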