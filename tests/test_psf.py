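import math

import numpy as np
import pytest

from sgpdeconv.psf import (
    GaussianPSFParams,
    PSFGeometryError,
    PSFParameterError,
    ProfileFitError,
    STEDPSFParams,
    estimate_gaussian_sigma,
    estimate_saturation,
    fwhm_from_sigma,
    gaussian_psf,
    sigma_from_fwhm,
    sted_fwhm,
    sted_lorentz_exponent_for_fwhm,
    sted_psf,
)


class TestGaussianPSF:
    def test_value_ratio_at_one_sigma(self):
        # pixel size = sigma so the ratio h(sigma)/h(0) falls on the grid
        k = gaussian_psf(GaussianPSFParams(93.0), (5, 5), (93.0, 93.0), "peak_preserving")
        c = k.center
        assert k.values[c[0], c[1] + 1] / k.values[c] == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    def test_fwhm_of_confocal_sigma(self):
        # sigma_r = 93 nm corresponds to the ~220 nm confocal FWHM
        assert fwhm_from_sigma(93.0) == pytest.approx(219.0, abs=0.05)
        assert sigma_from_fwhm(220.0) == pytest.approx(93.43, abs=0.005)

    def test_fwhm_sigma_round_trip(self):
        assert sigma_from_fwhm(fwhm_from_sigma(93.0)) == pytest.approx(93.0, rel=1e-12)
        assert fwhm_from_sigma(1.0) == pytest.approx(2.35482, abs=1e-5)

    def test_sum_to_one_normalization(self):
        k = gaussian_psf(GaussianPSFParams(93.0), (21, 21), (20.0, 20.0))
        assert k.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_3d_kernel_axial_gaussian(self):
        k = gaussian_psf(
            GaussianPSFParams(93.0, sigma_z=200.0), (5, 5, 5), (200.0, 93.0, 93.0),
            "peak_preserving",
        )
        c = k.center
        assert k.values[c[0] + 1, c[1], c[2]] / k.values[c] == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    @pytest.mark.parametrize("shape", [(4, 5), (5, 4), (0, 5)])
    def test_even_dims_rejected(self, shape):
        with pytest.raises(PSFGeometryError):
            gaussian_psf(GaussianPSFParams(93.0), shape, (20.0, 20.0))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(PSFParameterError):
            GaussianPSFParams(-1.0)
        with pytest.raises(PSFParameterError):
            GaussianPSFParams(93.0, sigma_z=0.0)


class TestSTEDPSF:
    def test_zero_saturation_equals_confocal(self):
        g = gaussian_psf(GaussianPSFParams(93.0), (21, 21), (20.0, 20.0), "peak_preserving")
        s = sted_psf(
            STEDPSFParams(93.0, psi=3.22e-3, saturation=0.0),
            (21, 21), (20.0, 20.0), "peak_preserving",
        )
        np.testing.assert_array_equal(g.values, s.values)

    def test_peak_invariant_in_saturation(self):
        kwargs = dict(shape=(21, 21), pixel_size=(20.0, 20.0), mode="peak_preserving")
        k0 = sted_psf(STEDPSFParams(93.0, 3.22e-3, 0.0), **kwargs)
        k7 = sted_psf(STEDPSFParams(93.0, 3.22e-3, 7.0), **kwargs)
        assert k7.peak == k0.peak

    def test_lorentzian_suppression_value(self):
        # at r = 100 nm with saturation 7, psi = 3.22e-3: 1/(1 + 7*0.322^2)
        params = STEDPSFParams(93.0, 3.22e-3, 7.0)
        k = sted_psf(params, (5, 5), (100.0, 100.0), "peak_preserving")
        g = gaussian_psf(GaussianPSFParams(93.0), (5, 5), (100.0, 100.0), "peak_preserving")
        c = k.center
        ratio = k.values[c[0], c[1] + 1] / g.values[c[0], c[1] + 1]
        assert ratio == pytest.approx(1.0 / (1.0 + 7.0 * 0.322**2), rel=1e-6)

    def test_fwhm_non_increasing_in_saturation(self):
        fwhms = [
            sted_fwhm(STEDPSFParams(93.0, 3.22e-3, s)) for s in (1e-12, 1.0, 3.0, 7.0)
        ]
        assert all(a >= b for a, b in zip(fwhms, fwhms[1:]))
        assert fwhms[0] == pytest.approx(fwhm_from_sigma(93.0), rel=1e-3)

    def test_exponent_calibration_hits_target_fwhm(self):
        p = sted_lorentz_exponent_for_fwhm(93.0, 3.22e-3, 7.0, 100.0)
        assert sted_fwhm(
            STEDPSFParams(93.0, 3.22e-3, 7.0, lorentz_exponent=p)
        ) == pytest.approx(100.0, abs=1e-6)

    def test_negative_parameters_rejected(self):
        with pytest.raises(PSFParameterError):
            STEDPSFParams(93.0, -1e-3, 7.0)
        with pytest.raises(PSFParameterError):
            STEDPSFParams(93.0, 3.22e-3, -0.1)


class TestKernelInvariants:
    @pytest.mark.parametrize(
        "kernel",
        [
            gaussian_psf(GaussianPSFParams(93.0), (15, 11), (20.0, 25.0)),
            sted_psf(STEDPSFParams(93.0, 3.22e-3, 7.0), (15, 15), (20.0, 20.0)),
        ],
        ids=["gaussian", "sted"],
    )
    def test_nonnegative_and_reflection_symmetric(self, kernel):
        v = kernel.values
        assert np.all(v >= 0)
        for axis in range(v.ndim):
            np.testing.assert_allclose(v, np.flip(v, axis=axis), atol=1e-15)

    def test_normalization_preserves_shape(self):
        k = gaussian_psf(GaussianPSFParams(93.0), (15, 15), (20.0, 20.0), "peak_preserving")
        n = k.normalized()
        ratio = k.values / n.values
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-12)


class TestProfileEstimation:
    u = np.arange(-600.0, 601.0, 20.0)

    def test_noiseless_sigma_recovery(self):
        profile = 500.0 * np.exp(-self.u**2 / (2 * 93.0**2)) + 20.0
        sigma, diag = estimate_gaussian_sigma(self.u, profile)
        assert sigma == pytest.approx(93.0, rel=1e-6)
        assert diag["residual_norm"] < 1e-6

    def test_flat_profile_is_a_fit_error(self):
        with pytest.raises(ProfileFitError):
            estimate_gaussian_sigma(self.u, np.full_like(self.u, 7.0))
        with pytest.raises(ProfileFitError):
            estimate_gaussian_sigma(self.u, np.zeros_like(self.u))

    def test_noisy_sigma_recovery_within_5_percent(self):
        # acceptance-grade parameter recovery: Poisson noise at ~500-count peak
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            noisy = rng.poisson(
                500.0 * np.exp(-self.u**2 / (2 * 93.0**2)) + 20.0
            ).astype(float)
            sigma, _ = estimate_gaussian_sigma(self.u, noisy)
            errs.append(abs(sigma - 93.0) / 93.0)
        assert max(errs) < 0.05

    def test_noiseless_saturation_recovery(self):
        profile = 500.0 * np.exp(-self.u**2 / (2 * 93.0**2)) / (
            1.0 + 7.0 * (3.22e-3 * self.u) ** 2
        ) + 20.0
        sat, _ = estimate_saturation(self.u, profile, 93.0, 3.22e-3)
        assert sat == pytest.approx(7.0, rel=1e-4)

    def test_confocal_limit_saturation_zero(self):
        profile = 500.0 * np.exp(-self.u**2 / (2 * 93.0**2)) + 20.0
        sat, diag = estimate_saturation(self.u, profile, 93.0, 3.22e-3)
        assert sat == pytest.approx(0.0, abs=1e-3)

    def test_broader_than_confocal_profile_clamped_at_zero(self):
        profile = 500.0 * np.exp(-self.u**2 / (2 * 150.0**2)) + 20.0
        sat, diag = estimate_saturation(self.u, profile, 93.0, 3.22e-3)
        assert sat == 0.0
        assert diag["clamped_at_zero"]

    def test_noisy_saturation_recovery_within_10_percent(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            mean = 500.0 * np.exp(-self.u**2 / (2 * 93.0**2)) / (
                1.0 + 5.2 * (3.22e-3 * self.u) ** 2
            ) + 20.0
            noisy = rng.poisson(mean).astype(float)
            sat, _ = estimate_saturation(self.u, noisy, 93.0, 3.22e-3)
            errs.append(abs(sat - 5.2) / 5.2)
        assert np.mean(errs) < 0.10
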