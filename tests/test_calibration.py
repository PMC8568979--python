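import numpy as np
import pytest

from qlfm import PhaseSpaceViews, compute_psf
from qlfm.calibration import (
    SubapertureShifts,
    calibrate_psf,
    estimate_subaperture_shifts,
    fit_zernike,
    integrate_shifts_to_wavefront,
    _pupil_coords,
)
from qlfm.errors import CalibrationError
from qlfm.psf import PSFSimulator
from qlfm.zernike import AberrationWavefront, zernike, zernike_wavefront


@pytest.fixture(scope="module")
def bead_psf(desk_config):
    """Unaberrated PSF of a defocused bead (z = 30 um), full angular sampling."""
    return compute_psf(desk_config, [30.0], simulator=PSFSimulator(desk_config))


def _views_from_kernel(kern, config):
    return PhaseSpaceViews(views=kern.copy(), config=config)


class TestSubapertureShifts:
    def test_autocorrelation_gives_zero_shift_unit_score(self, bead_psf, desk_config):
        captured = _views_from_kernel(bead_psf.kernels[0], desk_config)
        shifts = estimate_subaperture_shifts(captured, bead_psf)
        bright = bead_psf.kernels[0].sum(axis=(2, 3)) > 1e-4 * bead_psf.kernels[0].sum()
        assert np.allclose(shifts.shifts[bright], 0.0, atol=1e-6)
        assert np.all(shifts.scores[bright] > 0.99)

    def test_uniformly_translated_views_measure_the_translation(self, bead_psf, desk_config):
        kern = bead_psf.kernels[0]
        shifted = np.roll(kern, (2, 0), axis=(2, 3))
        shifts = estimate_subaperture_shifts(_views_from_kernel(shifted, desk_config), bead_psf)
        bright = kern.sum(axis=(2, 3)) > 1e-3 * kern.sum()
        assert np.allclose(shifts.shifts[bright][:, 0], 2.0, atol=0.05)
        assert np.allclose(shifts.shifts[bright][:, 1], 0.0, atol=0.05)

    def test_uncorrelated_views_raise(self, bead_psf, desk_config, rng):
        noise = rng.random(bead_psf.kernels[0].shape) * 0.0
        with pytest.raises(CalibrationError):
            estimate_subaperture_shifts(_views_from_kernel(noise, desk_config), bead_psf)


class TestSlopeIntegration:
    def test_zero_shifts_integrate_to_flat_wavefront(self, desk_config):
        nu = nv = 13
        shifts = SubapertureShifts(
            shifts=np.zeros((nu, nv, 2)), scores=np.ones((nu, nv)), valid=np.ones((nu, nv), bool)
        )
        wf = integrate_shifts_to_wavefront(shifts, desk_config)
        assert np.all(np.abs(wf.zernike_coefficients) < 1e-9)

    def test_analytic_defocus_slopes_recover_defocus(self, desk_config):
        """Slope field generated from the analytic gradient of Noll Z4:
        the integrated wavefront's defocus coefficient is within 10% and
        dominates all other modes."""
        nu = nv = 13
        ry, rx, mask = _pupil_coords(nu, nv)
        lam = desk_config.emission_wavelength
        c4 = 0.4  # wavelengths
        h = 1e-6

        def W(y, x):
            return c4 * lam * zernike(4, np.hypot(y, x), np.arctan2(y, x))

        dWdy = (W(ry + h, rx) - W(ry - h, rx)) / (2 * h)
        dWdx = (W(ry, rx + h) - W(ry, rx - h)) / (2 * h)
        na, pitch = desk_config.objective_na, desk_config.lens_pitch_sample
        shifts = np.zeros((nu, nv, 2))
        shifts[..., 0] = -dWdy / (na * pitch)
        shifts[..., 1] = -dWdx / (na * pitch)
        field = SubapertureShifts(shifts=shifts, scores=np.ones((nu, nv)), valid=mask)
        wf = integrate_shifts_to_wavefront(field, desk_config)
        assert wf.zernike_coefficients[3] == pytest.approx(c4, rel=0.10)
        others = np.delete(wf.zernike_coefficients[:11], 3)
        assert np.all(np.abs(others) < 0.1 * c4)

    def test_integrated_surface_rederives_input_slopes(self, desk_config, rng):
        """Consistency: differentiating the zonal surface reproduces the
        input slope field up to the injected noise floor."""
        nu = nv = 13
        ry, rx, mask = _pupil_coords(nu, nv)
        lam = desk_config.emission_wavelength

        def W(y, x):
            r, t = np.hypot(y, x), np.arctan2(y, x)
            return lam * (0.3 * zernike(6, r, t) + 0.2 * zernike(4, r, t))

        h = 1e-6
        dWdy = (W(ry + h, rx) - W(ry - h, rx)) / (2 * h)
        dWdx = (W(ry, rx + h) - W(ry, rx - h)) / (2 * h)
        sigma = 0.02
        na, pitch = desk_config.objective_na, desk_config.lens_pitch_sample
        shifts = np.zeros((nu, nv, 2))
        shifts[..., 0] = -(dWdy + sigma * rng.standard_normal((nu, nv))) / (na * pitch)
        shifts[..., 1] = -(dWdx + sigma * rng.standard_normal((nu, nv))) / (na * pitch)
        field = SubapertureShifts(shifts=shifts, scores=np.ones((nu, nv)), valid=mask)
        wf = integrate_shifts_to_wavefront(field, desk_config)
        # re-differentiate the zonal surface along x
        surf = wf.pupil_phase_map * lam / (2 * np.pi)  # um
        drho = rx[0, 1] - rx[0, 0]
        resid = []
        for iu in range(nu):
            for iv in range(nv - 1):
                if np.isfinite(surf[iu, iv]) and np.isfinite(surf[iu, iv + 1]):
                    fd = (surf[iu, iv + 1] - surf[iu, iv]) / drho
                    target = 0.5 * (dWdx[iu, iv] + dWdx[iu, iv + 1])
                    resid.append(fd - target)
        rms = float(np.sqrt(np.mean(np.square(resid))))
        assert rms < 3 * sigma

    def test_sparse_valid_field_raises(self, desk_config):
        nu = nv = 13
        valid = np.zeros((nu, nv), bool)
        valid[6, 6] = True
        field = SubapertureShifts(np.zeros((nu, nv, 2)), np.ones((nu, nv)), valid)
        with pytest.raises(CalibrationError):
            integrate_shifts_to_wavefront(field, desk_config)


class TestFitZernike:
    def test_fit_round_trips_coefficients(self):
        c = np.zeros(11)
        c[5], c[10] = 0.25, -0.4
        wf = zernike_wavefront(c, pupil_samples=96)
        fit = fit_zernike(wf, 11)
        assert np.allclose(fit, c, atol=5e-3)


class TestCalibratePsf:
    def test_unaberrated_bead_is_fixed_point(self, desk_config):
        """An unaberrated synthetic frame calibrates to ~zero coefficients
        in a single iteration."""
        from qlfm.experiments import calibration_recovery_experiment

        out = calibration_recovery_experiment(
            seed=0, spherical=0.0, astigmatism=0.0, peak_counts=None
        )
        coeffs = out["result"].wavefront.zernike_coefficients
        assert np.all(np.abs(coeffs) < 1.0 / 20.0)
        assert out["iterations"] == 1

    def test_known_aberrations_recovered_quickly(self, desk_config):
        """0.5 waves spherical + 0.3 waves astigmatism: both recovered
        within 15%, phase map converged in at most 4 iterations."""
        from qlfm.experiments import calibration_recovery_experiment

        out = calibration_recovery_experiment(seed=0)
        assert out["converged"]
        assert out["iterations"] <= 4
        assert out["recovered"]["spherical"] == pytest.approx(0.5, rel=0.15)
        assert out["recovered"]["astigmatism"] == pytest.approx(0.3, rel=0.15)
        scores = out["result"].score_history
        assert all(b >= a - 1e-6 for a, b in zip(scores, scores[1:]))

    def test_poisson_noise_robustness(self, desk_config):
        """With shot noise at 1000 peak counts the coefficients stay within
        25% (seeded)."""
        from qlfm.experiments import calibration_recovery_experiment

        out = calibration_recovery_experiment(seed=3, noise=True, peak_counts=1000.0)
        assert out["recovered"]["spherical"] == pytest.approx(0.5, rel=0.25)
        assert out["recovered"]["astigmatism"] == pytest.approx(0.3, rel=0.25)
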