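"""Response estimation, spherical deconvolution, and peak extraction."""

import numpy as np
import pytest

from lowbafd import _sphere, csd, dti, dwio, phantom
from lowbafd._sphere import angle_between
from tests.conftest import make_crossing_signal, make_single_fiber_signal


class TestResponse:
    def test_recovers_axially_symmetric_kernel(self, scheme, single_fiber_response, straight_phantom, straight_maps):
        """Estimated response reproduces the generating kernel within 1%."""
        ds, _ = straight_phantom
        field, maps = straight_maps
        est = csd.estimate_response(ds, field, maps, fa_select=0.7)
        theta = np.linspace(0, np.pi / 2, 64)
        a_true = single_fiber_response.amplitude(theta)
        a_est = est.amplitude(theta)
        assert np.abs(a_est - a_true).max() < 0.01 * np.abs(a_true).max()

    def test_isotropic_phantom_has_no_response_voxels(self, scheme):
        cfg = phantom.PhantomConfig(
            grid_shape=(10, 10, 10),
            bundles=(phantom.BundleSpec(f_ic=0.0),),
            d_axial=0.8e-3,
            d_radial_extra=0.8e-3,
        )
        ds, _ = phantom.build_phantom(cfg, scheme, snr=np.inf, seed=0)
        ds = dwio.normalize_by_median_b0(ds)
        field, maps = dti.compute_scalar_maps(ds, method="wls")
        with pytest.raises(csd.CSDError):
            csd.estimate_response(ds, field, maps, fa_select=0.7)

    def test_average_is_coefficient_mean_and_reduces_noise(self, scheme, single_fiber_response):
        r = single_fiber_response
        assert np.allclose(csd.average_responses([r, r]).r_l, r.r_l)
        neg = csd.ResponseFunction(r_l=np.array([r.r_l[0], *(-r.r_l[1:])]), lmax=r.lmax)
        avg = csd.average_responses([r, neg])
        assert np.allclose(avg.r_l[1:], 0.0)
        # variance reduction: average of noisy estimates beats each one in L2
        rng = np.random.default_rng(0)
        noisy = [
            csd.ResponseFunction(r_l=r.r_l + rng.normal(0, 0.05, size=len(r.r_l)), lmax=r.lmax)
            for _ in range(8)
        ]
        avg = csd.average_responses(noisy)
        err_avg = np.linalg.norm(avg.r_l - r.r_l)
        errs = [np.linalg.norm(x.r_l - r.r_l) for x in noisy]
        assert err_avg < min(errs)

    def test_mixed_lmax_rejected(self, single_fiber_response):
        other = csd.ResponseFunction(r_l=np.array([1.0, -0.5, 0.1]), lmax=4)
        with pytest.raises(csd.CSDError):
            csd.average_responses([single_fiber_response, other])


class TestFitCSD:
    def test_single_fiber_delta_recovery(self, scheme, single_fiber_response):
        """Deconvolving the kernel rotated to n yields one peak within 2 deg."""
        n = np.array([0.3, -0.5, 0.81])
        n /= np.linalg.norm(n)
        s = make_single_fiber_signal(scheme, n)
        f, ok = csd.fit_csd(s, scheme, single_fiber_response)
        assert ok
        peaks = csd.extract_peaks(f, min_amplitude=0.15)
        assert len(peaks) == 1
        assert angle_between(peaks[0].direction, n) < 2.0

    def test_orthogonal_crossing_two_equal_peaks(self, scheme, single_fiber_response):
        n1, n2 = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
        s = make_crossing_signal(scheme, n1, n2)
        f, _ = csd.fit_csd(s, scheme, single_fiber_response)
        peaks = csd.extract_peaks(f, min_amplitude=0.15)
        assert len(peaks) == 2
        errs = sorted(
            min(angle_between(p.direction, n1), angle_between(p.direction, n2))
            for p in peaks
        )
        assert errs[-1] < 5.0
        ratio = peaks[1].amplitude / peaks[0].amplitude
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_isotropic_signal_gives_flat_fodf(self, scheme, single_fiber_response):
        comp = phantom.VoxelCompartments(csf_fraction=1.0)
        s = phantom.simulate_signal(comp, scheme, 1.0)
        f, _ = csd.fit_csd(s, scheme, single_fiber_response)
        dirs, _ = _sphere.gauss_sphere_grid()
        amps = csd.fodf_amplitude(f, dirs)
        assert amps.std() < 0.05 * abs(amps.mean())

    def test_forward_model_consistency(self, scheme, single_fiber_response):
        """A representable non-negative fODF is reproduced exactly: the
        reconvolved signal matches the input to solver precision."""
        dirs, w = _sphere.gauss_sphere_grid()
        axis = np.array([0.2, 0.4, 0.89])
        axis /= np.linalg.norm(axis)
        vals = np.exp(3.0 * (dirs @ axis) ** 2)
        B = _sphere.sh_basis(dirs, 6)
        f_true = (B * w[:, None]).T @ vals
        A = csd._forward_matrix(scheme, single_fiber_response, 6)
        s = np.zeros(scheme.n_volumes)
        s[scheme.dwi_indices] = A @ f_true
        s[scheme.b0_indices] = 1.0
        f_fit, ok = csd.fit_csd(s, scheme, single_fiber_response)
        resid = np.linalg.norm(A @ f_fit - s[scheme.dwi_indices])
        assert ok and resid < 1e-3 * np.linalg.norm(s[scheme.dwi_indices])

    def test_rotation_equivariance(self, scheme, single_fiber_response):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = _sphere.random_uniform_sphere(1, rng)[0]
            s = make_single_fiber_signal(scheme, n)
            f, _ = csd.fit_csd(s, scheme, single_fiber_response)
            peaks = csd.extract_peaks(f, min_amplitude=0.15)
            assert peaks and angle_between(peaks[0].direction, n) < 2.0

    def test_negativity_controlled_after_convergence(self, scheme, single_fiber_response):
        n = np.array([0.3, -0.5, 0.81])
        n /= np.linalg.norm(n)
        s = make_single_fiber_signal(scheme, n)
        f, ok = csd.fit_csd(s, scheme, single_fiber_response)
        assert ok
        amps = csd._constraint_basis(300, 6) @ f
        assert np.mean(amps < -0.01 * amps.max()) == 0.0


class TestAmplitudeAndPeaks:
    def test_constant_term_only(self):
        coeffs = np.zeros(28)
        coeffs[0] = 2.0
        dirs = _sphere.fibonacci_hemisphere(20)
        amps = csd.fodf_amplitude(coeffs, dirs)
        assert np.allclose(amps, 2.0 / np.sqrt(4 * np.pi))

    def test_antipodal_symmetry(self):
        rng = np.random.default_rng(1)
        coeffs = rng.normal(size=28)
        d = _sphere.random_uniform_sphere(10, rng)
        assert np.allclose(
            csd.fodf_amplitude(coeffs, d), csd.fodf_amplitude(coeffs, -d), atol=1e-12
        )

    def test_sphere_integral_matches_orthonormality(self):
        """Quadrature of the expansion over the sphere equals c0 * sqrt(4 pi)."""
        rng = np.random.default_rng(2)
        coeffs = rng.normal(size=28)
        dirs, w = _sphere.gauss_sphere_grid()
        integral = np.sum(w * csd.fodf_amplitude(coeffs, dirs))
        assert integral == pytest.approx(coeffs[0] * np.sqrt(4 * np.pi), abs=1e-6)

    def test_threshold_above_max_gives_empty_peakset(self, scheme, single_fiber_response):
        s = make_single_fiber_signal(scheme, (0.0, 0.0, 1.0))
        f, _ = csd.fit_csd(s, scheme, single_fiber_response)
        assert csd.extract_peaks(f, min_amplitude=1e6) == ()

    def test_peaks_sorted_and_unit_norm(self, scheme, single_fiber_response):
        s = make_crossing_signal(scheme, (0, 0, 1.0), (1.0, 0, 0))
        f, _ = csd.fit_csd(s, scheme, single_fiber_response)
        peaks = csd.extract_peaks(f, min_amplitude=0.0, max_peaks=5)
        amps = [p.amplitude for p in peaks]
        assert amps == sorted(amps, reverse=True)
        for p in peaks:
            assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-9)
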