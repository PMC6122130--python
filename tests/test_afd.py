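"""Radial-signal intra-axonal fraction estimator and AFD along tracts."""

import numpy as np
import pytest

from lowbafd import afd, csd, dti, dwio, phantom, tracking
from lowbafd._sphere import random_uniform_sphere


def build_afd_setup(scheme, f_ic=0.7, snr=np.inf, seed=0, grid=12):
    ds, truth = phantom.build_phantom(
        phantom.single_bundle_config(grid=grid, f_ic=f_ic), scheme, snr=snr, seed=seed
    )
    ds = dwio.normalize_by_median_b0(ds)
    field, maps = dti.compute_scalar_maps(ds, method="wls")
    comp = phantom.VoxelCompartments(
        fiber_populations=(phantom.FiberPopulation((0.0, 0.0, 1.0), 1.0, f_ic),)
    )
    resp = csd.response_from_compartments(comp, scheme)
    fodf = csd.fit_csd_field(ds, resp)
    return ds, truth, maps, fodf


class TestMostPerpendicularGradient:
    def test_exact_perpendicular_found(self, scheme_with_perp):
        gi = afd.most_perpendicular_gradient(np.array([0.0, 0.0, 1.0]), scheme_with_perp)
        g = scheme_with_perp.directions[gi]
        assert abs(g @ [0, 0, 1]) < 1e-12

    def test_never_returns_parallel_gradient(self, scheme):
        g0 = scheme.directions[scheme.dwi_indices[0]]
        gi = afd.most_perpendicular_gradient(g0, scheme)
        assert abs(scheme.directions[gi] @ g0) < 1.0

    def test_matches_exhaustive_argmin(self, scheme):
        rng = np.random.default_rng(5)
        for p in random_uniform_sphere(20, rng):
            gi = afd.most_perpendicular_gradient(p, scheme)
            dots = np.abs(scheme.directions[scheme.dwi_indices] @ p)
            assert gi == scheme.dwi_indices[int(np.argmin(dots))]


class TestIntraAxonalFraction:
    def test_closed_form_recovery_with_exact_perpendicular(self, scheme_with_perp):
        """Noise-free two-compartment phantom: ratio = f_ic + (1-f_ic)exp(-b d_r)."""
        ds, truth, maps, fodf = build_afd_setup(scheme_with_perp)
        est = afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, 0.7)
        expected = 0.7 + 0.3 * np.exp(-1000 * 0.5e-3)
        assert est.mean_fraction == pytest.approx(expected, abs=1e-4)
        assert est.n_voxels > 0

    def test_estimate_increases_with_f_ic(self, scheme_with_perp):
        """Across f_ic in {0.5..0.8} the estimator tracks the closed form."""
        means = []
        for f_ic in (0.5, 0.6, 0.7, 0.8):
            ds, truth, maps, fodf = build_afd_setup(scheme_with_perp, f_ic=f_ic, grid=10)
            est = afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, 0.6)
            expected = f_ic + (1 - f_ic) * np.exp(-0.5)
            assert est.mean_fraction == pytest.approx(expected, abs=1e-3)
            means.append(est.mean_fraction)
        assert np.all(np.diff(means) > 0)

    def test_voxel_counts_non_increasing_in_cutoff(self, scheme):
        ds, truth, maps, fodf = build_afd_setup(scheme, snr=25, seed=3)
        ests = afd.intra_axonal_fraction_sweep(ds, fodf, maps.FA, (0.7, 0.75, 0.8, 0.85))
        ns = [e.n_voxels for e in ests]
        assert len(ests) == 4
        assert all(a >= b for a, b in zip(ns[:-1], ns[1:]))

    def test_sweep_equals_repeated_estimator(self, scheme):
        ds, truth, maps, fodf = build_afd_setup(scheme, snr=25, seed=3)
        sweep = afd.intra_axonal_fraction_sweep(ds, fodf, maps.FA, (0.7, 0.8))
        for est in sweep:
            single = afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, est.fa_cutoff)
            assert single.n_voxels == est.n_voxels
            assert single.mean_fraction == pytest.approx(est.mean_fraction, abs=1e-12)

    def test_rician_floor_biases_ratio_upward(self, scheme_with_perp):
        """At SNR 20 the magnitude floor inflates the radial ratio."""
        ds0, _, maps0, fodf0 = build_afd_setup(scheme_with_perp, grid=10)
        clean = afd.estimate_intra_axonal_fraction(ds0, fodf0, maps0.FA, 0.6)
        noisy_means = []
        for seed in range(3):
            ds, _, maps, fodf = build_afd_setup(scheme_with_perp, snr=20, seed=seed, grid=10)
            est = afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, 0.6)
            noisy_means.append(est.mean_fraction)
        assert np.mean(noisy_means) > clean.mean_fraction

    def test_bad_cutoff_rejected(self, scheme):
        ds, truth, maps, fodf = build_afd_setup(scheme, grid=10)
        with pytest.raises(afd.AFDError):
            afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, 1.5)

    def test_no_selected_voxels_warns_empty(self, scheme):
        ds, truth, maps, fodf = build_afd_setup(scheme, grid=10)
        with pytest.warns(UserWarning):
            est = afd.estimate_intra_axonal_fraction(ds, fodf, maps.FA, 0.999)
        assert est.n_voxels == 0


class TestLobeIntegral:
    def test_single_lobe_equals_full_sphere_integral(self, scheme, single_fiber_response):
        from tests.conftest import make_single_fiber_signal

        f, _ = csd.fit_csd(
            make_single_fiber_signal(scheme, (0.0, 0.0, 1.0)), scheme, single_fiber_response
        )
        peaks = csd.extract_peaks(f, 0.15)
        li = afd.lobe_integral(f, peaks[0], all_peaks=peaks)
        # clipping of residual negativity makes the quadrature slightly exceed
        # the analytic full-sphere integral c0 * sqrt(4 pi)
        assert li == pytest.approx(f[0] * np.sqrt(4 * np.pi), rel=0.05)

    def test_orthogonal_lobes_split_evenly(self, scheme, single_fiber_response):
        from tests.conftest import make_crossing_signal

        f, _ = csd.fit_csd(
            make_crossing_signal(scheme, (0, 0, 1.0), (1.0, 0, 0)), scheme, single_fiber_response
        )
        peaks = csd.extract_peaks(f, 0.15)
        assert len(peaks) == 2
        l1 = afd.lobe_integral(f, peaks[0], all_peaks=peaks)
        l2 = afd.lobe_integral(f, peaks[1], all_peaks=peaks)
        total = l1 + l2
        assert l1 == pytest.approx(total / 2, rel=0.05)

    def test_zero_fodf_integrates_to_zero(self):
        f = np.zeros(28)
        peak = csd.Peak(direction=np.array([0.0, 0.0, 1.0]), amplitude=0.0)
        assert afd.lobe_integral(f, peak) == 0.0

    def test_foreign_peak_rejected(self, scheme, single_fiber_response):
        from tests.conftest import make_single_fiber_signal

        f, _ = csd.fit_csd(
            make_single_fiber_signal(scheme, (0.0, 0.0, 1.0)), scheme, single_fiber_response
        )
        peaks = csd.extract_peaks(f, 0.15)
        rogue = csd.Peak(direction=np.array([1.0, 0.0, 0.0]), amplitude=1.0)
        with pytest.raises(afd.AFDError):
            afd.lobe_integral(f, rogue, all_peaks=peaks)


class TestAFDAlongTract:
    @pytest.fixture(scope="class")
    def tract_setup(self, scheme, single_fiber_response):
        ds, truth, maps, fodf = build_afd_setup(scheme, grid=14)
        seeds = np.argwhere(truth.bundle_labels == 1)[::5]
        cfg = tracking.TrackingConfig(algorithm="det_csd", step_mm=0.2, seed=2)
        tg = tracking.track(fodf, maps, seeds, None, cfg, ds.affine)
        return ds, truth, fodf, tg

    def test_bundle_core_afd_uniform(self, tract_setup):
        ds, truth, fodf, tg = tract_setup
        vals, dirs, flagged = afd.afd_along_tract(fodf, tg, ds.affine, ds.voxel_size)
        core = np.array([vals[v] for v in vals if truth.bundle_labels[v] == 1])
        assert len(core) > 10
        assert core.std() / core.mean() < 0.10
        assert not flagged

    def test_values_in_sanity_band(self, tract_setup):
        """AFD magnitudes sit in the low single digits (histogram mode in (0, 2))."""
        ds, truth, fodf, tg = tract_setup
        vals, *_ = afd.afd_along_tract(fodf, tg, ds.affine, ds.voxel_size)
        arr = np.array(list(vals.values()))
        assert np.all(arr >= 0)
        hist, edges = np.histogram(arr[arr > 0], bins=20)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert 0.0 < mode < 2.0

    def test_two_lobe_voxel_uses_matching_lobe(self, scheme, single_fiber_response, crossing_phantom):
        """Streamlines running along one bundle pick that bundle's lobe, not
        the total fODF integral."""
        ds, truth = crossing_phantom
        field, maps = dti.compute_scalar_maps(ds, method="wls")
        fodf = csd.fit_csd_field(ds, single_fiber_response)
        crossing = [v for v, c in truth.compartments.items() if len(c.fiber_populations) == 2]
        vox = crossing[len(crossing) // 2]
        # synthetic straight streamline along z through that voxel
        center = ds.affine[:3, :3] @ np.array(vox, float) + ds.affine[:3, 3]
        z = np.arange(-3, 3.01, 0.4)
        sl = center[None, :] + z[:, None] * np.array([0.0, 0.0, 1.0])
        tg = dwio.Tractogram(streamlines=[sl])
        vals, dirs, _ = afd.afd_along_tract(fodf, tg, ds.affine, ds.voxel_size)
        peaks = csd.extract_peaks(fodf.coeffs[vox], 0.15)
        assert len(peaks) == 2
        z_peak = max(peaks, key=lambda p: abs(p.direction[2]))
        expected = afd.lobe_integral(fodf.coeffs[vox], z_peak, all_peaks=peaks)
        total = fodf.coeffs[vox][0] * np.sqrt(4 * np.pi)
        assert vals[vox] == pytest.approx(expected, rel=1e-6)
        assert vals[vox] < 0.8 * total

    def test_empty_tractogram_rejected(self, scheme, single_fiber_response):
        ds, truth, maps, fodf = build_afd_setup(scheme, grid=10)
        with pytest.raises(afd.AFDError):
            afd.afd_along_tract(fodf, dwio.Tractogram(), ds.affine, ds.voxel_size)
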