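"""Gradient schemes, the multi-compartment forward model, and phantom geometry."""

import numpy as np
import pytest

from lowbafd import phantom
from lowbafd.phantom import (
    FiberPopulation,
    GradientScheme,
    PhantomError,
    VoxelCompartments,
    add_rician_noise,
    build_phantom,
    make_half_sphere_scheme,
    simulate_signal,
)


class TestHalfSphereScheme:
    def test_study_acquisition_layout(self, scheme):
        assert scheme.n_volumes == 31
        assert len(scheme.b0_indices) == 1
        dw = scheme.directions[scheme.dwi_indices]
        assert np.allclose(scheme.b_values[scheme.dwi_indices], 1000.0)
        assert np.allclose(np.linalg.norm(dw, axis=1), 1.0, atol=1e-8)
        assert np.all(dw[:, 2] >= 0), "directions must cover a half sphere"

    def test_minimal_scheme_has_seven_entries(self):
        s = make_half_sphere_scheme(6, 1000.0, seed=1)
        assert s.n_volumes == 7

    def test_too_few_directions_rejected(self):
        with pytest.raises(PhantomError):
            make_half_sphere_scheme(5, 1000.0, seed=1)

    def test_deterministic_for_fixed_seed(self):
        a = make_half_sphere_scheme(12, 1000.0, seed=7)
        b = make_half_sphere_scheme(12, 1000.0, seed=7)
        assert np.array_equal(a.directions, b.directions)

    def test_spread_matches_long_repulsion_oracle(self):
        """Minimum pairwise (antipodally symmetric) angle is within 2 degrees
        of an independent brute-force repulsion run with 10x iterations."""

        def min_angle(v):
            d = np.abs(v @ v.T)
            np.fill_diagonal(d, 0.0)
            return np.degrees(np.arccos(np.clip(d.max(), -1, 1)))

        fast = make_half_sphere_scheme(30, 1000.0, seed=1, n_iterations=2000)
        # independent oracle: plain fixed-step projected descent, 10x budget
        rng = np.random.default_rng(1)
        v = rng.normal(size=(30, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        for _ in range(20000):
            diff = v[:, None] - v[None, :]
            summ = v[:, None] + v[None, :]
            d1 = np.linalg.norm(diff, axis=2)
            d2 = np.linalg.norm(summ, axis=2)
            np.fill_diagonal(d1, np.inf)
            np.fill_diagonal(d2, np.inf)
            f = (diff / d1[..., None] ** 3).sum(1) + (summ / d2[..., None] ** 3).sum(1)
            f -= (f * v).sum(1, keepdims=True) * v
            v = v + 1e-3 * f
            v /= np.linalg.norm(v, axis=1, keepdims=True)
        got = min_angle(fast.directions[fast.dwi_indices])
        oracle = min_angle(v)
        assert got >= oracle - 2.0


class TestSimulateSignal:
    def test_two_compartment_closed_form(self, scheme):
        """Perpendicular gradient: S/s0 = f_ic + (1 - f_ic) * exp(-b * d_r)."""
        comp = VoxelCompartments(
            fiber_populations=(FiberPopulation((0.0, 0.0, 1.0), 1.0, 0.7),)
        )
        sch = GradientScheme(
            directions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            b_values=np.array([0.0, 1000.0]),
        )
        s = simulate_signal(comp, sch, 1.0)
        assert s[0] == 1.0
        assert s[1] == pytest.approx(0.7 + 0.3 * np.exp(-0.5), abs=1e-12)

    def test_pure_csf_limit(self):
        comp = VoxelCompartments(csf_fraction=1.0)
        sch = GradientScheme(
            directions=np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            b_values=np.array([0.0, 1000.0]),
        )
        s = simulate_signal(comp, sch, 2.0)
        assert s[1] == pytest.approx(2.0 * np.exp(-3.0), rel=1e-12)

    def test_b0_returns_s0_and_range(self, scheme):
        comp = VoxelCompartments(
            fiber_populations=(FiberPopulation((0.3, 0.4, 0.87), 0.8, 0.6),),
            csf_fraction=0.2,
        )
        s = simulate_signal(comp, scheme, 500.0)
        assert np.allclose(s[scheme.b0_indices], 500.0)
        assert np.all((s > 0) & (s <= 500.0))

    def test_decay_monotone_in_axis_alignment(self, scheme):
        """Single-fiber signal decreases as |g . n| grows (noise-free)."""
        n = np.array([0.0, 0.0, 1.0])
        comp = VoxelCompartments(fiber_populations=(FiberPopulation(tuple(n), 1.0, 0.7),))
        s = simulate_signal(comp, scheme, 1.0)[scheme.dwi_indices]
        align = np.abs(scheme.directions[scheme.dwi_indices] @ n)
        order = np.argsort(align)
        assert np.all(np.diff(s[order]) <= 1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(PhantomError):
            VoxelCompartments(
                fiber_populations=(FiberPopulation((0, 0, 1.0), 0.5, 0.7),),
                csf_fraction=0.2,
            )


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        s = np.linspace(0, 10, 50)
        assert np.array_equal(add_rician_noise(s, 0.0, seed=3), s)

    def test_zero_signal_rayleigh_mean(self):
        """Noise floor: E[magnitude of pure noise] = sigma * sqrt(pi/2)."""
        out = add_rician_noise(np.zeros(100_000), 1.0, seed=4)
        assert out.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.02)

    def test_reproducible_per_seed(self):
        s = np.full(100, 5.0)
        assert np.array_equal(add_rician_noise(s, 1.0, 9), add_rician_noise(s, 1.0, 9))

    def test_negative_sigma_rejected(self):
        with pytest.raises(PhantomError):
            add_rician_noise(np.ones(3), -0.1, seed=0)


class TestBuildPhantom:
    def test_straight_bundle_directions_follow_axis(self, scheme):
        ds, truth = build_phantom(
            phantom.single_bundle_config(grid=12), scheme, snr=np.inf, seed=0
        )
        for vox in map(tuple, np.argwhere(truth.bundle_labels == 1)):
            d = truth.compartments[vox].fiber_populations[0].direction
            assert abs(abs(d[2]) - 1.0) < 1e-9

    def test_crossing_voxels_have_two_equal_populations(self, crossing_phantom):
        _, truth = crossing_phantom
        crossing = [
            c for c in truth.compartments.values() if len(c.fiber_populations) == 2
        ]
        assert len(crossing) > 0
        for c in crossing:
            assert all(p.volume_fraction == 0.5 for p in c.fiber_populations)

    def test_arc_centerline_bends_slower_than_tracking_threshold(self, scheme):
        """Consecutive tangents at 0.2 mm spacing turn far less than 60 deg."""
        _, truth = build_phantom(
            phantom.single_bundle_config(grid=24, shape="arc"), scheme, snr=np.inf, seed=0
        )
        line = truth.bundle_centerlines[0]
        t = np.diff(line, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip((t[:-1] * t[1:]).sum(1), -1, 1)))
        assert ang.max() < 60.0

    def test_mask_is_labels_plus_dilation(self, scheme):
        from scipy.ndimage import binary_dilation

        ds, truth = build_phantom(
            phantom.single_bundle_config(grid=12, mask_dilation=2), scheme, snr=np.inf, seed=0
        )
        expected = binary_dilation(truth.bundle_labels > 0, iterations=2)
        assert np.array_equal(ds.wm_mask, expected)

    def test_fraction_conservation_everywhere(self, crossing_phantom):
        _, truth = crossing_phantom
        for comp in truth.compartments.values():
            total = comp.csf_fraction + sum(p.volume_fraction for p in comp.fiber_populations)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_out_of_grid_bundle_rejected(self, scheme):
        cfg = phantom.PhantomConfig(
            grid_shape=(10, 10, 10),
            bundles=(phantom.BundleSpec(center=(50.0, 50.0, 50.0)),),
        )
        with pytest.raises(PhantomError):
            build_phantom(cfg, scheme, snr=np.inf, seed=0)

    def test_median_b0_equals_s0_then_one_after_normalization(self, scheme):
        from lowbafd import dwio

        ds, _ = build_phantom(phantom.single_bundle_config(grid=12), scheme, snr=30, seed=5)
        med = np.median(ds.signal[ds.wm_mask][:, ds.scheme.b0_indices])
        assert med == pytest.approx(phantom.S0_DEFAULT, rel=0.05)
        norm = dwio.normalize_by_median_b0(ds)
        assert np.median(norm.signal[norm.wm_mask][:, norm.scheme.b0_indices]) == 1.0
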