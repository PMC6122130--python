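import numpy as np
import pytest

from lowbafd import csd, dti, dwio, phantom

B_VALUE = 1000.0


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition: 1 b0 + 30 half-sphere directions at b = 1000."""
    return phantom.make_half_sphere_scheme(30, B_VALUE, seed=1)


@pytest.fixture(scope="session")
def scheme_with_perp():
    """Same acquisition but guaranteed to contain a gradient exactly
    perpendicular to the z axis (for closed-form radial-signal checks)."""
    base = phantom.make_half_sphere_scheme(30, B_VALUE, seed=1)
    dirs = base.directions.copy()
    dirs[1] = np.array([1.0, 0.0, 0.0])  # replace the first weighted direction
    return phantom.GradientScheme(directions=dirs, b_values=base.b_values)


@pytest.fixture(scope="session")
def single_fiber_response(scheme):
    """Analytic single-fiber response kernel for the default compartments."""
    comp = phantom.VoxelCompartments(
        fiber_populations=(phantom.FiberPopulation((0.0, 0.0, 1.0), 1.0, 0.7),)
    )
    return csd.response_from_compartments(comp, scheme)


def make_single_fiber_signal(scheme, direction, f_ic=0.7, s0=1.0):
    d = np.asarray(direction, dtype=float)
    comp = phantom.VoxelCompartments(
        fiber_populations=(phantom.FiberPopulation(tuple(d), 1.0, f_ic),)
    )
    return phantom.simulate_signal(comp, scheme, s0)


def make_crossing_signal(scheme, d1, d2, f_ic=0.7, s0=1.0):
    comp = phantom.VoxelCompartments(
        fiber_populations=(
            phantom.FiberPopulation(tuple(d1), 0.5, f_ic),
            phantom.FiberPopulation(tuple(d2), 0.5, f_ic),
        )
    )
    return phantom.simulate_signal(comp, scheme, s0)


@pytest.fixture(scope="session")
def straight_phantom(scheme):
    """Noise-free single straight bundle along z on a 16^3 grid."""
    ds, truth = phantom.build_phantom(
        phantom.single_bundle_config(grid=16), scheme, snr=np.inf, seed=0
    )
    return dwio.normalize_by_median_b0(ds), truth


@pytest.fixture(scope="session")
def straight_maps(straight_phantom):
    ds, truth = straight_phantom
    field, maps = dti.compute_scalar_maps(ds, method="wls")
    return field, maps


@pytest.fixture(scope="session")
def crossing_phantom(scheme):
    """Noise-free 90-degree crossing phantom on a 20^3 grid."""
    ds, truth = phantom.build_phantom(
        phantom.crossing_config(grid=20), scheme, snr=np.inf, seed=0
    )
    return dwio.normalize_by_median_b0(ds), truth
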