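"""Synthetic diffusion-weighted phantoms with known microstructure.

Emulates a clinical low-demand acquisition — one b0 volume plus 30 unique
diffusion-encoding directions on a half sphere at b = 1,000 s/mm², 2 mm
isotropic voxels — over multi-compartment fiber geometries whose intra-axonal
fraction, orientation and crossing structure are known exactly, so that every
downstream stage (tensor fit, spherical deconvolution, tractography, density
analysis) can be validated against ground truth.

The noise-free forward model per voxel is a sum of compartments:

    S(g, b) = s0 * [ f_csf * exp(-b * d_csf)
                     + sum_k vf_k * ( f_ic,k * exp(-b * d_ax * (g.n_k)^2)
                       + (1 - f_ic,k) * exp(-b * (d_r + (d_ax - d_r)(g.n_k)^2)) ) ]

i.e. each fiber population k (direction n_k, volume fraction vf_k) contains a
perfectly restricted "stick" of intra-axonal fraction f_ic and an axially
symmetric extra-cellular "zeppelin" sharing its orientation.  Magnitude noise
is Rician.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _sphere

# Literature-typical diffusivities (mm^2/s) and b0 intensity.
D_AXIAL = 1.7e-3
D_RADIAL_EXTRA = 0.5e-3
D_CSF = 3.0e-3
D_ISO_BACKGROUND = 0.8e-3
S0_DEFAULT = 1000.0


class PhantomError(ValueError):
    """Invalid scheme, compartment, or geometry specification."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: unit directions and b-values (s/mm²)."""

    directions: np.ndarray  # (n, 3); b0 rows are zero vectors
    b_values: np.ndarray  # (n,)

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or len(d) != len(b):
            raise PhantomError("directions must be (n, 3) matching b_values")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "b_values", b)
        norms = np.linalg.norm(d[b > 0], axis=1)
        if len(norms) and np.any(np.abs(norms - 1.0) > 1e-8):
            raise PhantomError("weighted directions must be unit vectors")
        dw = d[b > 0]
        if len(dw) > 1:
            dots = np.abs(dw @ dw.T)
            np.fill_diagonal(dots, 0.0)
            if dots.max() > 1 - 1e-6:
                raise PhantomError("weighted directions must be pairwise non-collinear")

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b_values == 0)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b_values > 0)

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @property
    def b_nominal(self) -> float:
        """The single shell b-value (requires single-shell scheme)."""
        bw = np.unique(self.b_values[self.b_values > 0])
        if len(bw) != 1:
            raise PhantomError(f"scheme is not single-shell: b = {bw}")
        return float(bw[0])


@dataclass(frozen=True)
class FiberPopulation:
    direction: np.ndarray  # unit 3-vector
    volume_fraction: float
    f_ic: float  # intra-axonal fraction within this population

    def __post_init__(self):
        n = np.asarray(self.direction, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isfinite(nn) or nn == 0:
            raise PhantomError("fiber direction must be a nonzero vector")
        object.__setattr__(self, "direction", n / nn)
        if not (0 <= self.volume_fraction <= 1 and 0 <= self.f_ic <= 1):
            raise PhantomError("volume_fraction and f_ic must lie in [0, 1]")


@dataclass(frozen=True)
class VoxelCompartments:
    """Per-voxel tissue model: fiber populations plus a free-water pool."""

    fiber_populations: tuple[FiberPopulation, ...] = ()
    csf_fraction: float = 0.0
    d_axial: float = D_AXIAL
    d_radial_extra: float = D_RADIAL_EXTRA
    d_csf: float = D_CSF

    def __post_init__(self):
        total = self.csf_fraction + sum(p.volume_fraction for p in self.fiber_populations)
        if abs(total - 1.0) > 1e-9:
            raise PhantomError(f"compartment fractions sum to {total}, expected 1")
        if not (0 <= self.d_radial_extra <= self.d_axial <= self.d_csf):
            raise PhantomError("require 0 <= d_radial_extra <= d_axial <= d_csf")


@dataclass
class PhantomGroundTruth:
    """Known microstructure: the oracle every pipeline stage is checked against."""

    compartments: dict[tuple[int, int, int], VoxelCompartments]
    bundle_labels: np.ndarray  # int grid; 0 background, k = bundle id
    bundle_centerlines: list[np.ndarray]  # ordered (m, 3) point sequences, world mm
    brain_mask: np.ndarray  # all non-background voxels

    def fiber_directions(self, voxel: tuple[int, int, int]) -> np.ndarray:
        comp = self.compartments[voxel]
        return np.array([p.direction for p in comp.fiber_populations])


@dataclass
class DWIDataset:
    """4D diffusion-weighted signal with its gradient scheme and WM mask."""

    signal: np.ndarray  # (x, y, z, n_volumes), >= 0
    scheme: GradientScheme
    voxel_size: np.ndarray  # (3,) mm
    wm_mask: np.ndarray  # bool (x, y, z)
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4 or self.signal.shape[3] != self.scheme.n_volumes:
            raise PhantomError("signal 4th dimension must match the gradient scheme")
        if self.wm_mask.shape != self.signal.shape[:3]:
            raise PhantomError("mask shape must equal the spatial signal shape")
        if np.any(self.signal < 0):
            raise PhantomError("signal must be non-negative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def b0_mean(self) -> np.ndarray:
        """Mean over b0 volumes (the acquisition has one, but be general)."""
        return self.signal[..., self.scheme.b0_indices].mean(axis=3)


# ---------------------------------------------------------------------------
# gradient scheme
# ---------------------------------------------------------------------------


def make_half_sphere_scheme(
    n_directions: int,
    b: float,
    seed: int,
    n_iterations: int = 2000,
) -> GradientScheme:
    """One b0 plus ``n_directions`` half-sphere unit vectors at b-value ``b``.

    Directions are spread by electrostatic-repulsion energy minimization with
    antipodal symmetry (each point repels both the others and their
    antipodes), then mapped to the z >= 0 hemisphere.  Deterministic for a
    fixed seed.
    """
    if n_directions < 6:
        raise PhantomError("at least 6 directions are needed for a tensor fit")
    rng = np.random.default_rng(seed)
    v = _sphere.random_uniform_sphere(n_directions, rng)
    v = _repulsion_minimize(v, n_iterations)
    v = np.where(v[:, 2:3] < 0, -v, v)  # half sphere, z >= 0
    directions = np.vstack([np.zeros(3), v])
    b_values = np.concatenate([[0.0], np.full(n_directions, float(b))])
    return GradientScheme(directions=directions, b_values=b_values)


def _repulsion_energy(v: np.ndarray) -> float:
    d1 = np.linalg.norm(v[:, None] - v[None, :], axis=2)
    d2 = np.linalg.norm(v[:, None] + v[None, :], axis=2)
    iu = np.triu_indices(len(v), 1)
    return float((1.0 / d1[iu]).sum() + (1.0 / d2[iu]).sum())


def _repulsion_minimize(v: np.ndarray, n_iterations: int) -> np.ndarray:
    """Projected-gradient descent of the antipodal Coulomb energy."""
    step = 0.05
    energy = _repulsion_energy(v)
    for _ in range(n_iterations):
        diff = v[:, None] - v[None, :]
        summ = v[:, None] + v[None, :]
        d1 = np.linalg.norm(diff, axis=2)
        d2 = np.linalg.norm(summ, axis=2)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (summ / d2[..., None] ** 3).sum(axis=1)
        force -= (force * v).sum(axis=1, keepdims=True) * v  # tangent projection
        vn = v + step * force
        vn /= np.linalg.norm(vn, axis=1, keepdims=True)
        en = _repulsion_energy(vn)
        if en < energy:
            v, energy = vn, en
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return v


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def simulate_signal(
    compartments: VoxelCompartments, scheme: GradientScheme, s0: float = S0_DEFAULT
) -> np.ndarray:
    """Noise-free multi-compartment signal for one voxel, length = scheme size."""
    if s0 <= 0:
        raise PhantomError("s0 must be positive")
    b = scheme.b_values
    s = compartments.csf_fraction * np.exp(-b * compartments.d_csf)
    for pop in compartments.fiber_populations:
        c2 = (scheme.directions @ pop.direction) ** 2
        intra = np.exp(-b * compartments.d_axial * c2)
        d_r = compartments.d_radial_extra
        extra = np.exp(-b * (d_r + (compartments.d_axial - d_r) * c2))
        s += pop.volume_fraction * (pop.f_ic * intra + (1 - pop.f_ic) * extra)
    return s0 * s


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Rician (magnitude) noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma)."""
    if sigma < 0:
        raise PhantomError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BundleSpec:
    """One fiber bundle: a straight rod or a 180-degree arc.

    ``shape`` is "straight" or "arc".  A straight bundle runs along ``axis``
    through ``center`` (voxel units); an arc lies in the x-z plane centered at
    ``center`` with radius ``arc_radius_vox``, sweeping 180 degrees.  Voxels
    within ``radius_vox`` of the centerline belong to the bundle.
    """

    shape: str = "straight"
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center: tuple[float, float, float] | None = None
    radius_vox: float = 2.5
    arc_radius_vox: float = 12.0
    f_ic: float = 0.7


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 2.0
    bundles: tuple[BundleSpec, ...] = (
        BundleSpec(shape="straight", axis=(0.0, 0.0, 1.0)),
        BundleSpec(shape="straight", axis=(1.0, 0.0, 0.0)),
    )
    mask_dilation: int = 1
    s0: float = S0_DEFAULT
    d_axial: float = D_AXIAL
    d_radial_extra: float = D_RADIAL_EXTRA
    d_iso_background: float = D_ISO_BACKGROUND
    centerline_step_mm: float = 0.2


def _bundle_centerline(spec: BundleSpec, cfg: PhantomConfig) -> np.ndarray:
    """Centerline points in world mm at ``centerline_step_mm`` spacing."""
    shape = np.asarray(cfg.grid_shape, dtype=float)
    vs = cfg.voxel_size_mm
    center_vox = np.asarray(spec.center) if spec.center is not None else (shape - 1) / 2.0
    center = center_vox * vs
    if spec.shape == "straight":
        axis = np.asarray(spec.axis, dtype=float)
        axis /= np.linalg.norm(axis)
        half = float(np.max(shape) * vs)  # long enough to cross the grid
        n = int(np.ceil(2 * half / cfg.centerline_step_mm))
        t = np.linspace(-half, half, n)
        pts = center[None, :] + t[:, None] * axis[None, :]
    elif spec.shape == "arc":
        r = spec.arc_radius_vox * vs
        n = int(np.ceil(np.pi * r / cfg.centerline_step_mm))
        ang = np.linspace(0.0, np.pi, n)
        pts = np.stack(
            [center[0] + r * np.cos(ang), np.full(n, center[1]), center[2] + r * np.sin(ang)],
            axis=1,
        )
    else:
        raise PhantomError(f"unknown bundle shape {spec.shape!r}")
    # clip to points whose voxel lies inside the grid
    vox = pts / vs
    inside = np.all((vox >= -0.5) & (vox <= shape - 0.5), axis=1)
    pts = pts[inside]
    if len(pts) < 2:
        raise PhantomError("bundle lies outside the grid")
    return pts


def build_phantom(
    config: PhantomConfig,
    scheme: GradientScheme,
    snr: float = np.inf,
    seed: int = 0,
) -> tuple[DWIDataset, PhantomGroundTruth]:
    """Build a DWI dataset plus ground truth from a bundle geometry.

    ``snr`` is defined on the b0 (snr = s0 / sigma); ``snr = inf`` is
    noise-free.  Crossing voxels (claimed by several bundles) carry one fiber
    population per bundle with equal volume fractions.  The WM mask is the
    labelled voxels dilated ``mask_dilation`` times; unlabelled mask voxels
    are isotropic.
    """
    from scipy.ndimage import binary_dilation

    nx, ny, nz = config.grid_shape
    vs = config.voxel_size_mm
    labels = np.zeros(config.grid_shape, dtype=int)
    centerlines: list[np.ndarray] = []
    # voxel centers in world mm
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * vs

    per_bundle: list[dict[tuple[int, int, int], np.ndarray]] = []
    for b_id, spec in enumerate(config.bundles, start=1):
        line = _bundle_centerline(spec, config)
        centerlines.append(line)
        tangents = np.gradient(line, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        # distance from each voxel center to the centerline
        from scipy.spatial import cKDTree

        dmin, nearest = cKDTree(line).query(centers)
        member = dmin <= spec.radius_vox * vs
        voxdirs = {}
        for flat in np.flatnonzero(member):
            vox = tuple(int(x) for x in np.unravel_index(flat, config.grid_shape))
            voxdirs[vox] = tangents[nearest[flat]]
            labels[vox] = b_id if labels[vox] == 0 else labels[vox]
        per_bundle.append(voxdirs)

    wm_mask = labels > 0
    if config.mask_dilation > 0:
        wm_mask = binary_dilation(wm_mask, iterations=config.mask_dilation)

    iso = VoxelCompartments(
        fiber_populations=(),
        csf_fraction=1.0,
        d_axial=config.d_iso_background,
        d_radial_extra=config.d_iso_background,
        d_csf=config.d_iso_background,
    )
    compartments: dict[tuple[int, int, int], VoxelCompartments] = {}
    for vox in map(tuple, np.argwhere(wm_mask)):
        owners = [
            (b_id, voxdirs[vox])
            for b_id, voxdirs in enumerate(per_bundle, start=1)
            if vox in voxdirs
        ]
        if not owners:
            compartments[vox] = iso
            continue
        vf = 1.0 / len(owners)
        pops = tuple(
            FiberPopulation(direction=d, volume_fraction=vf, f_ic=config.bundles[b_id - 1].f_ic)
            for b_id, d in owners
        )
        compartments[vox] = VoxelCompartments(
            fiber_populations=pops,
            csf_fraction=0.0,
            d_axial=config.d_axial,
            d_radial_extra=config.d_radial_extra,
        )

    signal = np.zeros(config.grid_shape + (scheme.n_volumes,))
    for vox, comp in compartments.items():
        signal[vox] = simulate_signal(comp, scheme, config.s0)
    if np.isfinite(snr):
        if snr <= 0:
            raise PhantomError("snr must be positive")
        sigma = config.s0 / snr
        noisy = add_rician_noise(signal[wm_mask], sigma, seed)
        signal[wm_mask] = noisy

    affine = np.diag([vs, vs, vs, 1.0])
    dataset = DWIDataset(
        signal=signal,
        scheme=scheme,
        voxel_size=np.full(3, vs),
        wm_mask=wm_mask,
        affine=affine,
    )
    truth = PhantomGroundTruth(
        compartments=compartments,
        bundle_labels=labels,
        bundle_centerlines=centerlines,
        brain_mask=wm_mask.copy(),
    )
    return dataset, truth


def crossing_config(
    grid: int = 40, radius_vox: float = 2.5, f_ic: float = 0.7, **kwargs
) -> PhantomConfig:
    """Two straight bundles crossing at 90 degrees (z-bundle and x-bundle)."""
    return PhantomConfig(
        grid_shape=(grid, grid, grid),
        bundles=(
            BundleSpec(shape="straight", axis=(0.0, 0.0, 1.0), radius_vox=radius_vox, f_ic=f_ic),
            BundleSpec(shape="straight", axis=(1.0, 0.0, 0.0), radius_vox=radius_vox, f_ic=f_ic),
        ),
        **kwargs,
    )


def single_bundle_config(
    grid: int = 20, radius_vox: float = 2.5, f_ic: float = 0.7, shape: str = "straight", **kwargs
) -> PhantomConfig:
    """One bundle: a straight z-rod, or a 180-degree arc in the x-z plane."""
    spec = BundleSpec(shape=shape, radius_vox=radius_vox, f_ic=f_ic,
                      arc_radius_vox=grid * 0.3)
    return PhantomConfig(grid_shape=(grid, grid, grid), bundles=(spec,), **kwargs)
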