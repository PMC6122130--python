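"""Streamline tractography: deterministic and probabilistic, DTI and CSD.

Four per-step direction rules over trilinearly interpolated fields:

* ``det_dti``  — 4th-order Runge–Kutta integration of the principal
  diffusion direction (PDD) of the interpolated tensor;
* ``prob_dti`` — direction drawn from a Watson-like concentration
  distribution about the interpolated PDD, with concentration
  kappa = kappa0 * FA / (1 - FA + eps), so dispersion shrinks as anisotropy
  grows (a simplified surrogate of PICo-style uncertainty modelling);
* ``det_csd``  — the fODF peak nearest the incoming direction, found by
  amplitude ascent on the interpolated SH coefficients;
* ``prob_csd`` — direction sampled proportionally to the interpolated fODF
  amplitude over candidates drawn in the cone of the angular threshold
  around the incoming direction (single-step sampling, a documented
  simplification of multi-step fODF path integration).

Streamlines grow bidirectionally from each seed and stop on leaving the WM
mask, FA below threshold (tensor methods), fODF amplitude below threshold
(CSD methods), turning angle above threshold, or length bounds.  Streamlines
touching a region of avoidance (ROA) are discarded whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _sphere, csd as csd_mod
from .dti import ScalarMaps, TensorField
from .csd import FODFField
from .dwio import Tractogram

ALGORITHMS = ("det_dti", "prob_dti", "det_csd", "prob_csd")


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class TrackingConfig:
    algorithm: str = "det_dti"
    step_mm: float = 0.5
    angle_max_deg: float = 60.0
    fa_min: float = 0.2
    fodf_amp_min: float = 0.15
    seeds_per_voxel: int = 1
    max_length_mm: float = 250.0
    min_length_mm: float = 10.0
    seed: int = 0
    kappa0: float = 30.0  # prob_dti concentration scale
    n_cone_samples: int = 24  # prob_csd candidate directions per step

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise TrackingError(f"algorithm must be one of {ALGORITHMS}")
        if self.step_mm <= 0 or not (0 < self.angle_max_deg <= 90) or self.seeds_per_voxel < 1:
            raise TrackingError("invalid tracking configuration")


def _trilinear(grid: np.ndarray, p_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of grid[..., C] at one continuous voxel coord."""
    shape = grid.shape[:3]
    p = np.clip(p_vox, 0.0, np.asarray(shape) - 1.000001)
    i0 = np.floor(p).astype(int)
    f = p - i0
    i1 = np.minimum(i0 + 1, np.asarray(shape) - 1)
    c = 0.0
    for dx, wx in ((0, 1 - f[0]), (1, f[0])):
        if wx == 0:
            continue
        ix = i0[0] if dx == 0 else i1[0]
        for dy, wy in ((0, 1 - f[1]), (1, f[1])):
            if wy == 0:
                continue
            iy = i0[1] if dy == 0 else i1[1]
            for dz, wz in ((0, 1 - f[2]), (1, f[2])):
                if wz == 0:
                    continue
                iz = i0[2] if dz == 0 else i1[2]
                c = c + wx * wy * wz * grid[ix, iy, iz]
    return c


class _Field:
    """Shared geometry + interpolation for one tracking run."""

    def __init__(self, mask: np.ndarray, affine: np.ndarray):
        self.mask = mask
        self.affine = affine
        self.inv = np.linalg.inv(affine)

    def to_vox(self, x_world: np.ndarray) -> np.ndarray:
        return self.inv[:3, :3] @ x_world + self.inv[:3, 3]

    def in_mask(self, x_world: np.ndarray) -> bool:
        v = np.floor(self.to_vox(x_world) + 0.5).astype(int)
        if np.any(v < 0) or np.any(v >= np.asarray(self.mask.shape)):
            return False
        return bool(self.mask[tuple(v)])


class _TensorStepper(_Field):
    def __init__(self, tensor_field: TensorField, scalar_maps: ScalarMaps, affine, config):
        super().__init__(scalar_maps.valid | (scalar_maps.FA > 0), affine)
        self.tensors = tensor_field.tensors
        self.fa = scalar_maps.FA
        self.cfg = config

    def pdd(self, x_world: np.ndarray, ref: np.ndarray | None) -> np.ndarray | None:
        v = self.to_vox(x_world)
        t6 = _trilinear(self.tensors, v)
        D = np.empty((3, 3))
        D[0, 0], D[0, 1], D[0, 2] = t6[0], t6[1], t6[2]
        D[1, 0], D[1, 1], D[1, 2] = t6[1], t6[3], t6[4]
        D[2, 0], D[2, 1], D[2, 2] = t6[2], t6[4], t6[5]
        lam, vec = np.linalg.eigh(D)
        e1 = vec[:, 2]
        if ref is not None and np.dot(e1, ref) < 0:
            e1 = -e1
        return e1

    def fa_at(self, x_world: np.ndarray) -> float:
        return float(_trilinear(self.fa, self.to_vox(x_world)))

    def initial_direction(self, x_world, rng):
        return self.pdd(x_world, None)

    def next_direction(self, x_world, incoming, rng):
        if self.fa_at(x_world) < self.cfg.fa_min:
            return None
        if self.cfg.algorithm == "det_dti":
            # RK4 on the interpolated PDD field
            h = self.cfg.step_mm
            k1 = self.pdd(x_world, incoming)
            k2 = self.pdd(x_world + 0.5 * h * k1, incoming)
            k3 = self.pdd(x_world + 0.5 * h * k2, incoming)
            k4 = self.pdd(x_world + h * k3, incoming)
            d = k1 + 2 * k2 + 2 * k3 + k4
            n = np.linalg.norm(d)
            return d / n if n > 0 else None
        # prob_dti: Watson-like sample about the PDD
        mu = self.pdd(x_world, incoming)
        fa = min(self.fa_at(x_world), 1.0 - 1e-6)
        kappa = self.cfg.kappa0 * fa / (1.0 - fa + 1e-6)
        return _sample_watson(mu, kappa, rng, toward=incoming)


def _sample_watson(mu: np.ndarray, kappa: float, rng: np.random.Generator, toward=None):
    """Draw one axis from a Watson-like density ~ exp(kappa * (mu.d)^2)."""
    for _ in range(1000):
        u = rng.uniform(-1.0, 1.0)
        if rng.uniform() < np.exp(kappa * (u * u - 1.0)):
            break
    else:  # very high kappa: accept the mode
        u = 1.0
    phi = rng.uniform(0.0, 2 * np.pi)
    r = np.sqrt(max(1.0 - u * u, 0.0))
    local = np.array([r * np.cos(phi), r * np.sin(phi), u])
    d = _sphere.rotation_to(mu) @ local
    if toward is not None and np.dot(d, toward) < 0:
        d = -d
    return d


class _FODFStepper(_Field):
    def __init__(self, fodf: FODFField, scalar_maps: ScalarMaps, affine, config):
        super().__init__(scalar_maps.valid | (scalar_maps.FA > 0), affine)
        self.coeffs = fodf.coeffs
        self.lmax = fodf.lmax
        self.cfg = config

    def coeffs_at(self, x_world):
        return _trilinear(self.coeffs, self.to_vox(x_world))

    def initial_direction(self, x_world, rng):
        f = self.coeffs_at(x_world)
        peaks = csd_mod.extract_peaks(f, self.cfg.fodf_amp_min, max_peaks=3, lmax=self.lmax)
        if not peaks:
            return None
        return peaks[0].direction

    def next_direction(self, x_world, incoming, rng):
        f = self.coeffs_at(x_world)
        if self.cfg.algorithm == "det_csd":
            # nearest peak: amplitude ascent started from the incoming direction
            d = csd_mod.refine_direction(
                f, incoming, self.lmax, scales_deg=csd_mod._REFINE_SCALES_FAST
            )
            if np.dot(d, incoming) < 0:
                d = -d
            amp = csd_mod.fodf_amplitude(f, d, self.lmax)
            return d if amp >= self.cfg.fodf_amp_min else None
        # prob_csd: amplitude-weighted sample within the angular cone
        cand = _sphere.sample_cone(
            incoming, np.radians(self.cfg.angle_max_deg), self.cfg.n_cone_samples, rng
        )
        amps = csd_mod.fodf_amplitude(f, cand, self.lmax)
        amps = np.where(amps >= self.cfg.fodf_amp_min, amps, 0.0)
        total = amps.sum()
        if total <= 0:
            return None
        return cand[rng.choice(len(cand), p=amps / total)]


def _grow(stepper, x0: np.ndarray, d0: np.ndarray, cfg: TrackingConfig, rng):
    """Grow one half-streamline; returns the list of points after x0."""
    pts = []
    x, d = x0.copy(), d0.copy()
    cos_max = np.cos(np.radians(cfg.angle_max_deg))
    max_steps = int(np.ceil(cfg.max_length_mm / cfg.step_mm))
    for _ in range(max_steps):
        d_new = stepper.next_direction(x, d, rng)
        if d_new is None:
            break
        if np.dot(d_new, d) < cos_max:
            break
        x = x + cfg.step_mm * d_new
        if not stepper.in_mask(x):
            break
        pts.append(x.copy())
        d = d_new
    return pts


def track(
    field,
    scalar_maps: ScalarMaps,
    seeds: np.ndarray,
    roas: list[np.ndarray] | None,
    config: TrackingConfig,
    affine: np.ndarray,
) -> Tractogram:
    """Reconstruct streamlines from seed voxels.

    ``field`` is a TensorField (DTI algorithms) or FODFField (CSD
    algorithms); ``seeds`` an (n, 3) integer array of voxel indices;
    ``roas`` a list of boolean exclusion masks on the same grid.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=int))
    if isinstance(field, TensorField):
        if config.algorithm not in ("det_dti", "prob_dti"):
            raise TrackingError(f"{config.algorithm} needs an FODFField")
        stepper = _TensorStepper(field, scalar_maps, affine, config)
    elif isinstance(field, FODFField):
        if config.algorithm not in ("det_csd", "prob_csd"):
            raise TrackingError(f"{config.algorithm} needs a TensorField")
        stepper = _FODFStepper(field, scalar_maps, affine, config)
    else:
        raise TrackingError("field must be a TensorField or FODFField")
    rng = np.random.default_rng(config.seed)
    probabilistic = config.algorithm.startswith("prob")
    mask_shape = scalar_maps.FA.shape

    streamlines: list[np.ndarray] = []
    seed_ids: list[int] = []
    n_skipped = 0
    for s_id, vox in enumerate(seeds):
        if np.any(vox < 0) or np.any(vox >= mask_shape) or not stepper.mask[tuple(vox)]:
            n_skipped += 1
            continue
        for rep in range(config.seeds_per_voxel):
            if probabilistic and rep > 0:
                jitter = rng.uniform(-0.5, 0.5, size=3)
            else:
                jitter = np.zeros(3)
            x0 = affine[:3, :3] @ (vox + jitter) + affine[:3, 3]
            d0 = stepper.initial_direction(x0, rng)
            if d0 is None:
                continue
            fwd = _grow(stepper, x0, d0, config, rng)
            # condition the backward half on the realized first forward step so
            # the junction at the seed also respects the angular threshold
            if fwd:
                d_first = fwd[0] - x0
                d_first /= np.linalg.norm(d_first)
            else:
                d_first = d0
            bwd = _grow(stepper, x0, -d_first, config, rng)
            pts = bwd[::-1] + [x0] + fwd
            if len(pts) < 2:
                continue
            arr = np.asarray(pts)
            length = float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())
            if not (config.min_length_mm <= length <= config.max_length_mm):
                continue
            if roas and _touches_any(arr, roas, affine):
                continue
            streamlines.append(arr)
            seed_ids.append(s_id)
    return Tractogram(streamlines=streamlines, seed_indices=seed_ids)


def _touches_any(points: np.ndarray, roas, affine) -> bool:
    from .dwio import voxel_index

    idx = voxel_index(points, affine)
    for roa in roas:
        shp = np.asarray(roa.shape)
        ok = np.all((idx >= 0) & (idx < shp), axis=1)
        if np.any(roa[tuple(idx[ok].T)]):
            return True
    return False
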