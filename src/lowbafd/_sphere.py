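"""Sphere sampling and real spherical-harmonic (SH) utilities.

Everything here works with the real, even-degree, antipodally symmetric SH
basis used for fiber orientation distribution functions (fODFs).  Basis
functions are orthonormal on the unit sphere; coefficients are ordered by
ascending degree l = 0, 2, ..., lmax and, within a degree, by order
m = -l ... l.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import roots_legendre, sph_harm_y


def n_coeffs(lmax: int) -> int:
    """Number of even-degree real SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be a non-negative even integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


@lru_cache(maxsize=None)
def sh_degrees_orders(lmax: int):
    """(l, m) index arrays for the even-degree basis up to ``lmax``."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def cart_to_sphere(dirs: np.ndarray):
    """Cartesian unit vectors -> (polar theta, azimuth phi)."""
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def sphere_to_cart(theta, phi):
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Real even-degree SH design matrix, shape (n_dirs, n_coeffs(lmax)).

    Real basis from the complex harmonics Y_l^m: sqrt(2)*Im(Y_l^|m|) for
    m < 0, Y_l^0 for m = 0, sqrt(2)*Re(Y_l^m) for m > 0.  Orthonormal, and
    antipodally symmetric because only even degrees enter.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta, phi = cart_to_sphere(dirs)
    ls, ms = sh_degrees_orders(lmax)
    # one vectorized call: broadcast (n_coef,) against (n_dirs, 1)
    y = sph_harm_y(ls[None, :], np.abs(ms)[None, :], theta[:, None], phi[:, None])
    out = np.where(
        ms[None, :] < 0,
        np.sqrt(2.0) * y.imag,
        np.where(ms[None, :] > 0, np.sqrt(2.0) * y.real, y.real),
    )
    return np.ascontiguousarray(out)


def zonal_basis(theta: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of the m = 0 (zonal) harmonics Y_l0(theta), even l only."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ls = np.arange(0, lmax + 1, 2)
    return sph_harm_y(ls[None, :], 0, theta[:, None], 0.0).real


def zonal_expand(r_l: np.ndarray, lmax: int) -> np.ndarray:
    """Embed zonal coefficients r_l into a full coefficient vector (m=0 slots)."""
    ls, ms = sh_degrees_orders(lmax)
    coeffs = np.zeros(len(ls))
    for i, rl in zip(np.flatnonzero((ms == 0)), np.asarray(r_l, dtype=float)):
        coeffs[i] = rl
    return coeffs


def kernel_multipliers(r_l: np.ndarray, lmax: int) -> np.ndarray:
    """Per-coefficient Funk–Hecke factors for spherical convolution.

    Convolving an fODF (coefficients f_lm) with an axially symmetric kernel of
    zonal coefficients r_l multiplies each f_lm by sqrt(4*pi/(2l+1)) * r_l.
    """
    ls, _ = sh_degrees_orders(lmax)
    r_of_l = {l: r for l, r in zip(range(0, lmax + 1, 2), np.asarray(r_l, dtype=float))}
    return np.array([np.sqrt(4.0 * np.pi / (2 * l + 1)) * r_of_l[l] for l in ls])


@lru_cache(maxsize=None)
def _icosphere(subdivisions: int):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    # vertex adjacency as index lists (local-maximum search on the tessellation)
    neighbors = [np.asarray(nb, dtype=int) for nb in mesh.vertex_neighbors]
    return verts, neighbors


def icosphere_vertices(subdivisions: int = 4):
    """Unit vertices and adjacency of a subdivided icosahedron (full sphere)."""
    return _icosphere(subdivisions)


@lru_cache(maxsize=None)
def hemisphere_vertices(subdivisions: int = 4):
    """Antipodally deduplicated icosphere vertices with adjacency.

    subdivisions=4 gives 2562 full-sphere vertices, hence 1281 on the
    hemisphere — the grid used for fODF peak detection.
    """
    verts, neighbors = _icosphere(subdivisions)
    eps = 1e-9
    keep = (verts[:, 2] > eps) | (
        (np.abs(verts[:, 2]) <= eps)
        & ((verts[:, 1] > eps) | ((np.abs(verts[:, 1]) <= eps) & (verts[:, 0] > 0)))
    )
    idx = np.flatnonzero(keep)
    # map every full-sphere vertex to its hemisphere representative
    rep = np.full(len(verts), -1, dtype=int)
    rep[idx] = np.arange(len(idx))
    dropped = np.flatnonzero(~keep)
    if len(dropped):
        # representative of -v is the kept vertex closest to -v (it is exactly -v)
        d = np.abs((-verts[dropped]) @ verts[idx].T)
        rep[dropped] = np.argmax(d, axis=1)
    hemi_neighbors = []
    for i in idx:
        nb = np.unique(rep[neighbors[i]])
        hemi_neighbors.append(nb[nb != rep[i]])
    return verts[idx], hemi_neighbors


@lru_cache(maxsize=None)
def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (Fibonacci lattice).

    Used as the amplitude-constraint set in constrained spherical deconvolution.
    """
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere only
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@lru_cache(maxsize=None)
def gauss_sphere_grid(n_theta: int = 24, n_phi: int = 48):
    """Product quadrature grid on the full sphere: (directions, weights).

    Gauss–Legendre in cos(theta) times trapezoid in phi; integrates spherical
    harmonics exactly up to degree min(2*n_theta - 1, n_phi - 1).  Weights sum
    to 4*pi.
    """
    x, w = roots_legendre(n_theta)
    theta = np.arccos(x)
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = sphere_to_cart(tt.ravel(), pp.ravel())
    weights = np.repeat(w, n_phi) * (2 * np.pi / n_phi)
    return dirs, weights


def random_uniform_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_cone(axis: np.ndarray, max_angle_rad: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n directions uniform (by solid angle) in the cone around ``axis``."""
    cos_max = np.cos(max_angle_rad)
    z = rng.uniform(cos_max, 1.0, size=n)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    local = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return local @ rotation_to(axis).T


def rotation_to(target: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying the +z axis onto unit vector ``target``."""
    t = np.asarray(target, dtype=float)
    t = t / np.linalg.norm(t)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, t))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, t)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def angle_between(a: np.ndarray, b: np.ndarray, antipodal: bool = True) -> float:
    """Angle in degrees between unit vectors; antipodal=True ignores sign."""
    d = float(np.dot(a, b))
    if antipodal:
        d = abs(d)
    return float(np.degrees(np.arccos(np.clip(d, -1.0, 1.0))))
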