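"""Diffusion tensor fitting and scalar maps.

Two per-voxel estimators of the 3x3 symmetric diffusion tensor D from
log-linearized signals S_i = s0 * exp(-b_i g_i^T D g_i):

* ``wls`` — weighted least squares on log(S) with weights S^2, the standard
  log-linear estimator;
* ``constrained`` — Levenberg–Marquardt nonlinear least squares in the signal
  domain on a Cholesky parameterization D = L L^T, which guarantees a
  positive-semidefinite tensor even at very low SNR; initialized from the
  WLS solution.

Scalars: FA, MD, axial/radial diffusivity, and the Westin shape coefficients
CL, CP, CS normalized by the eigenvalue sum so CL + CP + CS = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phantom import DWIDataset, GradientScheme

# tensor element order used throughout: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


class TensorFitError(RuntimeError):
    pass


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    t6 = np.asarray(t6, dtype=float)
    m = np.empty(t6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_IDX):
        m[..., i, j] = t6[..., k]
        m[..., j, i] = t6[..., k]
    return m


def tensor_eigensystem(t6: np.ndarray, psd: bool = False):
    """Descending eigenvalues and matching eigenvectors of packed tensors.

    ``psd=True`` declares the tensors positive semidefinite by construction
    (Cholesky-parameterized fits); eigenvalues that are negative by pure
    round-off (|lam| below 1e3 * eps * scale) are snapped to zero.
    """
    D = tensor6_to_matrix(t6)
    lam, vec = np.linalg.eigh(D)
    lam = lam[..., ::-1]
    vec = vec[..., ::-1]
    if psd:
        scale = np.maximum(np.abs(lam).max(axis=-1, keepdims=True), np.finfo(float).tiny)
        tol = 1e3 * np.finfo(float).eps * scale
        lam = np.where((lam < 0) & (lam > -tol), 0.0, lam)
    return lam, vec


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows [1, -b*gx^2, -2b*gxgy, -2b*gxgz, -b*gy^2, -2b*gygz, -b*gz^2]."""
    g = scheme.directions
    b = scheme.b_values
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -b * gy * gy,
            -2 * b * gy * gz,
            -b * gz * gz,
        ],
        axis=1,
    )


def _check_scheme(scheme: GradientScheme):
    if len(scheme.dwi_indices) < 6 or len(scheme.b0_indices) < 1:
        raise TensorFitError("tensor fit needs >= 6 weighted directions and >= 1 b0")


def _clamp_log(signal: np.ndarray):
    eps = np.finfo(float).tiny
    n_clamped = int(np.sum(signal < eps))
    return np.log(np.maximum(signal, eps)), n_clamped


def fit_tensor_wls(signal: np.ndarray, scheme: GradientScheme):
    """WLS log-linear fit; returns (tensor6, s0, n_clamped)."""
    _check_scheme(scheme)
    X = design_matrix(scheme)
    y, n_clamped = _clamp_log(np.asarray(signal, dtype=float))
    w = np.maximum(signal, 0.0) ** 2
    Xw = X * w[:, None]
    A = Xw.T @ X
    if np.linalg.matrix_rank(A) < 7:
        raise TensorFitError("rank-deficient design matrix")
    beta = np.linalg.solve(A, Xw.T @ y)
    return beta[1:], float(np.exp(beta[0])), n_clamped


def _cholesky_params(t6: np.ndarray) -> np.ndarray:
    """Lower-triangular factor of the PSD projection of a tensor, packed."""
    D = tensor6_to_matrix(t6)
    lam, V = np.linalg.eigh(D)
    lam = np.maximum(lam, 1e-10)
    L = np.linalg.cholesky(V @ np.diag(lam) @ V.T)
    return np.array([L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2]])


def _unpack_L(p: np.ndarray) -> np.ndarray:
    L = np.zeros((3, 3))
    L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2] = p
    return L


def fit_tensor_constrained(signal: np.ndarray, scheme: GradientScheme, max_iter: int = 100):
    """Signal-domain LM fit of D = L L^T; returns (tensor6, s0, converged)."""
    _check_scheme(scheme)
    t6, s0, _ = fit_tensor_wls(signal, scheme)
    g = scheme.directions
    b = scheme.b_values
    s = np.asarray(signal, dtype=float)
    p0 = np.concatenate([_cholesky_params(t6), [np.log(max(s0, 1e-300))]])

    def model_q(p):
        L = _unpack_L(p[:6])
        gL = g @ L  # rows: L^T g
        q = (gL**2).sum(axis=1)
        return np.exp(p[6]) * np.exp(-b * q), gL

    def residuals(p):
        m, _ = model_q(p)
        return m - s

    def jacobian(p):
        m, gL = model_q(p)
        J = np.empty((len(s), 7))
        # d model / d L_jk = m * (-b) * 2 * (L^T g)_k * g_j
        cols = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
        for c, (j, k) in enumerate(cols):
            J[:, c] = m * (-b) * 2.0 * gL[:, k] * g[:, j]
        J[:, 6] = m
        return J

    try:
        res = least_squares(
            residuals, p0, jac=jacobian, method="lm", xtol=1e-8, ftol=1e-8, max_nfev=max_iter * 8
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise TensorFitError(str(exc)) from exc
    L = _unpack_L(res.x[:6])
    D = L @ L.T
    t6_out = np.array([D[i, j] for i, j in _IDX])
    return t6_out, float(np.exp(res.x[6])), bool(res.success)


def fit_tensor(signal: np.ndarray, scheme: GradientScheme, method: str = "wls") -> np.ndarray:
    """Fit one voxel; returns the 6 unique tensor elements (mm²/s)."""
    if method == "wls":
        return fit_tensor_wls(signal, scheme)[0]
    if method == "constrained":
        return fit_tensor_constrained(signal, scheme)[0]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# scalars
# ---------------------------------------------------------------------------


def tensor_scalars(l1, l2, l3):
    """Scalar invariants from ordered eigenvalues l1 >= l2 >= l3 >= 0.

    Returns (FA, MD, CL, CP, CS, AD, RD).  Westin coefficients use the
    eigenvalue-sum normalization, so CL + CP + CS = 1.  All-zero eigenvalues
    yield the zero sentinel for every scalar.
    """
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    tr = l1 + l2 + l3
    valid = tr > 0
    safe_tr = np.where(valid, tr, 1.0)
    md = tr / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1**2 + l2**2 + l3**2
    fa = np.where(valid, np.sqrt(1.5) * np.sqrt(num / np.where(den > 0, den, 1.0)), 0.0)
    cl = np.where(valid, (l1 - l2) / safe_tr, 0.0)
    cp = np.where(valid, 2.0 * (l2 - l3) / safe_tr, 0.0)
    cs = np.where(valid, 3.0 * l3 / safe_tr, 0.0)
    ad = np.where(valid, l1, 0.0)
    rd = np.where(valid, (l2 + l3) / 2.0, 0.0)
    md = np.where(valid, md, 0.0)
    return fa, md, cl, cp, cs, ad, rd


SCALAR_NAMES = ("FA", "MD", "CL", "CP", "CS", "AD", "RD")


@dataclass
class TensorField:
    """Per-voxel tensors, eigensystems and a validity mask on the image grid."""

    tensors: np.ndarray  # (x, y, z, 6)
    eigenvalues: np.ndarray  # (x, y, z, 3) descending
    eigenvectors: np.ndarray  # (x, y, z, 3, 3); [..., :, i] pairs eigenvalue i
    valid: np.ndarray  # bool (x, y, z)

    def principal_direction(self, voxel) -> np.ndarray:
        return self.eigenvectors[voxel][:, 0]


@dataclass
class ScalarMaps:
    """FA/MD/CL/CP/CS/AD/RD grids; sentinel 0 where invalid."""

    FA: np.ndarray
    MD: np.ndarray
    CL: np.ndarray
    CP: np.ndarray
    CS: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    valid: np.ndarray

    def as_dict(self):
        return {name: getattr(self, name) for name in SCALAR_NAMES}


def _batched_wls(signals: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """WLS fit of many voxels at once; returns (n_vox, 7) beta."""
    X = design_matrix(scheme)
    y, _ = _clamp_log(signals)
    w = np.maximum(signals, 0.0) ** 2
    A = np.einsum("vn,ni,nj->vij", w, X, X)
    rhs = np.einsum("vn,ni,vn->vi", w, X, y)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def compute_scalar_maps(
    dataset: DWIDataset, method: str = "constrained"
) -> tuple[TensorField, ScalarMaps]:
    """Fit tensors inside the WM mask and derive scalar maps.

    Outside-mask voxels carry sentinel 0 with validity False.  Non-converged
    constrained fits fall back to WLS and are flagged invalid.
    """
    shape = dataset.spatial_shape
    tensors = np.zeros(shape + (6,))
    valid = np.zeros(shape, dtype=bool)
    vox = np.argwhere(dataset.wm_mask)
    if len(vox):
        signals = dataset.signal[dataset.wm_mask]
        if method == "wls":
            beta = _batched_wls(signals, dataset.scheme)
            t6 = beta[:, 1:]
            ok = np.ones(len(vox), dtype=bool)
        elif method == "constrained":
            t6 = np.empty((len(vox), 6))
            ok = np.ones(len(vox), dtype=bool)
            for i in range(len(vox)):
                t6[i], _, ok[i] = fit_tensor_constrained(signals[i], dataset.scheme)
        else:
            raise ValueError(f"unknown method {method!r}")
        tensors[tuple(vox.T)] = t6
        valid[tuple(vox.T)] = ok

    lam, vec = tensor_eigensystem(tensors, psd=(method == "constrained"))
    fa, md, cl, cp, cs, ad, rd = tensor_scalars(lam[..., 0], lam[..., 1], lam[..., 2])
    inmask = dataset.wm_mask
    maps = ScalarMaps(
        FA=np.where(inmask, fa, 0.0),
        MD=np.where(inmask, md, 0.0),
        CL=np.where(inmask, cl, 0.0),
        CP=np.where(inmask, cp, 0.0),
        CS=np.where(inmask, cs, 0.0),
        AD=np.where(inmask, ad, 0.0),
        RD=np.where(inmask, rd, 0.0),
        valid=valid,
    )
    field = TensorField(tensors=tensors, eigenvalues=lam, eigenvectors=vec, valid=valid)
    return field, maps
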