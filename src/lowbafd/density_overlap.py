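"""Track-density imaging, percent-of-max thresholding, Overlap Fraction,
and tract-based ROI statistics.

A track-density image (TDI) assigns each voxel the number of distinct
streamlines whose polyline passes through it (each streamline counts at most
once per voxel, making counts independent of the tracking step size).
Thresholding retains voxels whose density reaches a given percentage of the
map maximum; the 0% level is the raw TDI (all visited voxels).  The Overlap
Fraction between a target and a reference mask is

    OF = 100 * |V_target intersect V_reference| / |V_reference|  (percent).

Thresholded TDIs also serve as ROIs over which tensor scalar maps are
averaged (tract-based ROI analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti import SCALAR_NAMES, ScalarMaps
from .dwio import Tractogram, world_to_voxel


class DensityError(ValueError):
    pass


@dataclass
class TDIMap:
    counts: np.ndarray  # non-negative int grid
    affine: np.ndarray
    algorithm: str = ""

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise DensityError("TDI counts must be non-negative")


@dataclass(frozen=True)
class OFResult:
    of_percent: float
    cutoff_percent: float
    target: str
    reference: str
    n_target: int
    n_reference: int
    n_intersection: int


def streamline_voxels(points: np.ndarray, affine: np.ndarray, shape, voxel_size) -> np.ndarray:
    """Distinct voxel indices visited by one streamline polyline.

    Each segment is supersampled at intervals of at most half the smallest
    voxel dimension so no traversed voxel is skipped.
    """
    step = 0.5 * float(np.min(voxel_size))
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    samples = [points[0]]
    for i, L in enumerate(seglen):
        n = max(int(np.ceil(L / step)), 1)
        t = np.arange(1, n + 1) / n
        samples.append(points[i] + t[:, None] * (points[i + 1] - points[i]))
    pts = np.vstack(samples)
    idx = np.floor(world_to_voxel(pts, affine) + 0.5).astype(int)
    shape = np.asarray(shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    return np.unique(idx[ok], axis=0)


def compute_tdi(
    tractogram: Tractogram, shape, affine: np.ndarray, voxel_size, algorithm: str = ""
) -> TDIMap:
    """Count distinct streamlines per voxel on the given grid."""
    counts = np.zeros(shape, dtype=int)
    for s in tractogram.streamlines:
        vox = streamline_voxels(np.asarray(s), affine, shape, voxel_size)
        counts[tuple(vox.T)] += 1
    return TDIMap(counts=counts, affine=affine, algorithm=algorithm)


def threshold_tdi(tdi: TDIMap, cutoff_percent: float) -> np.ndarray:
    """Binary mask of voxels with count > 0 and count >= cutoff% of the max.

    The comparison is inclusive (>=), so the 0% level equals the raw TDI.
    """
    if not (0 <= cutoff_percent < 100):
        raise DensityError("cutoff_percent must lie in [0, 100)")
    m = int(tdi.counts.max())
    if m == 0:
        import warnings

        warnings.warn("thresholding an all-zero TDI yields an empty mask")
        return np.zeros_like(tdi.counts, dtype=bool)
    return (tdi.counts > 0) & (tdi.counts >= cutoff_percent / 100.0 * m)


def overlap_fraction(
    target_mask: np.ndarray,
    reference_mask: np.ndarray,
    cutoff_percent: float = 0.0,
    target: str = "target",
    reference: str = "reference",
) -> OFResult:
    """Percent of the reference volume covered by the target volume."""
    if target_mask.shape != reference_mask.shape:
        raise DensityError("masks must share one grid")
    n_ref = int(np.count_nonzero(reference_mask))
    if n_ref == 0:
        raise DensityError("overlap fraction undefined for an empty reference")
    n_tgt = int(np.count_nonzero(target_mask))
    n_int = int(np.count_nonzero(target_mask & reference_mask))
    return OFResult(
        of_percent=100.0 * n_int / n_ref,
        cutoff_percent=float(cutoff_percent),
        target=target,
        reference=reference,
        n_target=n_tgt,
        n_reference=n_ref,
        n_intersection=n_int,
    )


def tract_roi_stats(scalar_maps: ScalarMaps, mask: np.ndarray) -> dict[str, float]:
    """Mean of each scalar map over the valid voxels of a tract mask.

    Returns means plus ``n_voxels`` and ``n_invalid`` (masked voxels excluded
    because their fit was flagged).
    """
    if not np.any(mask):
        raise DensityError("tract ROI mask is empty")
    use = mask & scalar_maps.valid
    n_invalid = int(np.count_nonzero(mask) - np.count_nonzero(use))
    if not np.any(use):
        raise DensityError("no valid voxels in the tract ROI")
    out = {name: float(scalar_maps.as_dict()[name][use].mean()) for name in SCALAR_NAMES}
    out["n_voxels"] = int(np.count_nonzero(use))
    out["n_invalid"] = n_invalid
    return out
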