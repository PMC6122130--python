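"""File formats and intensity normalization.

NIfTI-1 volumes via nibabel, FSL-dialect gradient tables (bvals: one row of
N values; bvecs: three rows of N values, image coordinates), MRtrix-style TCK
tractograms, and the median-b0 normalization applied before response-function
and fiber-density work.

Coordinate conventions: streamline points live in world mm through the NIfTI
affine; voxel lookup maps world -> continuous voxel coordinates and takes the
half-open voxel [i - 0.5, i + 0.5) around each integer index (voxel centers
sit at integer voxel coordinates, as the affine defines them).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIDataset, GradientScheme, PhantomError


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# tractogram container
# ---------------------------------------------------------------------------


@dataclass
class Tractogram:
    """A set of streamlines, each an ordered (n_i, 3) float array in world mm."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    seed_indices: list[int] = field(default_factory=list)
    space: str = "world"

    def __post_init__(self):
        for s in self.streamlines:
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise FormatError("each streamline needs >= 2 points of 3 coordinates")
            if np.any(np.linalg.norm(np.diff(s, axis=0), axis=1) == 0):
                raise FormatError("consecutive streamline points must be distinct")
        if not self.seed_indices:
            self.seed_indices = list(range(len(self.streamlines)))

    def __len__(self) -> int:
        return len(self.streamlines)


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World mm -> continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    p = np.atleast_2d(points)
    return p @ inv[:3, :3].T + inv[:3, 3]


def voxel_index(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World mm -> integer voxel index (half-open voxel around its center)."""
    return np.floor(world_to_voxel(points, affine) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# DWI read/write
# ---------------------------------------------------------------------------


def read_dwi(nifti_path, bvals_path, bvecs_path, mask_path) -> DWIDataset:
    """Load a 4D DWI volume with its FSL gradient table and binary WM mask.

    bvecs are renormalized to unit length; zero-norm bvec columns must carry
    b = 0 and are classified as b0 volumes.
    """
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.dataobj, dtype=float)
    if signal.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4D volume, got {signal.ndim}D")
    if not np.all(np.isfinite(signal)):
        bad = np.argwhere(~np.isfinite(signal))
        raise FormatError(f"{nifti_path}: non-finite voxels at indices {bad[:10].tolist()}")
    bvals = np.loadtxt(str(bvals_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvecs_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise FormatError(f"{bvecs_path}: expected 3xN or Nx3 layout")
    if len(bvals) != len(bvecs) or len(bvals) != signal.shape[3]:
        raise FormatError(
            f"gradient table length {len(bvals)}/{len(bvecs)} does not match "
            f"{signal.shape[3]} volumes"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    zero = norms < 1e-6
    if np.any(bvals[zero] != 0):
        raise FormatError("zero-norm bvec with nonzero b-value")
    bvecs = np.where(zero[:, None], 0.0, bvecs / np.where(zero, 1.0, norms)[:, None])
    bvals = np.where(zero, 0.0, bvals)
    scheme = GradientScheme(directions=bvecs, b_values=bvals)
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    affine = img.affine
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIDataset(
        signal=signal, scheme=scheme, voxel_size=voxel_size, wm_mask=mask, affine=affine
    )


def write_dwi(dataset: DWIDataset, out_dir, prefix: str = "dwi") -> dict[str, Path]:
    """Write NIfTI + FSL bvals/bvecs + mask; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": out / f"{prefix}.nii.gz",
        "bvals": out / f"{prefix}.bval",
        "bvecs": out / f"{prefix}.bvec",
        "mask": out / f"{prefix}_mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(dataset.signal, dataset.affine), str(paths["nifti"]))
    np.savetxt(paths["bvals"], dataset.scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(paths["bvecs"], dataset.scheme.directions.T, fmt="%.9g")
    nib.save(
        nib.Nifti1Image(dataset.wm_mask.astype(np.uint8), dataset.affine), str(paths["mask"])
    )
    return paths


def normalize_by_median_b0(dataset: DWIDataset) -> DWIDataset:
    """Divide every volume by the median b0 intensity over the WM mask."""
    if not dataset.wm_mask.any():
        raise FormatError("cannot normalize: WM mask is empty")
    b0_idx = dataset.scheme.b0_indices
    if len(b0_idx) == 0:
        raise FormatError("cannot normalize: scheme has no b0 volume")
    med = float(np.median(dataset.signal[dataset.wm_mask][:, b0_idx]))
    if med <= 0:
        raise FormatError("median b0 over the mask is not positive")
    return replace(dataset, signal=dataset.signal / med)


# ---------------------------------------------------------------------------
# TCK tractograms (MRtrix binary track format)
# ---------------------------------------------------------------------------

_TCK_MAGIC = "mrtrix tracks"


def write_tractogram(path, tractogram: Tractogram) -> None:
    """Write streamlines as TCK: float32 LE triplets, NaN separators, Inf EOF."""
    path = Path(path)
    body = []
    for s in tractogram.streamlines:
        body.append(np.asarray(s, dtype="<f4"))
        body.append(np.full((1, 3), np.nan, dtype="<f4"))
    body.append(np.full((1, 3), np.inf, dtype="<f4"))
    data = np.concatenate(body, axis=0) if body else np.full((1, 3), np.inf, dtype="<f4")
    header = (
        f"{_TCK_MAGIC}\ndatatype: Float32LE\ncount: {len(tractogram)}\n"
    ).encode()
    # fixed-width offset field so the header length is known before writing
    offset = len(header) + len(f"file: . {0:>10d}\nEND\n".encode())
    tail = f"file: . {offset:>10d}\nEND\n".encode()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(tail)
        fh.write(data.tobytes())


def read_tractogram(path) -> Tractogram:
    path = Path(path)
    raw = path.read_bytes()
    if not raw.startswith(_TCK_MAGIC.encode()):
        raise FormatError(f"{path}: not a TCK file")
    end = raw.find(b"END\n")
    if end < 0:
        raise FormatError(f"{path}: header without END")
    header = raw[:end].decode(errors="replace")
    offset = None
    for line in header.splitlines():
        if line.startswith("file:"):
            offset = int(line.split()[-1])
    if offset is None:
        raise FormatError(f"{path}: header without file offset")
    body = raw[offset:]
    if len(body) % 12:
        raise FormatError(f"{path}: truncated triplet stream")
    flat = np.frombuffer(body, dtype="<f4")
    pts = flat.reshape(-1, 3)
    streamlines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    ended = False
    for p in pts:
        if np.all(np.isinf(p)):
            ended = True
            break
        if np.any(np.isnan(p)):
            if current:
                streamlines.append(np.array(current, dtype=float))
                current = []
        else:
            current.append(p.astype(float))
    if not ended:
        raise FormatError(f"{path}: missing Inf end-of-file marker")
    if current:
        streamlines.append(np.array(current, dtype=float))
    return Tractogram(streamlines=streamlines)


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------


def write_ground_truth(truth, affine: np.ndarray, out_dir, prefix: str = "truth") -> dict[str, Path]:
    """Label map as NIfTI plus a JSON sidecar of per-voxel compartment params."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": out / f"{prefix}_labels.nii.gz",
        "sidecar": out / f"{prefix}_compartments.json",
    }
    nib.save(nib.Nifti1Image(truth.bundle_labels.astype(np.int16), affine), str(paths["labels"]))
    records = []
    for vox, comp in truth.compartments.items():
        records.append(
            {
                "voxel": [int(v) for v in vox],
                "csf_fraction": comp.csf_fraction,
                "d_axial": comp.d_axial,
                "d_radial_extra": comp.d_radial_extra,
                "d_csf": comp.d_csf,
                "fibers": [
                    {
                        "direction": [float(x) for x in p.direction],
                        "volume_fraction": p.volume_fraction,
                        "f_ic": p.f_ic,
                    }
                    for p in comp.fiber_populations
                ],
            }
        )
    paths["sidecar"].write_text(json.dumps(records))
    return paths
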