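"""Core I/O and geometry for diffusion-weighted volumes.

NIfTI reading/writing is delegated to :mod:`nibabel`; gradient tables use the
FSL bval/bvec text dialect (bvals: one whitespace-separated row; bvecs: three
rows of x, y, z components, one column per volume).  A transposed q-by-3 bvec
layout is detected by shape and accepted.

Conventions: voxel indices are 0-based; world coordinates are obtained through
the NIfTI affine and assumed RAS+ after loading.  All ROI centres elsewhere in
the package are world-space millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GradientTable",
    "DWIVolume",
    "VolumeMask",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "resample_affine",
    "B0_THRESHOLD",
]

#: b-values below this (s/mm^2) count as b=0 — scanners emit small nominal values.
B0_THRESHOLD = 50.0


class GradientValidationError(ValueError):
    """Raised when a gradient table violates its invariants."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit direction vectors.

    Parameters
    ----------
    bvals : (q,) array
        Non-negative b-values.
    bvecs : (q, 3) array
        Direction cosines; rows paired with b > 0 must have unit norm
        (tolerance 1e-4).  Rows paired with b = 0 may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2:
            raise GradientValidationError("bvecs must be a 2-D array")
        if bvecs.shape[0] != bvals.size and bvecs.shape == (3, bvals.size):
            bvecs = bvecs.T  # tolerate FSL 3-row layout passed directly
        if bvecs.shape != (bvals.size, 3):
            raise GradientValidationError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise GradientValidationError("b-values must be non-negative")
        dw = bvals >= B0_THRESHOLD
        if not np.any(~dw):
            raise GradientValidationError("gradient table has no b=0 entry")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-4):
            worst = float(np.abs(norms - 1.0).max())
            raise GradientValidationError(
                f"non-unit bvec for b>0 entry (max |norm-1| = {worst:.2e})"
            )
        if _n_distinct_directions(bvecs[dw]) < 6:
            raise GradientValidationError(
                "fewer than 6 non-collinear diffusion-weighted directions"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean mask of b=0 entries (b < 50 s/mm^2)."""
        return self.bvals < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask


def _n_distinct_directions(vecs: np.ndarray, tol: float = 1e-3) -> int:
    """Count directions distinct up to sign (collinear pairs merged)."""
    kept: list[np.ndarray] = []
    for v in vecs:
        if not any(min(np.linalg.norm(v - u), np.linalg.norm(v + u)) < tol for u in kept):
            kept.append(v)
    return len(kept)


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted series with its grid geometry and gradients."""

    signal: np.ndarray
    affine: np.ndarray
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4-D (x, y, z, q)")
        if self.signal.shape[3] != len(self.gtab):
            raise ValueError(
                f"volume count mismatch: image has {self.signal.shape[3]} volumes "
                f"but gradient table has {len(self.gtab)} entries"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.signal < 0):
            raise ValueError("DWI signal must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class VolumeMask:
    """Binary 3-D mask on a voxel grid."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask must be 3-D")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = data.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)


# ---------------------------------------------------------------------------
# FSL-dialect gradient text files


def read_bvals_bvecs(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise GradientValidationError("bvec file must contain a 2-D table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise GradientValidationError(f"unrecognised bvec layout {bvecs.shape}")
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(gtab: GradientTable, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# Volume I/O


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4-D NIfTI plus FSL bval/bvec files into a validated DWIVolume."""
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata())
    gtab = read_bvals_bvecs(bval_path, bvec_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    if data.shape[3] != len(gtab):
        raise ValueError(
            f"volume count mismatch: image has {data.shape[3]} volumes "
            f"but gradient table has {len(gtab)} entries"
        )
    return DWIVolume(signal=data, affine=img.affine, gtab=gtab)


def write_dwi(vol: DWIVolume, image_path, bval_path, bvec_path) -> tuple[Path, Path, Path]:
    """Write a DWIVolume as NIfTI + FSL-dialect gradient text files."""
    img = nib.Nifti1Image(np.asarray(vol.signal, dtype=np.float64), vol.affine)
    nib.save(img, str(image_path))
    write_bvals_bvecs(vol.gtab, bval_path, bvec_path)
    return Path(image_path), Path(bval_path), Path(bvec_path)


def read_mask(path) -> VolumeMask:
    img = nib.load(str(path))
    return VolumeMask(data=np.rint(img.get_fdata()).astype(np.int8), affine=img.affine)


def write_mask(mask: VolumeMask, path) -> Path:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return Path(path)


def save_map(data: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a scalar 3-D map as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Resampling


def resample_affine(
    data: np.ndarray,
    affine: np.ndarray,
    transform: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    interp: str = "trilinear",
) -> np.ndarray:
    """Resample a 3-D map onto a target grid through a world-space affine.

    ``transform`` maps source-world (mm) to target-world (mm).  Each target
    voxel centre is pulled back through ``transform``-inverse and the source
    grid is sampled with trilinear (continuous maps) or nearest-neighbour
    (masks/labels) interpolation; samples outside the source grid are 0.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 matrix")
    if interp not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    # target voxel -> target world -> source world -> source voxel
    full = np.linalg.inv(np.asarray(affine, float)) @ np.linalg.inv(transform) @ np.asarray(
        target_affine, float
    )
    ii, jj, kk = np.meshgrid(
        *(np.arange(s, dtype=float) for s in target_shape), indexing="ij"
    )
    coords = np.stack([ii, jj, kk, np.ones_like(ii)])
    src = np.einsum("ab,bxyz->axyz", full, coords)[:3]
    order = 1 if interp == "trilinear" else 0
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), src, order=order, mode="constant", cval=0.0
    )
    if interp == "nearest" and np.all(np.isin(np.unique(data), (0, 1))):
        out = out.astype(data.dtype)
    return out
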