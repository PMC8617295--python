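"""4D BOLD volumes, binary masks and voxel→world coordinate mapping.

All per-voxel arrays in the package (fingerprints, gradients, trend-surface
inputs) share a single voxel scan order: C order over the true voxels of the
mask, i.e. last grid axis fastest.  This is the order produced by
``numpy.argwhere`` / ``numpy.ndarray.__getitem__`` with a boolean mask and is
what :func:`voxel_coordinates` documents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from gradpain.errors import DataError

log = logging.getLogger(__name__)


@dataclass
class BoldVolume:
    """A 4D BOLD time series.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel grid with time on the last axis (NIfTI convention).
    affine : ndarray, shape (4, 4)
        Voxel-index (0-based) to world (mm) map.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise DataError(f"BOLD data must be 4D (X,Y,Z,T), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise DataError(f"need at least 2 timepoints, got {self.data.shape[3]}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            idx = tuple(int(v) for v in bad[0])
            raise DataError(f"non-finite values in BOLD data, first at voxel index {idx}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise DataError("affine must be an invertible 4x4 matrix")
        if not self.tr > 0:
            raise DataError(f"repetition time must be positive, got {self.tr}")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def timeseries(self, mask: "Mask") -> np.ndarray:
        """Return a T × N matrix of the time series of the mask's true voxels,
        columns in the package voxel scan order."""
        check_grid(self, mask)
        return self.data[mask.data].T  # boolean indexing yields C-order rows


@dataclass
class Mask:
    """A boolean voxel grid aligned with a :class:`BoldVolume` grid."""

    data: np.ndarray
    label: str = "mask"
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DataError(f"mask '{self.label}' must be 3D, got shape {self.data.shape}")
        if not self.data.any():
            raise DataError(f"mask '{self.label}' has zero true voxels")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """N × 3 integer voxel indices of true voxels, C scan order."""
        return np.argwhere(self.data)


def check_grid(volume: BoldVolume, mask: Mask) -> None:
    if volume.shape3d != mask.data.shape:
        raise DataError(
            f"grid mismatch: volume grid {volume.shape3d} vs mask '{mask.label}' grid {mask.data.shape}"
        )


def load_volume(path: str | Path, tr: float | None = None) -> BoldVolume:
    """Load a 4D NIfTI volume.

    The repetition time is read from the header pixdim unless overridden.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise DataError(f"no usable repetition time in header of {path}; pass tr explicitly")
    return BoldVolume(data=data, affine=np.asarray(img.affine), tr=tr)


def save_volume(volume: BoldVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (volume.tr,))
    nib.save(img, str(path))


def load_mask(path: str | Path, label: str | None = None) -> Mask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0.5
    return Mask(data=data, label=label or Path(path).name, affine=np.asarray(img.affine))


def save_mask(mask: Mask, path: str | Path, affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else (mask.affine if mask.affine is not None else np.eye(4))
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), aff), str(path))


def voxel_coordinates(mask: Mask, affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of the mask's true voxels.

    Rows follow the package voxel scan order (C order, last axis fastest);
    coordinates are the affine applied to 0-based voxel indices.
    """
    affine = np.asarray(affine, dtype=np.float64)
    ijk = mask.indices().astype(np.float64)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def load_confounds(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited confound file, one column per regressor."""
    arr = np.loadtxt(str(path), ndmin=2)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"non-finite values in confound file {path}")
    return arr
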