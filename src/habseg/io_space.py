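"""Volumes, masks and the voxel/world coordinate convention.

All geometry in this package is done in world millimetres using the RAS+
convention (+x right, +y anterior, +z superior).  Voxel indices are
0-based and the affine maps voxel *centres* to world coordinates, the
dominant NIfTI convention.  Files read from disk are canonicalized to
RAS+ axis order on load; canonicalization permutes/flips the data axes
and adjusts the affine so that the world coordinate of every voxel
centre is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import BoundsError, DimensionalityError, ProtocolWarning

__all__ = [
    "Volume3D",
    "Mask3D",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "voxel_to_world",
    "world_to_voxel",
]

#: voxel dimensions (mm) expected for protocol-conformant structural scans
PROTOCOL_VOXEL_RANGE_MM = (0.3, 2.0)


@dataclass
class Volume3D:
    """A 3D intensity grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data:
        3D scalar array, arbitrary intensity units.
    affine:
        4x4 homogeneous matrix mapping 0-based voxel-centre indices
        (i, j, k, 1) to world millimetres (RAS+).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine's upper-left 3x3 block is singular")
        lo, hi = PROTOCOL_VOXEL_RANGE_MM
        dims = self.voxel_dims
        if np.any(dims < lo) or np.any(dims > hi):
            warnings.warn(
                f"voxel dimensions {dims} mm outside the protocol envelope "
                f"[{lo}, {hi}] mm",
                ProtocolWarning,
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_dims(self) -> np.ndarray:
        """Voxel edge lengths in mm per grid axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def axis_aligned(self, tol: float = 1e-6) -> bool:
        """True if each grid axis maps onto a single world axis."""
        m = np.abs(self.affine[:3, :3])
        return bool(np.all(m - np.diag(np.diag(m)) < tol * m.max()))


@dataclass
class Mask3D:
    """A binary ROI on a :class:`Volume3D` grid.

    The affine is that of the source volume the mask was traced on;
    masks are never resampled on write.
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary 0/1, found values {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data.astype(float), self.affine)


def _canonicalize(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 volume and canonicalize it to RAS+ axis order.

    Axis permutations/flips are applied to the data array with a matching
    affine update, so world coordinates of voxel centres are unchanged.
    Intensities are untouched.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got shape {img.shape}"
        )
    img = _canonicalize(img)
    data = np.asanyarray(img.dataobj)
    return Volume3D(data, img.affine)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1, affine verbatim."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "other") -> Mask3D:
    """Read a binary mask; nonzero voxels become foreground."""
    vol = read_volume(path)
    return Mask3D((np.asarray(vol.data) != 0).astype(np.uint8), vol.affine, label)


def write_mask(mask: Mask3D, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI-1 with its source affine verbatim."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def _check_bounds(vol: Volume3D | Mask3D, index: np.ndarray) -> None:
    shape = np.asarray(vol.shape)
    if np.any(index < 0) or np.any(index >= shape):
        raise BoundsError(f"index {tuple(index)} outside grid of shape {tuple(shape)}")


def voxel_to_world(vol: Volume3D | Mask3D, index) -> np.ndarray:
    """World-mm coordinate of the voxel centre at ``index`` (0-based).

    Raises :class:`BoundsError` for indices outside the grid.
    """
    idx = np.asarray(index)
    single = idx.ndim == 1
    idx2 = np.atleast_2d(idx)
    for row in idx2:
        _check_bounds(vol, np.asarray(row))
    out = idx2 @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if single else out


def world_to_voxel(vol: Volume3D | Mask3D, point, round_to_int: bool = True):
    """Inverse of :func:`voxel_to_world`; rounds to the nearest voxel by default."""
    pt = np.asarray(point, dtype=float)
    inv = np.linalg.inv(vol.affine)
    cont = pt @ inv[:3, :3].T + inv[:3, 3]
    if not round_to_int:
        return cont
    return np.round(cont).astype(int)
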