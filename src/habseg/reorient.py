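"""Rigid AC–PC reorientation.

The protocol places the midpoint of the anterior commissure (AC) at the
world origin, rotates so the posterior commissure (PC) lies on the -y
axis at the same x and z as the AC, and rolls about the AC–PC axis until
the midsagittal plane coincides with x = 0.  The transform is computed
from three user-supplied landmarks and, by default, applied to the image
header only — the data grid is never resampled unless explicitly
requested, preserving the acquired resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateGeometryError, ProtocolWarning
from .io_space import Mask3D, Volume3D

__all__ = [
    "RigidTransform",
    "AcpcLandmarks",
    "compute_acpc_transform",
    "apply_transform_header",
    "resample_to_acpc_grid",
    "read_acpc_landmarks",
]

#: plausible human AC–PC distance envelope (mm); outside -> warning
ACPC_DISTANCE_RANGE_MM = (15.0, 40.0)
#: minimum angular separation of the midsagittal point from the AC–PC line
MIN_MIDSAG_ANGLE_DEG = 5.0


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R p + t (world mm to world mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1), no reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class AcpcLandmarks:
    """AC, PC and a midsagittal point, in world mm.

    ``midsagittal`` is any point on the interhemispheric plane well away
    from the AC–PC line; it fixes the roll about that axis.
    """

    ac: np.ndarray
    pc: np.ndarray
    midsagittal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ac", "pc", "midsagittal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        d = float(np.linalg.norm(self.ac - self.pc))
        if d < 1e-9:
            raise DegenerateGeometryError("AC and PC coincide")
        lo, hi = ACPC_DISTANCE_RANGE_MM
        if not lo <= d <= hi:
            warnings.warn(
                f"AC–PC distance {d:.1f} mm outside plausible range [{lo}, {hi}] mm",
                ProtocolWarning,
                stacklevel=2,
            )
        u = (self.pc - self.ac) / d
        v = self.midsagittal - self.ac
        vn = float(np.linalg.norm(v))
        if vn < 1e-9:
            raise DegenerateGeometryError("midsagittal point coincides with AC")
        sin_angle = float(np.linalg.norm(np.cross(u, v / vn)))
        if sin_angle < 1e-9:
            raise DegenerateGeometryError(
                "midsagittal point is collinear with the AC–PC line"
            )
        if np.degrees(np.arcsin(min(sin_angle, 1.0))) < MIN_MIDSAG_ANGLE_DEG:
            warnings.warn(
                "midsagittal point is nearly collinear with the AC–PC line "
                f"(< {MIN_MIDSAG_ANGLE_DEG} deg); roll is poorly conditioned",
                ProtocolWarning,
                stacklevel=2,
            )

    @property
    def acpc_distance(self) -> float:
        return float(np.linalg.norm(self.ac - self.pc))


def compute_acpc_transform(landmarks: AcpcLandmarks) -> RigidTransform:
    """Rigid transform taking native world coordinates to the AC–PC frame.

    Guarantees, by construction: T(ac) = origin, T(pc) = (0, -|ac-pc|, 0),
    and T(midsagittal) lies on the x = 0 plane with a positive z
    component (the midsagittal point is conventionally superior to the
    AC–PC line).
    """
    ac, pc, ms = landmarks.ac, landmarks.pc, landmarks.midsagittal
    ey = (ac - pc) / np.linalg.norm(ac - pc)  # +y points AC-ward (anterior)
    w = ms - ac
    w_perp = w - np.dot(w, ey) * ey
    n = np.linalg.norm(w_perp)
    if n < 1e-9:
        raise DegenerateGeometryError("midsagittal point collinear with AC–PC line")
    ez = w_perp / n
    ex = np.cross(ey, ez)
    R = np.vstack([ex, ey, ez])  # rows = frame axes -> det +1 by construction
    return RigidTransform(R, -R @ ac)


def apply_transform_header(vol: Volume3D, transform: RigidTransform) -> Volume3D:
    """Re-express the volume in the transformed frame without resampling.

    The data grid is untouched; only the affine is composed with the
    transform.  Lossless: world coordinates of every voxel move exactly
    by the rigid motion.
    """
    return Volume3D(vol.data, transform.matrix @ vol.affine)


def apply_transform_header_mask(mask: Mask3D, transform: RigidTransform) -> Mask3D:
    """Header-only transform for a mask (companion of the volume path)."""
    return Mask3D(mask.data, transform.matrix @ mask.affine, mask.label)


def _output_grid(vol: Volume3D, transform: RigidTransform, voxel_size: float):
    """Axis-aligned AC–PC-frame grid covering the transformed input FOV."""
    shape = np.asarray(vol.shape)
    corners = np.array(
        [[i, j, k] for i in (0, shape[0] - 1)
         for j in (0, shape[1] - 1)
         for k in (0, shape[2] - 1)],
        dtype=float,
    )
    world = corners @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    acpc = transform.apply(world)
    lo = acpc.min(axis=0)
    hi = acpc.max(axis=0)
    n = np.maximum(np.floor((hi - lo) / voxel_size + 0.5).astype(int) + 1, 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return n, affine


def resample_to_acpc_grid(
    vol: Volume3D,
    transform: RigidTransform,
    voxel_size: float,
    *,
    is_mask: bool = False,
) -> Volume3D | Mask3D:
    """Resample onto an axis-aligned grid in the AC–PC frame.

    Interpolation happens exactly once: trilinear for intensities,
    nearest-neighbour when ``is_mask`` so binary masks stay binary.
    Regions of the output grid outside the input field of view are zero.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    n, out_affine = _output_grid(vol, transform, voxel_size)
    # output voxel -> acpc world -> native world -> input voxel
    inv = np.linalg.inv(vol.affine) @ transform.inverse().matrix @ out_affine
    ii, jj, kk = np.meshgrid(
        np.arange(n[0]), np.arange(n[1]), np.arange(n[2]), indexing="ij"
    )
    idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (inv @ idx)[:3]
    order = 0 if is_mask else 1
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), src, order=order,
        mode="constant", cval=0.0,
    ).reshape(tuple(n))
    if is_mask:
        return Mask3D((data > 0.5).astype(np.uint8), out_affine)
    return Volume3D(data, out_affine)


def read_acpc_landmarks(path: str | Path) -> AcpcLandmarks:
    """Load AC/PC/midsagittal landmarks from a JSON file in world mm.

    Expected keys: ``ac``, ``pc``, ``midsagittal``, each a 3-element list.
    """
    with open(path) as fh:
        obj = json.load(fh)
    return AcpcLandmarks(obj["ac"], obj["pc"], obj["midsagittal"])


def midsagittal_residual(landmarks: AcpcLandmarks, transform: RigidTransform) -> float:
    """QC number: |x| of the transformed midsagittal point (mm).

    The protocol gives no symmetry tolerance, so the residual is exposed
    rather than thresholded.
    """
    return float(abs(transform.apply(landmarks.midsagittal)[0]))
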