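"""Landmark-driven habenula delineation.

The habenula ROI is built slice by slice on coronal planes of an
AC–PC-aligned grid.

In *posterior* slices — those in which the posterior / habenular
commissure (PC/HC) is visible — the lateral boundary cannot be resolved
by image contrast, so a geometric construction is used.  Three landmarks
are placed per slice and hemisphere:

* **A** — intersection of the medial habenula boundary with the PC/HC;
* **B** — dorsal point of the medial boundary where it meets the
  mediodorsal (MD) thalamus;
* **C** — lateral aspect of the mesopontine junction next to the
  tentorial incisure.

The lateral edge is the straight line through B and C (line *x*), the
medial edge is the segment A–B along the third-ventricle CSF (line *y*),
and the ventral edge extends horizontally and laterally from A
(line *z*).  The ventrolateral apex is the intersection of lines
*x* and *z*; the slice ROI is the triangle A–B–apex.

In *anterior* slices the stria medullaris and fasciculus retroflexus
provide enough contrast, and an intensity-threshold region growing from
a seed voxel is used instead.

Voxel centres on a polygon edge count as inside (ambiguous dark-grey
voxels at the medial boundary are included); an optional one-voxel
medial dilation restricted to intermediate intensities is also provided.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import (
    ContiguityError,
    DegeneratePolygonError,
    LeakageError,
    NoIntersectionError,
    ProtocolWarning,
)
from .io_space import Mask3D, Volume3D

__all__ = [
    "SliceLandmarks",
    "SlicePolygon",
    "IntensityReferences",
    "apex_from_landmarks",
    "posterior_slice_polygon",
    "rasterize_polygon",
    "anterior_slice_roi",
    "assemble_roi",
    "trace_habenula",
    "read_slice_landmarks",
]

#: minimum pairwise landmark separation (mm)
MIN_LANDMARK_SEPARATION_MM = 0.1
#: protocol slice-span envelope at the reference slice thickness
REFERENCE_SLICE_THICKNESS_MM = 0.77
SLICE_SPAN_RANGE = (3, 5)


@dataclass(frozen=True)
class SliceLandmarks:
    """Per-slice landmark triplet for one hemisphere.

    In-plane points are (x, z) world mm on the coronal plane ``y_mm``.
    """

    y_mm: float
    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        pts = {n: np.asarray(getattr(self, n), dtype=float) for n in "ABC"}
        for n, p in pts.items():
            if p.shape != (2,):
                raise ValueError(f"point {n} must be an (x, z) pair")
            object.__setattr__(self, n, (float(p[0]), float(p[1])))
        for m, n in (("A", "B"), ("A", "C"), ("B", "C")):
            if np.linalg.norm(pts[m] - pts[n]) <= MIN_LANDMARK_SEPARATION_MM:
                raise DegeneratePolygonError(f"points {m} and {n} coincide")
        if not pts["B"][1] > pts["A"][1]:
            raise DegeneratePolygonError("B must be dorsal to A (B.z > A.z)")
        if not pts["C"][1] < pts["B"][1]:
            raise DegeneratePolygonError("C must be ventral to B (C.z < B.z)")
        xs = np.array([pts[n][0] for n in "ABC"])
        if self.side == "right" and np.any(xs < -1.0):
            warnings.warn("right-side landmarks extend past x = -1 mm",
                          ProtocolWarning, stacklevel=2)
        if self.side == "left" and np.any(xs > 1.0):
            warnings.warn("left-side landmarks extend past x = +1 mm",
                          ProtocolWarning, stacklevel=2)

    def mirrored(self) -> "SliceLandmarks":
        """Reflection in the midsagittal plane x = 0, switching hemisphere."""
        flip = {"left": "right", "right": "left"}
        return SliceLandmarks(
            self.y_mm,
            (-self.A[0], self.A[1]),
            (-self.B[0], self.B[1]),
            (-self.C[0], self.C[1]),
            flip[self.side],
        )


@dataclass(frozen=True)
class SlicePolygon:
    """The triangular posterior-slice ROI [A, B, apex] with its three edges."""

    vertices: np.ndarray  # (3, 2): A, B, apex
    side: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 2):
            raise ValueError("polygon must have exactly three (x, z) vertices")
        object.__setattr__(self, "vertices", v)
        if self.area <= 0:
            raise DegeneratePolygonError("polygon has zero area")

    @property
    def A(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def B(self) -> np.ndarray:
        return self.vertices[1]

    @property
    def apex(self) -> np.ndarray:
        return self.vertices[2]

    @property
    def area(self) -> float:
        """Shoelace area, mm^2."""
        (x1, z1), (x2, z2), (x3, z3) = np.asarray(self.vertices, dtype=float)
        return abs(x1 * (z2 - z3) + x2 * (z3 - z1) + x3 * (z1 - z2)) / 2.0


def _lateral_sign(side: str) -> float:
    return 1.0 if side == "right" else -1.0


def apex_from_landmarks(lm: SliceLandmarks) -> np.ndarray:
    """Ventrolateral apex: the B–C line intersected with the horizontal
    line through A.

    Raises :class:`NoIntersectionError` when B–C is horizontal and
    :class:`DegeneratePolygonError` when the apex falls medial to A.
    """
    A = np.asarray(lm.A, dtype=float)
    B = np.asarray(lm.B, dtype=float)
    C = np.asarray(lm.C, dtype=float)
    dz = C[1] - B[1]
    if abs(dz) <= 1e-6:
        raise NoIntersectionError("line B–C is horizontal; no apex exists")
    x = B[0] + (A[1] - B[1]) * (C[0] - B[0]) / dz
    apex = np.array([x, A[1]])
    if _lateral_sign(lm.side) * (apex[0] - A[0]) <= 0:
        raise DegeneratePolygonError(
            f"apex {tuple(apex)} is not lateral to A {lm.A} on the {lm.side}"
        )
    return apex


def posterior_slice_polygon(lm: SliceLandmarks) -> SlicePolygon:
    """Triangle [A, B, apex] bounding the habenula in a posterior slice."""
    apex = apex_from_landmarks(lm)
    return SlicePolygon(np.array([lm.A, lm.B, apex]), lm.side)


def _require_axis_aligned(vol: Volume3D | Mask3D) -> None:
    m = np.abs(np.asarray(vol.affine)[:3, :3])
    if np.any(m - np.diag(np.diag(m)) > 1e-6 * m.max()):
        raise ValueError(
            "delineation requires an axis-aligned (AC–PC frame) grid; "
            "resample or reorient first"
        )


def _coronal_slice_index(vol: Volume3D, y_mm: float) -> int:
    """Nearest coronal slice; an exact midpoint rounds toward posterior."""
    a = vol.affine
    ys = a[1, 3] + a[1, 1] * np.arange(vol.shape[1])
    d = np.abs(ys - y_mm)
    dmin = d.min()
    candidates = np.nonzero(d <= dmin + 1e-9)[0]
    return int(candidates[np.argmin(ys[candidates])])


def _inplane_axes(vol: Volume3D):
    a = vol.affine
    xs = a[0, 3] + a[0, 0] * np.arange(vol.shape[0])
    zs = a[2, 3] + a[2, 2] * np.arange(vol.shape[2])
    return xs, zs


def points_in_triangle(px: np.ndarray, pz: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Inclusive point-in-triangle test (edges and vertices count as inside).

    Vectorised half-plane sign test: a point is inside iff the three edge
    cross-products all carry the triangle's orientation sign or vanish.
    """
    (x1, z1), (x2, z2), (x3, z3) = np.asarray(tri, dtype=float)
    orient = (x2 - x1) * (z3 - z1) - (z2 - z1) * (x3 - x1)
    if orient == 0:
        return np.zeros(np.broadcast(px, pz).shape, dtype=bool)
    d1 = (x2 - x1) * (pz - z1) - (z2 - z1) * (px - x1)
    d2 = (x3 - x2) * (pz - z2) - (z3 - z2) * (px - x2)
    d3 = (x1 - x3) * (pz - z3) - (z1 - z3) * (px - x3)
    return (d1 * orient >= 0) & (d2 * orient >= 0) & (d3 * orient >= 0)


def rasterize_polygon(poly: SlicePolygon, vol: Volume3D, y_mm: float) -> Mask3D:
    """Colour the voxels of one coronal slice whose centres fall inside
    (or on the boundary of) the slice polygon."""
    _require_axis_aligned(vol)
    j = _coronal_slice_index(vol, y_mm)
    xs, zs = _inplane_axes(vol)
    inside = points_in_triangle(xs[:, None], zs[None, :], poly.vertices)
    data = np.zeros(vol.shape, dtype=np.uint8)
    data[:, j, :] = inside.astype(np.uint8)
    if not inside.any():
        warnings.warn("polygon lies outside the field of view: empty slice mask",
                      ProtocolWarning, stacklevel=2)
    return Mask3D(data, vol.affine)


@dataclass(frozen=True)
class IntensityReferences:
    """Intensity anchors for the anterior-slice region growing.

    ``seed`` is the in-plane (i, k) voxel index of a point inside the
    habenula.  On T1-weighted images CSF must be darker than MD grey
    matter, and the habenula brighter than MD (dense white-matter
    plexuses).
    """

    csf_mean: float
    md_mean: float
    seed: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.csf_mean < self.md_mean:
            raise ValueError(
                "csf_mean must be below md_mean on T1-weighted images "
                f"(got csf {self.csf_mean}, md {self.md_mean})"
            )


def anterior_slice_roi(
    vol: Volume3D,
    y_mm: float,
    refs: IntensityReferences,
    max_extent: float = 4.0,
) -> Mask3D:
    """Region-grow the habenula on an anterior slice.

    4-connected growth from the seed over voxels with intensity at or
    above tau = (md_mean + seed-region mean) / 2, clipped to a box of
    half-width ``max_extent`` mm around the seed.  If the grown region
    touches the clip box on two or more sides the local contrast is
    deemed insufficient and :class:`LeakageError` is raised.
    """
    _require_axis_aligned(vol)
    j = _coronal_slice_index(vol, y_mm)
    plane = np.asarray(vol.data, dtype=float)[:, j, :]
    si, sk = int(refs.seed[0]), int(refs.seed[1])
    if not (0 <= si < plane.shape[0] and 0 <= sk < plane.shape[1]):
        raise IndexError(f"seed {refs.seed} outside the slice grid")
    nb = plane[max(si - 1, 0): si + 2, max(sk - 1, 0): sk + 2]
    seed_mean = float(nb.mean())
    data = np.zeros(vol.shape, dtype=np.uint8)
    if seed_mean < refs.md_mean:
        warnings.warn(
            f"seed-region intensity {seed_mean:.3g} below MD reference "
            f"{refs.md_mean:.3g}: seed likely in CSF; returning seed-only mask",
            ProtocolWarning, stacklevel=2,
        )
        data[si, j, sk] = 1
        return Mask3D(data, vol.affine)
    tau = (refs.md_mean + seed_mean) / 2.0
    dims = np.linalg.norm(np.asarray(vol.affine)[:3, :3], axis=0)
    hw_i = max(int(round(max_extent / dims[0])), 1)
    hw_k = max(int(round(max_extent / dims[2])), 1)
    i0, i1 = max(si - hw_i, 0), min(si + hw_i + 1, plane.shape[0])
    k0, k1 = max(sk - hw_k, 0), min(sk + hw_k + 1, plane.shape[1])
    box = plane[i0:i1, k0:k1] >= tau
    labels, _ = ndimage.label(box, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    region = labels == labels[si - i0, sk - k0]
    if labels[si - i0, sk - k0] == 0:  # seed itself below tau (flat nb mean)
        region = np.zeros_like(box)
        region[si - i0, sk - k0] = True
    touched = sum(
        bool(edge.any())
        for edge in (region[0, :], region[-1, :], region[:, 0], region[:, -1])
    )
    if touched >= 2:
        raise LeakageError(
            f"grown region touches the {2 * max_extent:g} mm clip box on "
            f"{touched} sides: contrast insufficient for region growing"
        )
    data[i0:i1, j, k0:k1] = region.astype(np.uint8)
    return Mask3D(data, vol.affine)


def dilate_medial_ambiguous(
    mask: Mask3D, vol: Volume3D, csf_mean: float, side: str
) -> Mask3D:
    """Optionally include ambiguous dark-grey voxels at the medial boundary.

    One-voxel dilation in the medial direction, restricted to voxels with
    intensity strictly between the CSF reference and the current ROI
    mean — the voxels likely to contain part of the habenula.
    """
    data = mask.data.astype(bool)
    if not data.any():
        return mask
    img = np.asarray(vol.data, dtype=float)
    roi_mean = float(img[data].mean())
    shifted = np.zeros_like(data)
    if side == "right":  # medial is -x
        shifted[:-1] = data[1:]
    else:
        shifted[1:] = data[:-1]
    candidates = shifted & ~data & (img > csf_mean) & (img < roi_mean)
    return Mask3D((data | candidates).astype(np.uint8), mask.affine, mask.label)


def assemble_roi(
    slices: list[Mask3D],
    posterior_y: float,
    anterior_y: float,
    label: str = "other",
) -> Mask3D:
    """Union the single-slice masks into the final habenula ROI.

    The occupied coronal slices must be contiguous; the slice span is
    checked against the protocol envelope (3–5 slices at 0.77 mm,
    rescaled proportionally for other slice spacings) and a warning is
    issued outside it.
    """
    if not slices:
        raise ValueError("no slice masks supplied")
    if posterior_y > anterior_y:
        raise ValueError("posterior_y must not exceed anterior_y")
    affine = slices[0].affine
    for s in slices[1:]:
        if not np.allclose(s.affine, affine, atol=1e-9):
            raise ValueError("slice masks are on different grids")
    data = np.zeros(slices[0].shape, dtype=np.uint8)
    for s in slices:
        data |= s.data
    occupied = np.nonzero(data.any(axis=(0, 2)))[0]
    if occupied.size == 0:
        warnings.warn("assembled ROI is empty", ProtocolWarning, stacklevel=2)
        return Mask3D(data, affine, label)
    if not np.array_equal(occupied, np.arange(occupied[0], occupied[-1] + 1)):
        raise ContiguityError(
            f"occupied coronal slices {occupied.tolist()} are not contiguous"
        )
    span = int(occupied.size)
    spacing = float(np.linalg.norm(np.asarray(affine)[:3, 1]))
    scale = REFERENCE_SLICE_THICKNESS_MM / spacing
    lo = int(round(SLICE_SPAN_RANGE[0] * scale))
    hi = int(round(SLICE_SPAN_RANGE[1] * scale))
    if not lo <= span <= hi:
        warnings.warn(
            f"ROI spans {span} coronal slices at {spacing:.3g} mm; protocol "
            f"envelope is [{lo}, {hi}]",
            ProtocolWarning, stacklevel=2,
        )
    return Mask3D(data, affine, label)


def trace_habenula(
    vol: Volume3D,
    posterior_landmarks: list[SliceLandmarks],
    anterior_slices: list[tuple[float, IntensityReferences]],
    posterior_y: float,
    anterior_y: float,
    side: str,
    max_extent: float = 4.0,
) -> Mask3D:
    """Full per-hemisphere tracing: geometric posterior slices, intensity
    region growing on anterior slices, assembly with span validation."""
    masks: list[Mask3D] = []
    for lm in posterior_landmarks:
        if lm.side != side:
            raise ValueError(f"landmark at y={lm.y_mm} is for the {lm.side} side")
        poly = posterior_slice_polygon(lm)
        masks.append(rasterize_polygon(poly, vol, lm.y_mm))
    for y_mm, refs in anterior_slices:
        masks.append(anterior_slice_roi(vol, y_mm, refs, max_extent=max_extent))
    return assemble_roi(masks, posterior_y, anterior_y, label=f"{side}_habenula")


def read_slice_landmarks(path: str | Path) -> list[SliceLandmarks]:
    """Load per-slice landmarks from JSON: a list of objects with keys
    side, y_mm, A, B, C (in-plane [x, z] mm)."""
    with open(path) as fh:
        rows = json.load(fh)
    return [
        SliceLandmarks(r["y_mm"], tuple(r["A"]), tuple(r["B"]), tuple(r["C"]),
                       r["side"])
        for r in rows
    ]
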