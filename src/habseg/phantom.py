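"""Synthetic epithalamic phantoms with ground truth.

The generator emulates the T1-weighted appearance of the epithalamic
neighbourhood: a bright habenula pair protruding into the dark CSF of
the third ventricle, darker MD thalamus laterally, the posterior /
habenular commissure band ventrally, the pineal stalk posteriorly and
the stria medullaris antero-dorsally.  All geometry is analytic in
world mm on an AC–PC-aligned grid, so exact ground-truth masks,
landmarks and volumes are available for every structure.

The habenula cross-section transitions from pyramidal (triangular) in
posterior slices to oblong in anterior slices, matching its appearance
on coronal sections.  Posterior-slice triangles are generated directly
from the same A/B/C landmark construction the delineation protocol
uses, so the phantom also supplies ground-truth per-slice landmarks.

The lateral width of the cross-sections is calibrated numerically so
the voxelized per-side volume matches ``habenula_volume_target``
(default 30 mm^3, the human in-vivo scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .delineate import IntensityReferences, SliceLandmarks, points_in_triangle
from .exceptions import ConfigurationError, ProtocolWarning
from .io_space import Mask3D, Volume3D
from .reorient import AcpcLandmarks

__all__ = [
    "LABELS",
    "PhantomSpec",
    "PhantomOutput",
    "generate_phantom",
    "simulate_rater",
    "slice_span_simulation",
    "trace_with_true_landmarks",
]

#: integer codes of the label map
LABELS = {
    "background": 0,
    "csf": 1,
    "md_thalamus": 2,
    "habenula_left": 3,
    "habenula_right": 4,
    "pc_hc": 5,
    "pineal": 6,
    "stria_medullaris": 7,
}

# fixed anatomy-scale shape constants (mm)
_MEDIAL_WALL_X = 0.7       # third-ventricle half-width / habenula medial wall
_TRIANGLE_HEIGHT = 4.0     # posterior pyramidal cross-section height
_OBLONG_HEIGHT = 2.6       # anterior oblong cross-section height
_OBLONG_Z_OFFSET = 0.4     # anterior sections sit slightly dorsal
_Z_BASE = 1.5              # ventral habenula boundary above the AC–PC line
_Z_RISE = 0.8              # dorsal shift across the A–P extent


def _default_intensities() -> dict[str, float]:
    return {"csf": 0.3, "md": 1.0, "habenula": 1.3, "white": 1.6, "pineal": 1.1}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic epithalamic volume.

    Defaults follow the imaging protocol (0.77 mm isotropic voxels) and
    human habenula anatomy (~30 mm^3 per side, ~2.5 mm A–P extent).
    ``seed`` is required; generation is fully deterministic given it.
    """

    seed: int
    grid_shape: tuple[int, int, int] = (64, 80, 64)
    voxel_size: float = 0.77
    habenula_volume_target: float = 30.0
    ap_extent: float = 2.5
    intensities: dict[str, float] = field(default_factory=_default_intensities)
    noise_sigma: float = 0.03
    acpc_distance: float = 25.0
    hab_posterior_y: float = -24.7

    def __post_init__(self) -> None:
        if self.habenula_volume_target <= 0:
            raise ConfigurationError("habenula_volume_target must be positive")
        if not 0.5 < self.ap_extent < 6.0:
            raise ConfigurationError("ap_extent must lie in (0.5, 6) mm")
        i = self.intensities
        if not i["csf"] < i["md"] < i["habenula"]:
            raise ConfigurationError(
                "intensity ordering CSF < MD < habenula is required"
            )
        if self.voxel_size <= 0 or self.noise_sigma < 0:
            raise ConfigurationError("voxel_size > 0 and noise_sigma >= 0 required")


@dataclass
class PhantomOutput:
    """Image, label map and complete ground truth for one phantom."""

    image: Volume3D
    labels: Volume3D
    acpc: AcpcLandmarks
    slice_landmarks: list[SliceLandmarks]
    true_masks: dict[str, Mask3D]
    true_volumes: dict[str, float]
    posterior_y: float
    anterior_y: float
    anterior_slice_y: list[float]
    spec: PhantomSpec

    def intensity_references(self, side: str) -> list[tuple[float, IntensityReferences]]:
        """Per-anterior-slice (y_mm, refs) pairs for region growing.

        CSF and MD reference means are sampled from the labelled voxels
        of the image itself; seeds are placed at the truth-mask centroid
        of each anterior slice.
        """
        img = np.asarray(self.image.data, dtype=float)
        lab = np.asarray(self.labels.data)
        csf_mean = float(img[lab == LABELS["csf"]].mean())
        md_mean = float(img[lab == LABELS["md_thalamus"]].mean())
        truth = self.true_masks[side].data
        a = self.image.affine
        out = []
        for y in self.anterior_slice_y:
            j = int(round((y - a[1, 3]) / a[1, 1]))
            ii, kk = np.nonzero(truth[:, j, :])
            seed = (int(round(ii.mean())), int(round(kk.mean())))
            out.append((y, IntensityReferences(csf_mean, md_mean, seed)))
        return out


def _slab(coord: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (coord >= lo) & (coord <= hi)


def _side_landmarks(y: float, z0: float, width: float, side: str) -> SliceLandmarks:
    s = 1.0 if side == "right" else -1.0
    A = (s * _MEDIAL_WALL_X, z0)
    B = (s * (_MEDIAL_WALL_X + 0.5), z0 + _TRIANGLE_HEIGHT)
    apex = (s * (_MEDIAL_WALL_X + width), z0)
    # C on the B->apex line, extended ventrally past the apex
    C = (B[0] + 1.5 * (apex[0] - B[0]), B[1] + 1.5 * (apex[1] - B[1]))
    return SliceLandmarks(y, A, B, C, side)


def _hab_slice_mask(xs: np.ndarray, zs: np.ndarray, z0: float, width: float,
                    side: str, posterior: bool) -> np.ndarray:
    """In-plane habenula cross-section on the voxel-centre lattice."""
    s = 1.0 if side == "right" else -1.0
    if posterior:
        tri = np.array(
            [[s * _MEDIAL_WALL_X, z0],
             [s * (_MEDIAL_WALL_X + 0.5), z0 + _TRIANGLE_HEIGHT],
             [s * (_MEDIAL_WALL_X + width), z0]]
        )
        return points_in_triangle(xs[:, None], zs[None, :], tri)
    x_lo, x_hi = sorted((s * _MEDIAL_WALL_X, s * (_MEDIAL_WALL_X + width)))
    z_lo = z0 + _OBLONG_Z_OFFSET
    return (
        _slab(xs, x_lo, x_hi)[:, None]
        & _slab(zs, z_lo, z_lo + _OBLONG_HEIGHT)[None, :]
    )


def _occupied_slices(spec: PhantomSpec, ys: np.ndarray) -> np.ndarray:
    y0 = spec.hab_posterior_y
    return np.nonzero((ys >= y0) & (ys < y0 + spec.ap_extent))[0]


def _z0_for(spec: PhantomSpec, s: int, n_occ: int) -> float:
    return _Z_BASE + _Z_RISE * (s / max(n_occ - 1, 1))


def _count_hab_voxels(spec: PhantomSpec, xs, zs, occ, n_post, width) -> int:
    total = 0
    for s in range(len(occ)):
        z0 = _z0_for(spec, s, len(occ))
        total += int(
            _hab_slice_mask(xs, zs, z0, width, "right", s < n_post).sum()
        )
    return total


def _calibrate_width(spec: PhantomSpec, xs, zs, occ, n_post) -> float:
    """Bisect the lateral width so the voxelized volume hits the target."""
    n_ant = len(occ) - n_post
    vox_vol = spec.voxel_size**3
    target_n = spec.habenula_volume_target / vox_vol
    per_mm = n_post * 0.5 * _TRIANGLE_HEIGHT + n_ant * _OBLONG_HEIGHT
    w0 = spec.habenula_volume_target / (spec.voxel_size * per_mm)
    lo, hi = 0.4 * w0, 2.5 * w0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _count_hab_voxels(spec, xs, zs, occ, n_post, mid) < target_n:
            lo = mid
        else:
            hi = mid
    # evaluate just off the bisection jump so no cross-section edge sits
    # exactly on a voxel-centre coordinate (keeps inclusion float-robust)
    candidates = (lo - 1e-3, hi + 1e-3)
    return min(
        candidates,
        key=lambda w: abs(_count_hab_voxels(spec, xs, zs, occ, n_post, w) - target_n),
    )


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Build the phantom image, label map and ground truth.

    Deterministic given ``spec.seed``; Gaussian noise of
    ``spec.noise_sigma`` is added to the noise-free intensity model.
    """
    nx, ny, nz = spec.grid_shape
    v = spec.voxel_size
    # x/z lattices are exactly antisymmetric about the midline so the two
    # hemispheres are bit-exact mirrors of each other
    xs = v * (np.arange(nx) - (nx - 1) / 2.0)
    ys = v * (np.arange(ny) - round(0.8 * ny))
    zs = v * (np.arange(nz) - (nz - 1) / 2.0)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = (xs[0], ys[0], zs[0])

    occ = _occupied_slices(spec, ys)
    if occ.size < 2:
        raise ConfigurationError(
            "habenula spans fewer than two coronal slices on this grid"
        )
    n_post = int(np.ceil(occ.size / 2))
    width = _calibrate_width(spec, xs, zs, occ, n_post)

    y0 = spec.hab_posterior_y
    z_top = _Z_BASE + _Z_RISE + _TRIANGLE_HEIGHT
    need = {
        "x": (-(_MEDIAL_WALL_X + width + 2), _MEDIAL_WALL_X + width + 2),
        "y": (y0 - 1.6, y0 + spec.ap_extent + 1.2),
        "z": (_Z_BASE - 2.5, z_top + 1.5),
    }
    fov = {"x": (xs[0], xs[-1]), "y": (ys[0], ys[-1]), "z": (zs[0], zs[-1])}
    for ax, (lo, hi) in need.items():
        if lo < fov[ax][0] or hi > fov[ax][1]:
            raise ConfigurationError(
                f"grid too small along {ax}: need [{lo:.1f}, {hi:.1f}] mm, "
                f"have [{fov[ax][0]:.1f}, {fov[ax][1]:.1f}] mm"
            )

    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    lab = np.zeros(spec.grid_shape, dtype=np.int16)

    md = (
        (np.abs(X) >= _MEDIAL_WALL_X) & (np.abs(X) <= 13.0)
        & _slab(Y, -29.0, -15.0) & _slab(Z, -2.5, 9.0)
    )
    lab[md] = LABELS["md_thalamus"]
    csf = (np.abs(X) <= _MEDIAL_WALL_X) & _slab(Y, -30.0, -8.0) & _slab(Z, -4.0, 8.0)
    lab[csf] = LABELS["csf"]
    pineal = (
        (np.abs(X) <= 2.3) & _slab(Y, y0 - 4.2, y0 - 0.3) & _slab(Z, 0.5, 4.5)
    )
    lab[pineal] = LABELS["pineal"]
    pc_y_hi = ys[occ[n_post - 1]] + v / 2.0
    pc = (np.abs(X) <= 3.0) & _slab(Y, y0 - 1.5, pc_y_hi) & _slab(Z, -0.5, 1.3)
    lab[pc] = LABELS["pc_hc"]
    stria = (
        (np.abs(X) >= _MEDIAL_WALL_X) & (np.abs(X) <= 2.7)
        & _slab(Y, -23.6, -15.5) & _slab(Z, z_top + 1.0, z_top + 2.5)
    )
    lab[stria] = LABELS["stria_medullaris"]

    slice_lms: list[SliceLandmarks] = []
    masks = {side: np.zeros(spec.grid_shape, dtype=np.uint8) for side in ("left", "right")}
    anterior_slice_y: list[float] = []
    for s, j in enumerate(occ):
        z0 = _z0_for(spec, s, occ.size)
        posterior = s < n_post
        if posterior:
            for side in ("left", "right"):
                slice_lms.append(_side_landmarks(ys[j], z0, width, side))
        else:
            anterior_slice_y.append(float(ys[j]))
        right_inplane = _hab_slice_mask(xs, zs, z0, width, "right", posterior)
        masks["right"][:, j, :] = right_inplane.astype(np.uint8)
        masks["left"][:, j, :] = np.flip(right_inplane, axis=0).astype(np.uint8)
    lab[masks["left"].astype(bool)] = LABELS["habenula_left"]
    lab[masks["right"].astype(bool)] = LABELS["habenula_right"]

    inten = spec.intensities
    lut = np.zeros(8)
    lut[LABELS["csf"]] = inten["csf"]
    lut[LABELS["md_thalamus"]] = inten["md"]
    lut[LABELS["habenula_left"]] = inten["habenula"]
    lut[LABELS["habenula_right"]] = inten["habenula"]
    lut[LABELS["pc_hc"]] = inten["white"]
    lut[LABELS["stria_medullaris"]] = inten["white"]
    lut[LABELS["pineal"]] = inten["pineal"]
    img = lut[lab]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    vox_vol = v**3
    true_masks = {
        side: Mask3D(masks[side], affine, f"{side}_habenula") for side in masks
    }
    return PhantomOutput(
        image=Volume3D(img, affine),
        labels=Volume3D(lab, affine),
        acpc=AcpcLandmarks(
            ac=(0.0, 0.0, 0.0),
            pc=(0.0, -spec.acpc_distance, 0.0),
            midsagittal=(0.0, -12.0, 20.0),
        ),
        slice_landmarks=slice_lms,
        true_masks=true_masks,
        true_volumes={s: float(m.n_voxels * vox_vol) for s, m in true_masks.items()},
        posterior_y=float(ys[occ[0]]),
        anterior_y=float(ys[occ[-1]]),
        anterior_slice_y=anterior_slice_y,
        spec=spec,
    )


def trace_with_true_landmarks(phantom: PhantomOutput, side: str):
    """Run the full delineation pipeline on a phantom using its own
    ground-truth landmarks and intensity references."""
    from .delineate import trace_habenula

    lms = [lm for lm in phantom.slice_landmarks if lm.side == side]
    return trace_habenula(
        phantom.image,
        lms,
        phantom.intensity_references(side),
        phantom.posterior_y,
        phantom.anterior_y,
        side,
    )


def simulate_rater(
    truth: Mask3D, boundary_sd: float, bias: float, seed: int
) -> Mask3D:
    """A simulated human tracing of a ground-truth mask.

    The truth boundary is displaced by a smooth zero-mean random field
    of standard deviation ``boundary_sd`` mm plus a systematic
    dilation (+) / erosion (-) ``bias`` in mm: a voxel is included when
    its signed distance to the truth boundary is at most bias + field.
    Deterministic given ``seed``; the output is kept connected within
    each coronal slice (largest component).
    """
    if boundary_sd < 0:
        raise ValueError("boundary_sd must be non-negative")
    fg = truth.data.astype(bool)
    dims = np.linalg.norm(np.asarray(truth.affine)[:3, :3], axis=0)
    d_out = ndimage.distance_transform_edt(~fg, sampling=dims)
    d_in = ndimage.distance_transform_edt(fg, sampling=dims)
    # distances are to the nearest opposite voxel centre; shift by half a
    # voxel so zero sits on the mask boundary surface
    half = 0.5 * float(dims.mean())
    signed = np.where(fg, -(d_in - half), d_out - half)
    if boundary_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=fg.shape)
        field_ = ndimage.gaussian_filter(noise, sigma=1.5 / dims)
        sd = field_.std()
        field_ = field_ * (boundary_sd / sd) if sd > 0 else field_
    else:
        field_ = np.zeros_like(signed)
    out = signed <= bias + field_
    # keep each coronal slice a single connected blob, as a human tracing is
    cleaned = np.zeros_like(out)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for j in np.nonzero(out.any(axis=(0, 2)))[0]:
        plane = out[:, j, :]
        labels_, nlab = ndimage.label(plane, structure=structure)
        if nlab == 0:
            continue
        sizes = ndimage.sum_labels(plane, labels_, index=np.arange(1, nlab + 1))
        cleaned[:, j, :] = labels_ == (1 + int(np.argmax(sizes)))
    if not cleaned.any():
        warnings.warn(
            "perturbation removed every voxel; retaining one truth voxel",
            ProtocolWarning, stacklevel=2,
        )
        idx = np.argwhere(fg)
        if idx.size:
            i, j, k = idx[len(idx) // 2]
            cleaned[i, j, k] = True
    return Mask3D(cleaned.astype(np.uint8), truth.affine, truth.label)


def count_intersected_slabs(extent: float, offset: float, thickness: float) -> int:
    """Number of slabs [m*t, (m+1)*t) intersected by [offset, offset+extent)."""
    if extent <= 0 or thickness <= 0:
        raise ValueError("extent and thickness must be positive")
    return int(np.ceil((offset + extent) / thickness) - np.floor(offset / thickness))


def slice_span_simulation(
    ap_extent_range: tuple[float, float],
    slice_thickness: float,
    n_draws: int,
    seed: int,
) -> tuple[int, int]:
    """Min/max number of coronal slabs intersected by a structure.

    A–P extents are drawn uniformly from ``ap_extent_range`` and placed
    at uniform random offsets against a contiguous slab grid of the
    given thickness; the count of intersected slabs is recorded.
    """
    lo, hi = ap_extent_range
    if lo <= 0 or hi < lo:
        raise ValueError("ap_extent_range must be a positive interval")
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    extents = rng.uniform(lo, hi, size=n_draws)
    offsets = rng.uniform(0.0, slice_thickness, size=n_draws)
    t = slice_thickness
    counts = np.ceil((offsets + extents) / t) - np.floor(offsets / t)
    return int(counts.min()), int(counts.max())
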