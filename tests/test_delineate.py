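import numpy as np
import pytest

from habseg import (
    IntensityReferences,
    SliceLandmarks,
    SlicePolygon,
    Volume3D,
    anterior_slice_roi,
    apex_from_landmarks,
    assemble_roi,
    posterior_slice_polygon,
    rasterize_polygon,
)
from habseg.delineate import points_in_triangle
from habseg.exceptions import (
    ContiguityError,
    DegeneratePolygonError,
    LeakageError,
    NoIntersectionError,
    ProtocolWarning,
)
from habseg.io_space import Mask3D

REF = dict(y_mm=-24.0, A=(0.0, 0.0), B=(0.5, 2.0), C=(4.5, -6.0), side="right")


def _grid(shape=(40, 10, 40), voxel=0.77, origin=(-8.0, -28.0, -8.0)):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = origin
    return Volume3D(np.zeros(shape), affine)


class TestApex:
    def test_analytic_intersection(self):
        apex = apex_from_landmarks(SliceLandmarks(**REF))
        assert np.allclose(apex, (1.5, 0.0))

    def test_c_at_a_height_gives_c_itself(self):
        lm = SliceLandmarks(-24.0, (0, 0), (1, 1), (2, 0), "right")
        assert np.allclose(apex_from_landmarks(lm), (2.0, 0.0))

    def test_horizontal_bc_has_no_intersection(self):
        lm = SliceLandmarks(-24.0, (0, 0), (1, 1), (3, 1 - 1e-9), "right")
        with pytest.raises(NoIntersectionError):
            apex_from_landmarks(lm)

    def test_apex_medial_to_a_rejected(self):
        # B-C line slopes back toward the midline: apex lands medial to A
        lm = SliceLandmarks(-24.0, (2.0, 0.0), (2.5, 2.0), (1.0, -4.0), "right")
        with pytest.raises(DegeneratePolygonError):
            apex_from_landmarks(lm)


class TestPolygon:
    def test_triangle_and_shoelace_area(self):
        poly = posterior_slice_polygon(SliceLandmarks(**REF))
        assert np.allclose(poly.vertices, [(0, 0), (0.5, 2), (1.5, 0)])
        assert poly.area == pytest.approx(1.5)

    def test_mirrored_landmarks_mirror_polygon(self):
        lm = SliceLandmarks(**REF)
        poly = posterior_slice_polygon(lm)
        mpoly = posterior_slice_polygon(lm.mirrored())
        assert np.allclose(mpoly.vertices * np.array([-1, 1]), poly.vertices)
        assert mpoly.area == pytest.approx(poly.area)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            SliceLandmarks(-24.0, (0, 0), (0.0, 0.05), (4.5, -6), "right")

    def test_zero_area_polygon_cannot_be_constructed(self):
        with pytest.raises(DegeneratePolygonError):
            SlicePolygon(np.array([(0, 0), (1, 1), (2, 2)]), "right")

    def test_ordering_invariants_enforced(self):
        with pytest.raises(DegeneratePolygonError):
            SliceLandmarks(-24.0, (0.0, 2.0), (0.5, 0.0), (4.5, -6.0), "right")


class TestRasterize:
    def test_matches_hand_counted_lattice(self):
        # unit-spaced lattice at integer coordinates: triangle (0,0),(0.5,2),(1.5,0)
        vol = _grid(shape=(8, 3, 8), voxel=1.0, origin=(-2.0, -25.0, -2.0))
        poly = posterior_slice_polygon(SliceLandmarks(**REF))
        mask = rasterize_polygon(poly, vol, -24.0)
        fg = {(x, z) for x, _, z in np.argwhere(mask.data)}
        # voxel centres x,z in {-2..5}; at z=0 the triangle spans x in [0, 1.5],
        # at z=1 it spans [0.25, 1.0]: world points (0,0), (1,0), (1,1)
        expected = {(2, 2), (3, 2), (3, 3)}
        assert fg == expected

    def test_refinement_limit_area_ratio(self):
        lm = SliceLandmarks(**REF)
        big = SliceLandmarks(-24.0, (0, 0), (1.0, 4.0), (9.0, -12.0), "right")
        vol = _grid(shape=(240, 3, 240), voxel=0.1, origin=(-6.0, -24.1, -6.0))
        n_small = rasterize_polygon(posterior_slice_polygon(lm), vol, -24.0).n_voxels
        n_big = rasterize_polygon(posterior_slice_polygon(big), vol, -24.0).n_voxels
        # big triangle is the small one scaled x2 in both in-plane axes
        assert n_big / n_small == pytest.approx(4.0, rel=0.10)

    def test_polygon_outside_fov_warns_empty(self):
        vol = _grid()
        lm = SliceLandmarks(-24.0, (100.0, 0.0), (100.5, 2.0), (104.5, -6.0), "right")
        with pytest.warns(ProtocolWarning):
            mask = rasterize_polygon(posterior_slice_polygon(lm), vol, -24.0)
        assert mask.n_voxels == 0

    def test_mirror_symmetry_exact(self, rng):
        """Reflecting landmarks in x=0 and switching side flips the mask."""
        # lattice chosen exactly antisymmetric in binary floating point
        vol = _grid(shape=(40, 6, 40), voxel=0.5, origin=(-0.5 * 39 / 2, -26.0, -9.0))
        done = 0
        while done < 20:
            A = (rng.uniform(0, 2), rng.uniform(-3, 3))
            B = (A[0] + rng.uniform(-1, 2), A[1] + rng.uniform(1, 4))
            C = (B[0] + rng.uniform(1, 6), B[1] - rng.uniform(2, 8))
            try:
                lm = SliceLandmarks(-24.5, A, B, C, "right")
                poly = posterior_slice_polygon(lm)
                mpoly = posterior_slice_polygon(lm.mirrored())
            except (DegeneratePolygonError, NoIntersectionError):
                continue
            m = rasterize_polygon(poly, vol, -24.5)
            mm = rasterize_polygon(mpoly, vol, -24.5)
            assert np.array_equal(mm.data, np.flip(m.data, axis=0))
            done += 1


class TestAnterior:
    def test_recovers_phantom_truth_exactly(self, noise_free_phantom):
        ph = noise_free_phantom
        for y, refs in ph.intensity_references("right"):
            roi = anterior_slice_roi(ph.image, y, refs)
            j = np.nonzero(roi.data.any(axis=(0, 2)))[0][0]
            truth_slice = ph.true_masks["right"].data[:, j, :]
            assert np.array_equal(roi.data[:, j, :], truth_slice)

    def test_seed_in_csf_warns_and_returns_seed_only(self, noise_free_phantom):
        ph = noise_free_phantom
        y, refs = ph.intensity_references("right")[0]
        csf_seed = IntensityReferences(refs.csf_mean, refs.md_mean,
                                       (ph.image.shape[0] // 2, refs.seed[1]))
        with pytest.warns(ProtocolWarning):
            roi = anterior_slice_roi(ph.image, y, csf_seed)
        assert roi.n_voxels == 1

    def test_uniform_image_leaks(self):
        vol = _grid(shape=(30, 3, 30))
        vol.data[:] = 2.0
        refs = IntensityReferences(0.3, 1.0, (15, 15))
        with pytest.raises(LeakageError):
            anterior_slice_roi(vol, -25.0, refs)

    def test_inverted_contrast_references_rejected(self):
        with pytest.raises(ValueError):
            IntensityReferences(csf_mean=1.2, md_mean=1.0, seed=(0, 0))


class TestAssemble:
    @staticmethod
    def _slice_mask(vol, j):
        data = np.zeros(vol.shape, dtype=np.uint8)
        data[5:8, j, 5:8] = 1
        return Mask3D(data, vol.affine)

    def test_contiguous_slices_assemble_quietly(self):
        vol = _grid()
        masks = [self._slice_mask(vol, j) for j in (3, 4, 5, 6)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", ProtocolWarning)
            roi = assemble_roi(masks, -26.0, -23.0)
        assert np.count_nonzero(roi.data.any(axis=(0, 2))) == 4

    def test_span_outside_protocol_envelope_warns(self):
        vol = _grid()
        masks = [self._slice_mask(vol, j) for j in (3, 4)]
        with pytest.warns(ProtocolWarning):
            assemble_roi(masks, -26.0, -24.5)

    def test_gap_in_slices_is_an_error(self):
        vol = _grid()
        masks = [self._slice_mask(vol, 3), self._slice_mask(vol, 5)]
        with pytest.raises(ContiguityError):
            assemble_roi(masks, -26.0, -23.0)


def test_points_in_triangle_includes_boundary():
    tri = np.array([(0.0, 0.0), (0.0, 2.0), (2.0, 0.0)])
    px = np.array([0.0, 1.0, 1.0, 1.01])
    pz = np.array([1.0, 1.0, 0.0, 1.0])
    assert points_in_triangle(px, pz, tri).tolist() == [True, True, True, False]
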