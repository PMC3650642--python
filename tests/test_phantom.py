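import numpy as np
import pytest

from habseg import (
    LABELS,
    PhantomSpec,
    generate_phantom,
    mask_volume,
    simulate_rater,
    slice_span_simulation,
    trace_with_true_landmarks,
)
from habseg.exceptions import ConfigurationError, ProtocolWarning
from habseg.phantom import count_intersected_slabs


class TestGenerate:
    def test_deterministic_given_seed(self):
        a = generate_phantom(PhantomSpec(seed=21))
        b = generate_phantom(PhantomSpec(seed=21))
        assert np.array_equal(np.asarray(a.image.data), np.asarray(b.image.data))
        assert np.array_equal(np.asarray(a.labels.data), np.asarray(b.labels.data))
        c = generate_phantom(PhantomSpec(seed=22))
        assert not np.array_equal(np.asarray(a.image.data), np.asarray(c.image.data))

    def test_truth_volume_hits_target_within_one_voxel(self, noise_free_phantom):
        vox = noise_free_phantom.spec.voxel_size ** 3
        for side in ("left", "right"):
            tv = noise_free_phantom.true_volumes[side]
            assert tv == pytest.approx(
                mask_volume(noise_free_phantom.true_masks[side])
            )
            assert abs(tv - noise_free_phantom.spec.habenula_volume_target) <= vox

    def test_hemispheres_are_exact_mirrors(self, noise_free_phantom):
        left = noise_free_phantom.true_masks["left"].data
        right = noise_free_phantom.true_masks["right"].data
        assert np.array_equal(left, np.flip(right, axis=0))

    def test_habenulae_disjoint_with_midline_csf_column(self, noise_free_phantom):
        lab = np.asarray(noise_free_phantom.labels.data)
        left = lab == LABELS["habenula_left"]
        right = lab == LABELS["habenula_right"]
        assert not (left & right).any()
        # at every coronal/axial position the habenula occupies, the two
        # central voxel columns are third-ventricle CSF
        nx = lab.shape[0]
        jk = np.argwhere(right.any(axis=0))
        assert jk.size > 0
        for j, k in jk:
            assert np.all(lab[nx // 2 - 1: nx // 2 + 1, j, k] == LABELS["csf"])

    def test_habenula_touches_csf_medially_and_md_laterally(self, noise_free_phantom):
        lab = np.asarray(noise_free_phantom.labels.data)
        right = lab == LABELS["habenula_right"]
        medial_nb = np.zeros_like(right)
        medial_nb[:-1] = right[1:]  # voxel just medial (-x) of a habenula voxel
        lateral_nb = np.zeros_like(right)
        lateral_nb[1:] = right[:-1]
        assert (lab[medial_nb & ~right] == LABELS["csf"]).any()
        assert (lab[lateral_nb & ~right] == LABELS["md_thalamus"]).any()

    def test_habenula_brighter_than_md_without_noise(self, noise_free_phantom):
        img = np.asarray(noise_free_phantom.image.data)
        lab = np.asarray(noise_free_phantom.labels.data)
        hab = img[(lab == LABELS["habenula_left"]) | (lab == LABELS["habenula_right"])]
        md_max = img[lab == LABELS["md_thalamus"]].max()
        assert np.all(hab > md_max)

    def test_grid_too_small_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            generate_phantom(PhantomSpec(seed=1, grid_shape=(10, 80, 10)))

    def test_invalid_intensity_ordering_rejected(self):
        bad = {"csf": 1.2, "md": 1.0, "habenula": 1.3, "white": 1.6, "pineal": 1.1}
        with pytest.raises(ConfigurationError):
            PhantomSpec(seed=1, intensities=bad)


class TestPipelineRecovery:
    def test_tracing_true_landmarks_recovers_truth(self, noise_free_phantom):
        for side in ("left", "right"):
            traced = trace_with_true_landmarks(noise_free_phantom, side)
            tv = noise_free_phantom.true_volumes[side]
            assert abs(mask_volume(traced) - tv) / tv <= 0.15

    def test_finer_grid_reduces_voxelization_error(self):
        ph = generate_phantom(
            PhantomSpec(seed=4, noise_sigma=0.0, voxel_size=0.3,
                        grid_shape=(160, 208, 160))
        )
        traced = trace_with_true_landmarks(ph, "right")
        tv = ph.true_volumes["right"]
        assert abs(mask_volume(traced) - tv) / tv <= 0.05


class TestSimulateRater:
    def test_zero_perturbation_returns_truth(self, noise_free_phantom):
        truth = noise_free_phantom.true_masks["right"]
        out = simulate_rater(truth, 0.0, 0.0, seed=3)
        assert np.array_equal(out.data, truth.data)

    def test_one_voxel_dilation_bias_grows_mask(self, noise_free_phantom):
        truth = noise_free_phantom.true_masks["right"]
        out = simulate_rater(truth, 0.0, 0.77, seed=3)
        assert out.n_voxels > truth.n_voxels
        assert np.all(truth.data <= out.data)

    def test_deterministic_given_seed(self, noise_free_phantom):
        truth = noise_free_phantom.true_masks["right"]
        a = simulate_rater(truth, 0.5, 0.0, seed=9)
        b = simulate_rater(truth, 0.5, 0.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_annihilating_bias_warns_and_keeps_seed_voxel(self, noise_free_phantom):
        truth = noise_free_phantom.true_masks["right"]
        with pytest.warns(ProtocolWarning):
            out = simulate_rater(truth, 0.0, -50.0, seed=3)
        assert out.n_voxels == 1

    def test_slices_stay_connected(self, noise_free_phantom):
        from scipy import ndimage

        truth = noise_free_phantom.true_masks["right"]
        out = simulate_rater(truth, 0.6, 0.0, seed=17)
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for j in np.nonzero(out.data.any(axis=(0, 2)))[0]:
            _, nlab = ndimage.label(out.data[:, j, :], structure=structure)
            assert nlab == 1


def test_two_simulated_raters_reproduce_closed_form_icc():
    """Across 200 phantom subjects with ~4 mm^3 between-subject volume SD,
    two independent simulated raters (0.4 mm boundary noise) give an
    ICC(2,1) within 0.05 of the variance-ratio closed form, with the
    rater error variance measured empirically against ground truth."""
    from habseg import RaterTable, icc_2_1

    rng = np.random.default_rng(42)
    truths, ratings = [], []
    for _ in range(200):
        target = float(np.clip(rng.normal(30.0, 4.0), 22.0, 38.0))
        ph = generate_phantom(
            PhantomSpec(seed=int(rng.integers(1, 2**31 - 1)), noise_sigma=0.0,
                        habenula_volume_target=target, grid_shape=(48, 80, 48))
        )
        truth = ph.true_masks["right"]
        truths.append(mask_volume(truth))
        ratings.append(
            [mask_volume(simulate_rater(truth, 0.4, 0.0,
                                        int(rng.integers(1, 2**31 - 1))))
             for _ in range(2)]
        )
    truths = np.asarray(truths)
    ratings = np.asarray(ratings)
    est = icc_2_1(RaterTable(ratings)).estimate
    resid = ratings - truths[:, None]
    sigma_e = np.std(resid - resid.mean())
    sigma_b = np.std(truths, ddof=1)
    closed = sigma_b**2 / (sigma_b**2 + sigma_e**2)
    assert est == pytest.approx(closed, abs=0.05)


class TestSliceSpanSimulation:
    def test_analytic_slab_counting(self):
        assert count_intersected_slabs(1.54, 0.0, 0.77) == 2
        assert count_intersected_slabs(0.5, 0.5, 0.77) == 2

    def test_protocol_extent_range_gives_three_to_five_slices(self):
        assert slice_span_simulation((2.0, 3.0), 0.77, 1000, seed=5) == (3, 5)

    def test_halving_thickness_roughly_doubles_span(self):
        lo, hi = slice_span_simulation((2.0, 3.0), 0.385, 2000, seed=5)
        assert 5 <= lo <= 7
        assert 8 <= hi <= 10

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            slice_span_simulation((0.0, 1.0), 0.77, 10, seed=1)
        with pytest.raises(ValueError):
            slice_span_simulation((1.0, 2.0), 0.77, 0, seed=1)
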