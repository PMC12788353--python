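import dataclasses

import numpy as np
import pytest

from specspat import (LabelMap, ProbabilityMap, RefineParams, RefineState,
                      build_kernels, class_energies, class_energy, corrupt_seed,
                      icm_sweep, make_scene, one_hot_seed, refine,
                      spatial_kernel, spectral_kernel, update_probabilities,
                      weak_label_feedback, SceneSpec, KernelStack)
from specspat.refine import _Grid

from oracles import (all_energies_oracle, spectral_kernel_oracle, sweep_oracle)


# ---------------------------------------------------------------------------
# helpers


def uniform_kernels(m, n, r):
    """All-ones kernel stack (center excluded) for hand-checkable energies."""
    s = np.ones((2 * r + 1, 2 * r + 1))
    s[r, r] = 0.0
    w = np.ones((m, n, 2 * r + 1, 2 * r + 1))
    return KernelStack(S=s, W=w, r=r)


def one_hot_state(labels_2d, class_ids=(1, 2)):
    lm = LabelMap(np.asarray(labels_2d, dtype=np.int32))
    pm = one_hot_seed(lm, class_ids=np.asarray(class_ids))
    return RefineState(labels=lm.labels, probs=pm)


def random_state(rng, m=7, n=7, k=3, background=0.1):
    """Random labels/probabilities with some background pixels."""
    labels = rng.integers(1, k + 1, size=(m, n)).astype(np.int32)
    bg = rng.random((m, n)) < background
    labels[bg] = 0
    coords = np.argwhere(labels > 0)
    probs = rng.random((len(coords), k))
    probs /= probs.sum(axis=1, keepdims=True)
    pm = ProbabilityMap(probs=probs, class_ids=np.arange(1, k + 1),
                        pixel_coords=coords)
    return RefineState(labels=labels, probs=pm)


def grid_arrays(state, kernels):
    g = _Grid(state, kernels)
    return g.labels_int, g.p_raster, g.valid


# ---------------------------------------------------------------------------
# kernels


class TestSpatialKernel:
    def test_center_is_one_before_exclusion(self):
        s = spatial_kernel(2, 1.3, exclude_center=False)
        assert s[2, 2] == 1.0

    def test_center_excluded_by_default(self):
        assert spatial_kernel(2, 1.3)[2, 2] == 0.0

    def test_unit_offset_value(self):
        # exp(-1 / (2 * 1.3^2)) = exp(-1/3.38)
        s = spatial_kernel(1, 1.3)
        assert s[1 + 1, 1 + 0] == pytest.approx(np.exp(-1 / 3.38), rel=1e-12)
        assert s[1 + 1, 1 + 0] == pytest.approx(0.7439, abs=1e-4)

    def test_negation_symmetry(self):
        s = spatial_kernel(4, 1.3, exclude_center=False)
        np.testing.assert_allclose(s, s[::-1, ::-1])

    def test_errors(self):
        with pytest.raises(ValueError):
            spatial_kernel(0, 1.0)
        with pytest.raises(ValueError):
            spatial_kernel(1, 0.0)


class TestSpectralKernel:
    def test_identical_features_give_one(self):
        feats = np.full((4, 4, 3), 0.7)
        padded = np.pad(feats, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
        w = spectral_kernel(padded, 1, sigma_w=1.3)
        np.testing.assert_array_equal(w, 1.0)

    def test_known_distance_value(self):
        # ||fi - fj||^2 = 3.38 with sigma_w = 1.3 -> exp(-1)
        feats = np.zeros((1, 2, 1))
        feats[0, 1, 0] = np.sqrt(3.38)
        padded = np.pad(feats, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
        w = spectral_kernel(padded, 1, sigma_w=1.3)
        assert w[0, 0, 1, 2] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_matches_pair_loop_oracle(self, rng):
        feats = rng.random((6, 6, 2))
        padded = np.pad(feats, ((2, 2), (2, 2), (0, 0)), mode="symmetric")
        w = spectral_kernel(padded, 2, sigma_w=0.9)
        np.testing.assert_allclose(w, spectral_kernel_oracle(feats, 2, 0.9),
                                   atol=1e-12)

    def test_rejects_nonfinite(self):
        bad = np.full((4, 4, 1), np.nan)
        with pytest.raises(ValueError, match="finite"):
            spectral_kernel(bad, 1, 1.0)


# ---------------------------------------------------------------------------
# energies


class TestClassEnergy:
    def test_hand_computed_homogeneous_patch(self):
        state = one_hot_state(np.ones((3, 3)))
        ks = uniform_kernels(3, 3, 1)
        params = RefineParams(r=1, beta=0.4)
        assert class_energy(state, (1, 1), 1, ks, params) == pytest.approx(-11.2)
        assert class_energy(state, (1, 1), 2, ks, params) == pytest.approx(3.2)

    def test_beta_zero_reduces_to_spectral_support(self, rng):
        state = random_state(rng, 5, 5, 2, background=0.0)
        params = RefineParams(r=1, beta=0.0)
        feats = rng.random((5, 5, 2))
        ks = build_kernels(feats, params)
        e = class_energies(state, ks, params)
        lab_int, p, valid = grid_arrays(state, ks)
        expect = all_energies_oracle(lab_int, p, valid, ks.W, np.zeros_like(ks.S),
                                     0.0, "eq11_grouped", 1)
        np.testing.assert_allclose(e, expect, atol=1e-12)

    @pytest.mark.parametrize("form", ["eq11_grouped", "eq9"])
    def test_matches_triple_loop_oracle(self, form):
        rng = np.random.default_rng(42)
        for trial in range(3):
            state = random_state(rng)
            params = RefineParams(r=2, sigma_s=1.1, sigma_w=0.8, beta=0.35,
                                  potential_form=form)
            feats = rng.random((7, 7, 2))
            ks = build_kernels(feats, params)
            e = class_energies(state, ks, params)
            lab_int, p, valid = grid_arrays(state, ks)
            expect = all_energies_oracle(lab_int, p, valid, ks.W, ks.S,
                                         params.beta, form, 2)
            np.testing.assert_allclose(e, expect, atol=1e-10)

    def test_border_pixels_match_explicit_reflection(self, rng):
        state = random_state(rng, 5, 6, 3, background=0.15)
        params = RefineParams(r=2, sigma_s=1.3, sigma_w=1.3, beta=0.4)
        feats = rng.random((5, 6, 2))
        ks = build_kernels(feats, params)
        e = class_energies(state, ks, params)
        lab_int, p, valid = grid_arrays(state, ks)
        expect = all_energies_oracle(lab_int, p, valid, ks.W, ks.S, 0.4,
                                     "eq11_grouped", 2)
        # explicitly compare the border ring
        np.testing.assert_allclose(e[0, :, :], expect[0, :, :], atol=1e-10)
        np.testing.assert_allclose(e[:, 0, :], expect[:, 0, :], atol=1e-10)
        np.testing.assert_allclose(e[-1, :, :], expect[-1, :, :], atol=1e-10)
        np.testing.assert_allclose(e[:, -1, :], expect[:, -1, :], atol=1e-10)

    def test_unknown_class_rejected(self):
        state = one_hot_state(np.ones((3, 3)))
        ks = uniform_kernels(3, 3, 1)
        with pytest.raises(ValueError, match="unknown class"):
            class_energy(state, (1, 1), 9, ks, RefineParams(r=1))


# ---------------------------------------------------------------------------
# ICM sweep


class TestIcmSweep:
    def test_constant_scene_is_fixed_point(self):
        state = one_hot_state(np.full((4, 4), 2))
        ks = uniform_kernels(4, 4, 1)
        out = icm_sweep(state, ks, RefineParams(r=1, beta=0.4))
        np.testing.assert_array_equal(out.labels, state.labels)

    def test_flipped_interior_pixel_restored(self):
        labels = np.ones((5, 5), dtype=np.int32)
        labels[2, 2] = 2
        # probabilities still one-hot for class 1 everywhere
        pm = one_hot_seed(LabelMap(np.ones((5, 5), dtype=np.int32)),
                          class_ids=np.array([1, 2]))
        state = RefineState(labels=labels, probs=pm)
        out = icm_sweep(state, uniform_kernels(5, 5, 1),
                        RefineParams(r=1, beta=0.4))
        assert out.labels[2, 2] == 1
        np.testing.assert_array_equal(out.labels, 1)

    @pytest.mark.parametrize("form", ["eq11_grouped", "eq9"])
    def test_matches_oracle_sweep(self, form):
        rng = np.random.default_rng(5)
        state = random_state(rng, 5, 5, 3, background=0.1)
        params = RefineParams(r=1, sigma_s=1.0, sigma_w=0.7, beta=0.3,
                              potential_form=form)
        feats = rng.random((5, 5, 2))
        ks = build_kernels(feats, params)
        out = icm_sweep(state, ks, params)
        lab_int, p, valid = grid_arrays(state, ks)
        expect_int = sweep_oracle(lab_int, p, valid, ks.W, ks.S,
                                  params.beta, form, 1)
        got = grid_arrays(RefineState(labels=out.labels, probs=state.probs), ks)[0]
        np.testing.assert_array_equal(got, expect_int)

    def test_clamped_pixels_keep_labels(self):
        labels = np.ones((5, 5), dtype=np.int32)
        labels[2, 2] = 2
        pm = one_hot_seed(LabelMap(np.ones((5, 5), dtype=np.int32)),
                          class_ids=np.array([1, 2]))
        state = RefineState(labels=labels, probs=pm)
        clamp = np.zeros((5, 5), bool)
        clamp[2, 2] = True
        out = icm_sweep(state, uniform_kernels(5, 5, 1),
                        RefineParams(r=1, beta=0.4), clamp_mask=clamp)
        assert out.labels[2, 2] == 2  # held fixed despite the energy


# ---------------------------------------------------------------------------
# probability update


class TestUpdateProbabilities:
    def test_equal_energies_give_uniform(self):
        # symmetric checkerboard-free setup: beta=0 and equal probabilities
        m = n = 4
        labels = np.ones((m, n), dtype=np.int32)
        coords = np.argwhere(labels > 0)
        probs = np.full((m * n, 2), 0.5)
        pm = ProbabilityMap(probs=probs, class_ids=np.array([1, 2]),
                            pixel_coords=coords)
        state = RefineState(labels=labels, probs=pm)
        ks = uniform_kernels(m, n, 1)
        out = update_probabilities(state, ks, RefineParams(r=1, beta=0.0))
        np.testing.assert_allclose(out.probs, 0.5, atol=1e-12)

    def test_two_class_softmax_value(self):
        state = one_hot_state(np.ones((3, 3)))
        ks = uniform_kernels(3, 3, 1)
        out = update_probabilities(state, ks, RefineParams(r=1, beta=0.4))
        # center pixel: E = (-11.2, +3.2) -> P(1) = 1 / (1 + exp(-14.4))
        center_row = 4  # raster order on a full 3x3
        assert out.probs[center_row, 0] == pytest.approx(1 / (1 + np.exp(-14.4)),
                                                         rel=1e-12)

    def test_shift_invariance(self, rng):
        state = random_state(rng, 5, 5, 3, background=0.0)
        params = RefineParams(r=1, beta=0.3)
        ks = build_kernels(rng.random((5, 5, 2)), params)
        e = class_energies(state, ks, params)
        coords = state.probs.pixel_coords
        rows = e[coords[:, 0], coords[:, 1], :]
        soft = np.exp(-(rows - rows.min(axis=1, keepdims=True)))
        soft /= soft.sum(axis=1, keepdims=True)
        shifted = rows + rng.random((len(rows), 1)) * 50
        soft2 = np.exp(-(shifted - shifted.min(axis=1, keepdims=True)))
        soft2 /= soft2.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(soft, soft2, atol=1e-12)
        out = update_probabilities(state, ks, params)
        np.testing.assert_allclose(out.probs, soft, atol=1e-12)

    def test_rows_sum_to_one_and_no_overflow(self, rng):
        state = random_state(rng, 6, 6, 3, background=0.2)
        params = RefineParams(r=2, beta=0.9)
        ks = build_kernels(rng.random((6, 6, 2)) * 100, params)
        out = update_probabilities(state, ks, params)
        assert np.all(np.isfinite(out.probs))
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# outer loop


def scene_with_corruption(seed, flip=0.1, m=40, n=40, class_separation=10.0,
                          noise_sd=0.05):
    spec = SceneSpec(m=m, n=n, d=20, k=3, layout="voronoi",
                     class_separation=class_separation, noise_sd=noise_sd,
                     seed=seed)
    cube, labels = make_scene(spec)
    pm = one_hot_seed(labels)
    corrupted = corrupt_seed(pm, flip, seed=seed + 1000)
    # feature raster: min-max normalized leading bands (no PCA needed at
    # this scale; 3 bands keep the kernels cheap)
    feats = cube.values[:, :, :3]
    lo = feats.reshape(-1, 3).min(axis=0)
    hi = feats.reshape(-1, 3).max(axis=0)
    feats = (feats - lo) / (hi - lo)
    return labels, corrupted, feats


class TestRefine:
    def test_huge_epsilon_single_iteration(self, rng):
        labels, corrupted, feats = scene_with_corruption(0, m=20, n=20)
        params = RefineParams(r=2, epsilon=2.0 * corrupted.probs.size,
                              max_outer=10)
        out = refine(corrupted, feats, params=params)
        assert out.iteration == 1
        assert out.converged
        assert len(out.delta_history) == 1

    def test_homogeneous_one_hot_scene_fixed_point(self):
        # constant labels, one-hot P: nothing can move, delta ~ 0 at once
        labels = LabelMap(np.full((10, 10), 1))
        pm = one_hot_seed(labels, class_ids=np.array([1, 2]))
        feats = np.full((10, 10, 1), 0.3)
        params = RefineParams(r=2, beta=0.4)
        out = refine(pm, feats, params=params)
        assert out.converged
        assert out.iteration == 1
        np.testing.assert_array_equal(out.labels, labels.labels)
        assert out.delta_history[0] <= params.epsilon

    def test_two_region_one_hot_scene_unchanged(self):
        labels = LabelMap(np.full((10, 10), 1))
        labels.labels[:, 5:] = 2
        pm = one_hot_seed(labels)
        feats = (labels.labels == 2).astype(float)[:, :, None]
        out = refine(pm, feats, params=RefineParams(r=2, beta=0.4))
        assert out.converged
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_denoising_beats_seed(self):
        wins = 0
        improvements = []
        for seed in range(5):
            labels, corrupted, feats = scene_with_corruption(seed, m=30, n=30)
            seed_oa = np.mean(corrupted.argmax_labels()
                              == labels.labels[labels.labels > 0])
            out = refine(corrupted, feats, params=RefineParams(r=2))
            ref_oa = np.mean(out.labels[labels.labels > 0]
                             == labels.labels[labels.labels > 0])
            improvements.append(ref_oa - seed_oa)
            wins += ref_oa >= seed_oa
        assert wins >= 4
        assert np.mean(improvements) > 0

    def test_termination_and_delta_history(self):
        labels, corrupted, feats = scene_with_corruption(3, m=20, n=20)
        params = RefineParams(r=2, max_outer=4, epsilon=1e-12)
        out = refine(corrupted, feats, params=params)
        assert out.iteration <= 4
        assert len(out.delta_history) == out.iteration
        if out.converged:
            assert out.delta_history[-1] <= params.epsilon

    def test_nonconvergence_is_reported_not_raised(self):
        labels, corrupted, feats = scene_with_corruption(4, m=20, n=20)
        out = refine(corrupted, feats,
                     params=RefineParams(r=1, max_outer=1, epsilon=1e-300))
        assert out.converged is False
        assert out.iteration == 1

    def test_clamped_training_labels_respected(self):
        labels, corrupted, feats = scene_with_corruption(5, m=20, n=20)
        known = np.zeros(labels.shape, dtype=np.int32)
        known[0, 0] = labels.labels[0, 0]
        out = refine(corrupted, feats, labels_known=known,
                     params=RefineParams(r=2, max_outer=2))
        assert out.labels[0, 0] == labels.labels[0, 0]


class TestWeakLabelFeedback:
    def test_zero_runs_rejected(self):
        labels, corrupted, feats = scene_with_corruption(6, m=20, n=20)
        out = refine(corrupted, feats, params=RefineParams(r=1, max_outer=1))
        with pytest.raises(ValueError, match="n_runs"):
            weak_label_feedback(out, feats, n_runs=0)

    def test_fixed_point_is_idempotent(self):
        labels = LabelMap(np.full((8, 8), 1))
        labels.labels[:, 4:] = 2
        pm = one_hot_seed(labels)
        feats = (labels.labels == 2).astype(float)[:, :, None]
        params = RefineParams(r=2, beta=0.4)
        out = refine(pm, feats, params=params)
        fed = weak_label_feedback(out, feats, params=params, n_runs=1)
        np.testing.assert_array_equal(fed.labels, out.labels)

    def test_feedback_does_not_hurt(self):
        # small neighborhoods suit small scenes (radius scales with the
        # effective resolution); r=1 leaves no curvature over-smoothing
        keeps = 0
        params = RefineParams(r=1)
        for seed in range(5):
            labels, corrupted, feats = scene_with_corruption(seed + 50, m=30, n=30)
            truth = labels.labels[labels.labels > 0]
            out = refine(corrupted, feats, params=params)
            oa1 = np.mean(out.labels[labels.labels > 0] == truth)
            fed = weak_label_feedback(out, feats, params=params)
            oa2 = np.mean(fed.labels[labels.labels > 0] == truth)
            keeps += oa2 >= oa1 - 1e-12
        assert keeps >= 4


def test_beta_monotonicity_probe():
    """Spatially noisy seed on spectrally clean regions: the spatial term
    (beta=0.4) should not do worse than pure spectral support (beta=0)."""
    wins = 0
    for seed in range(8):
        labels, corrupted, feats = scene_with_corruption(seed + 100, flip=0.25,
                                                         m=30, n=30)
        truth = labels.labels[labels.labels > 0]
        oa = {}
        for beta in (0.0, 0.4):
            out = refine(corrupted, feats, params=RefineParams(r=1, beta=beta))
            oa[beta] = np.mean(out.labels[labels.labels > 0] == truth)
        wins += oa[0.4] >= oa[0.0]
    assert wins >= 6


def test_refine_params_validation():
    for bad in [dict(r=0), dict(sigma_s=0), dict(sigma_w=-1), dict(beta=1.5),
                dict(epsilon=0), dict(max_outer=0), dict(potential_form="x")]:
        with pytest.raises(ValueError):
            RefineParams(**bad)


def test_determinism_end_to_end():
    labels, corrupted, feats = scene_with_corruption(7, m=20, n=20)
    a = refine(corrupted, feats, params=RefineParams(r=2, max_outer=3))
    b = refine(corrupted, feats, params=RefineParams(r=2, max_outer=3))
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.probs.probs, b.probs.probs)
    assert a.delta_history == b.delta_history
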