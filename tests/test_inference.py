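"""Inference-level checks: losses, fixed points, LASSO oracle, back-projection."""

import numpy as np
import pytest

from sdpc import (InferenceConfig, LayerSpec, SDPCNetwork, inference_step,
                  layer_loss, run_inference)
from sdpc.operators import synthesize

from .test_operators import dense_matrix


def dense_lasso_objective(M, x, w, lam):
    return 0.5 * np.sum((x - M @ w) ** 2) + lam * np.sum(np.abs(w))


def dense_lasso_minimize(M, x, lam, n_iter=20000):
    """Projected proximal gradient on the materialized matrix (independent oracle)."""
    L = np.linalg.eigvalsh(M.T @ M).max()
    eta = 1.0 / L
    w = np.zeros(M.shape[1])
    for _ in range(n_iter):
        w = np.maximum(w - eta * (M.T @ (M @ w - x)) - eta * lam, 0.0)
    return w


@pytest.fixture
def single_layer():
    return SDPCNetwork([LayerSpec(3, 1, (3, 3), 1, 0.15)], rng_seed=3)


@pytest.fixture
def two_layer():
    specs = [LayerSpec(3, 1, (3, 3), 1, 0.1), LayerSpec(4, 3, (3, 3), 1, 0.1)]
    return SDPCNetwork(specs, rng_seed=4)


class TestLayerLoss:
    def test_zero_activities_leave_data_term_only(self, single_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        shapes = single_layer.activity_shapes((8, 8))
        acts = [np.zeros((3, *shapes[0]))]
        assert layer_loss(single_layer, acts, img, 0, k_fb=0) == \
            pytest.approx(0.5 * np.sum(img ** 2))

    def test_top_layer_has_no_feedback_term(self, two_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        shapes = two_layer.activity_shapes((8, 8))
        acts = [rng.random((3, *shapes[0])), rng.random((4, *shapes[1]))]
        # the top-layer loss must not depend on k_FB
        assert layer_loss(two_layer, acts, img, 1, k_fb=0.0) == \
            pytest.approx(layer_loss(two_layer, acts, img, 1, k_fb=5.0))

    def test_matches_term_by_term_oracle(self, two_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        shapes = two_layer.activity_shapes((8, 8))
        acts = [rng.random((3, *shapes[0])), rng.random((4, *shapes[1]))]
        k_fb, lam = 0.7, two_layer.specs[0].lambda_sparsity
        pred1 = synthesize(two_layer.dictionaries[0].atoms, acts[0], 1)
        pred2 = synthesize(two_layer.dictionaries[1].atoms, acts[1], 1)
        want = (0.5 * np.sum((img - pred1) ** 2)
                + 0.5 * k_fb * np.sum((acts[0] - pred2) ** 2)
                + lam * np.sum(acts[0]))
        assert layer_loss(two_layer, acts, img, 0, k_fb=k_fb) == pytest.approx(want)

    def test_out_of_range_layer_raises(self, single_layer, rng):
        with pytest.raises(IndexError):
            layer_loss(single_layer, [np.zeros((3, 6, 6))],
                       rng.standard_normal((1, 8, 8)), 2)


class TestInferenceStep:
    def test_huge_penalty_keeps_activity_at_zero(self, rng):
        net = SDPCNetwork([LayerSpec(3, 1, (3, 3), 1, 1e3)], rng_seed=3)
        img = rng.standard_normal((1, 8, 8))
        acts = [np.zeros((3, 6, 6))]
        new = inference_step(net, acts, img, 0, InferenceConfig(feedback_strength=0))
        assert np.all(new == 0)

    def test_orthonormal_case_lands_on_clipped_least_squares(self, rng):
        # stride = kernel side and a single unit-norm atom: columns orthonormal,
        # so one step from zero with lambda=0 is the non-negative projection
        atom = rng.standard_normal((1, 1, 3, 3))
        atom /= np.linalg.norm(atom)
        net = SDPCNetwork([LayerSpec(1, 1, (3, 3), 3, 0.0)],
                          [__import__("sdpc").Dictionary(atom)])
        img = rng.standard_normal((1, 9, 9))
        acts = [np.zeros((1, 3, 3))]
        new = inference_step(net, acts, img, 0, InferenceConfig(feedback_strength=0))
        from sdpc.operators import analyze
        want = np.maximum(analyze(atom, img, 3), 0.0)
        assert np.allclose(new, want, atol=1e-10)

    def test_nonnegative_output(self, single_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        acts = [rng.random((3, 6, 6))]
        new = inference_step(single_layer, acts, img, 0,
                             InferenceConfig(feedback_strength=0))
        assert new.min() >= 0

    def test_ista_loss_nonincreasing(self, single_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        acts = [np.zeros((3, 6, 6))]
        config = InferenceConfig(feedback_strength=0, acceleration="ista")
        losses = []
        for _ in range(50):
            acts[0] = inference_step(single_layer, acts, img, 0, config)
            losses.append(layer_loss(single_layer, acts, img, 0, k_fb=0))
        assert np.all(np.diff(losses) <= 1e-10)


class TestRunInference:
    def test_zero_image_converges_immediately_to_zero(self, two_layer):
        state = run_inference(two_layer, np.zeros((1, 8, 8)), InferenceConfig())
        assert state.n_iterations == 1
        assert state.all_converged
        assert all(np.all(a.values == 0) for a in state.activities)

    def test_single_atom_image_recovered_at_its_position(self, rng):
        atom = rng.standard_normal((2, 1, 5, 5))
        atom /= np.linalg.norm(atom.reshape(2, -1), axis=1)[:, None, None, None]
        net = SDPCNetwork([LayerSpec(2, 1, (5, 5), 1, 0.01)],
                          [__import__("sdpc").Dictionary(atom)])
        img = np.zeros((1, 12, 12))
        img[:, 3:8, 4:9] = atom[1]
        cfg = InferenceConfig(feedback_strength=0, fixed_point_threshold=1e-8,
                              max_iterations=3000)
        state = run_inference(net, img, cfg)
        g = state.activities[0].values
        assert np.unravel_index(g.argmax(), g.shape) == (1, 3, 4)
        recon = net.back_project(state.activities[0], 0)
        # residual norm bounded by a lambda-dependent amount (KKT: correlated
        # residual <= lambda per unit; generous factor for the small instance)
        assert np.linalg.norm(img - recon) <= 0.1

    def test_bitwise_deterministic(self, two_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        s1 = run_inference(two_layer, img, InferenceConfig())
        s2 = run_inference(two_layer, img, InferenceConfig())
        for a, b in zip(s1.activities, s2.activities):
            assert np.array_equal(a.values, b.values)

    def test_nonconvergence_reported_not_silent(self, single_layer, rng):
        img = 10 * rng.standard_normal((1, 8, 8))
        state = run_inference(single_layer, img,
                              InferenceConfig(max_iterations=1,
                                              fixed_point_threshold=1e-12))
        assert not state.all_converged

    def test_activities_nonnegative(self, two_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        state = run_inference(two_layer, img, InferenceConfig())
        assert all(a.values.min() >= 0 for a in state.activities)


class TestLassoOracle:
    def test_converged_activity_attains_dense_lasso_objective(self, rng):
        lam = 0.15
        net = SDPCNetwork([LayerSpec(2, 1, (3, 3), 1, lam)], rng_seed=7)
        img = rng.standard_normal((1, 6, 6))
        cfg = InferenceConfig(feedback_strength=0, fixed_point_threshold=1e-10,
                              max_iterations=20000)
        state = run_inference(net, img, cfg)
        obj = layer_loss(net, [state.activities[0].values], img, 0, k_fb=0)
        M = dense_matrix(net.dictionaries[0].atoms, (4, 4), 1)
        w = dense_lasso_minimize(M, img.ravel(), lam)
        oracle = dense_lasso_objective(M, img.ravel(), w, lam)
        assert obj <= oracle * (1 + 1e-6)
        assert abs(obj - oracle) <= 1e-6 * max(oracle, 1.0)

    def test_no_feedback_decouples_layers(self, two_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        cfg = InferenceConfig(feedback_strength=0, fixed_point_threshold=1e-9,
                              max_iterations=5000)
        joint = run_inference(two_layer, img, cfg)
        alone = SDPCNetwork(two_layer.specs[:1], two_layer.dictionaries[:1])
        solo = run_inference(alone, img, cfg)
        assert np.allclose(joint.activities[0].values, solo.activities[0].values,
                           atol=1e-5)

    def test_fista_not_worse_than_ista_at_equal_budget(self, single_layer, rng):
        img = rng.standard_normal((1, 8, 8))
        budget = 40
        objs = {}
        for accel in ("fista", "ista"):
            cfg = InferenceConfig(feedback_strength=0, acceleration=accel,
                                  fixed_point_threshold=1e-14, max_iterations=budget)
            st = run_inference(single_layer, img, cfg)
            objs[accel] = layer_loss(single_layer, [st.activities[0].values],
                                     img, 0, k_fb=0)
        assert objs["fista"] <= objs["ista"] * (1 + 1e-9)


class TestBackProjection:
    def test_layer1_effective_dictionary_is_d1(self, two_layer):
        eff = two_layer.effective_dictionary(0)
        assert np.array_equal(eff, two_layer.dictionaries[0].atoms)

    @pytest.mark.parametrize("k1,s1,k2,expected", [
        (3, 2, 3, 7), (3, 1, 3, 5), (5, 3, 3, 11), (9, 3, 9, 33)])
    def test_effective_support_composition_law(self, k1, s1, k2, expected):
        specs = [LayerSpec(2, 1, (k1, k1), s1, 0.1), LayerSpec(2, 2, (k2, k2), 1, 0.1)]
        net = SDPCNetwork(specs, rng_seed=0)
        assert net.effective_support(1) == (expected, expected)
        eff = net.effective_dictionary(1)
        assert eff.shape[2:] == (expected, expected)
        footprint = np.abs(eff[0, 0]) > 0
        rows = np.flatnonzero(footprint.any(axis=1))
        cols = np.flatnonzero(footprint.any(axis=0))
        assert rows[-1] - rows[0] + 1 == expected
        assert cols[-1] - cols[0] + 1 == expected

    def test_zero_activity_projects_to_zero(self, two_layer):
        shapes = two_layer.activity_shapes((8, 8))
        assert np.all(two_layer.back_project(np.zeros((4, *shapes[1])), 1) == 0)

    def test_layer1_backprojection_equals_synthesis(self, two_layer, rng):
        shapes = two_layer.activity_shapes((8, 8))
        g1 = rng.random((3, *shapes[0]))
        assert np.allclose(two_layer.back_project(g1, 0),
                           synthesize(two_layer.dictionaries[0].atoms, g1, 1))

    def test_layer2_delta_matches_effective_atom(self, two_layer):
        shapes = two_layer.activity_shapes((8, 8))
        g2 = np.zeros((4, *shapes[1]))
        g2[2, 0, 0] = 1.0
        img = two_layer.back_project(g2, 1)
        eff = two_layer.effective_dictionary(1)
        k = eff.shape[-1]
        assert np.allclose(img[:, :k, :k], eff[2])
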