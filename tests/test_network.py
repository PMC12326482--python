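"""Autoencoder forward pass, loss terms, sharpening, and gradients."""

import copy

import numpy as np
import pytest

from dadpc.adaptive_loss import SigmaNormSpec
from dadpc.network import (
    AutoencoderParams,
    class_probabilities,
    compute_coefficients,
    forward,
    init_params,
    load_params,
    reconstruction_loss,
    save_params,
    sharpen,
    source_loss,
    surrogate_gradients,
    surrogate_objective,
    total_objective,
)
from dadpc.possibilistic import CentroidSet, membership_update, pairwise_sigma_distances


def _toy_problem(rng, dims=(6, 5, 4, 5, 6), K=3, N=12, ns=7, activation="tanh"):
    params = init_params(list(dims), K, activation, seed=1)
    X = rng.normal(size=(N, dims[0]))
    y = rng.integers(0, K, ns)
    Y = np.eye(K)[y]
    src = np.arange(ns)
    spec = SigmaNormSpec(sigma=1e-3)
    C = CentroidSet(C=rng.normal(size=(K, dims[len(dims) // 2])))
    st = forward(params, X)
    V = membership_update(pairwise_sigma_distances(st.bottleneck(params), C.C, spec))
    coeffs = compute_coefficients(params, X, C, spec)
    return params, X, Y, src, V, C, coeffs, spec


def _pack(p):
    return np.concatenate(
        [w.ravel() for w in p.weights]
        + [b.ravel() for b in p.biases]
        + [p.head_W.ravel(), p.head_b.ravel()]
    )


def _unpack(template, vec):
    p = copy.deepcopy(template)
    i = 0
    for m in range(p.n_layers):
        s = p.weights[m].size
        p.weights[m] = vec[i : i + s].reshape(p.weights[m].shape)
        i += s
    for m in range(p.n_layers):
        s = p.biases[m].size
        p.biases[m] = vec[i : i + s].reshape(p.biases[m].shape)
        i += s
    s = p.head_W.size
    p.head_W = vec[i : i + s].reshape(p.head_W.shape)
    i += s
    p.head_b = vec[i:]
    return p


class TestForward:
    def test_identity_network_reconstructs_exactly(self):
        d = 3
        params = AutoencoderParams(
            weights=[np.eye(d), np.eye(d)],
            biases=[np.zeros(d), np.zeros(d)],
            layer_dims=[d, d, d],
            activation="identity",
            head_W=np.zeros((2, d)),
            head_b=np.zeros(2),
        )
        X = np.array([[1.0, -2.0, 0.5], [0.0, 3.0, 1.0]])
        assert np.allclose(forward(params, X).reconstruction, X)

    def test_hand_tanh_evaluation(self):
        params = AutoencoderParams(
            weights=[np.array([[2.0]]), np.array([[1.0]])],
            biases=[np.array([1.0]), np.array([0.0])],
            layer_dims=[1, 1, 1],
            activation="tanh",
            head_W=np.zeros((2, 1)),
            head_b=np.zeros(2),
        )
        st = forward(params, np.array([[0.0]]))
        assert st.H[1][0, 0] == pytest.approx(np.tanh(1.0))

    def test_tanh_activations_bounded(self, rng):
        params = init_params([4, 8, 2, 8, 4], 3, "tanh", seed=0)
        st = forward(params, rng.normal(size=(20, 4)) * 10)
        for H in st.H[1:]:
            assert np.all(np.abs(H) <= 1.0)

    def test_dimension_mismatch_rejected(self, rng):
        params = init_params([4, 3, 4], 2, seed=0)
        with pytest.raises(ValueError):
            forward(params, rng.normal(size=(5, 7)))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        d = 2
        params = AutoencoderParams(
            weights=[np.eye(d), np.eye(d)],
            biases=[np.zeros(d)] * 2,
            layer_dims=[d, d, d],
            activation="identity",
            head_W=np.zeros((2, d)),
            head_b=np.zeros(2),
        )
        X = np.ones((3, d))
        assert reconstruction_loss(forward(params, X), X, SigmaNormSpec(sigma=1.0)) == 0

    def test_single_residual_hand_value_squared_convention(self):
        d = 2
        params = AutoencoderParams(
            weights=[np.eye(d), np.eye(d)],
            biases=[np.zeros(d), np.array([3.0, 4.0])],
            layer_dims=[d, d, d],
            activation="identity",
            head_W=np.zeros((2, d)),
            head_b=np.zeros(2),
        )
        X = np.zeros((1, d))
        st = forward(params, X)
        spec = SigmaNormSpec(sigma=1.0)
        assert reconstruction_loss(st, X, spec, square=True) == pytest.approx(
            (25.0 / 3.0) ** 2
        )
        assert reconstruction_loss(st, X, spec, square=False) == pytest.approx(25.0 / 3.0)


class TestSharpen:
    def test_symmetric_row_is_fixed_point(self):
        assert np.allclose(sharpen(np.array([0.5, 0.5]), 0.2), [0.5, 0.5])

    def test_hand_value_and_identity_temperature(self):
        out = sharpen(np.array([0.8, 0.2]), 0.5)
        assert np.allclose(out, [0.64 / 0.68, 0.04 / 0.68])
        assert np.allclose(sharpen(np.array([0.8, 0.2]), 1.0), [0.8, 0.2])

    def test_low_temperature_approaches_one_hot(self):
        out = sharpen(np.array([0.6, 0.3, 0.1]), 0.01)
        assert out[0, 0] > 1 - 1e-6

    def test_preserves_simplex_and_reduces_entropy(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = sharpen(p, 0.4)[0]
            assert q.sum() == pytest.approx(1.0)
            assert np.all(q >= 0)
            ent = lambda r: -np.sum(r * np.log(np.maximum(r, 1e-300)))
            assert ent(q) <= ent(p) + 1e-12

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            sharpen(np.array([0.5, 0.5]), 0.0)


class TestSourceLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        params = init_params([4, 3, 2, 3, 4], 2, seed=0)
        X = rng.normal(size=(20, 4))
        # drive the head towards an extreme so sharpened probs ~ one-hot
        params.head_W = np.array([[50.0, 0.0], [-50.0, 0.0]])
        st = forward(params, X)
        p = class_probabilities(params, st.bottleneck(params))
        confident = np.where(p.max(axis=1) > 0.999)[0]
        assert len(confident) > 0
        Y = np.eye(2)[np.argmax(p[confident], axis=1)]
        loss = source_loss(
            params, st, Y, confident, SigmaNormSpec(sigma=1.0), 0.0, 0.0, tau=0.5
        )
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_gives_log2(self):
        d = 2
        params = AutoencoderParams(
            weights=[np.eye(d), np.eye(d)],
            biases=[np.zeros(d)] * 2,
            layer_dims=[d, d, d],
            activation="identity",
            head_W=np.zeros((2, d)),
            head_b=np.zeros(2),
        )
        st = forward(params, np.zeros((1, d)))
        loss = source_loss(
            params,
            st,
            np.array([[1.0, 0.0]]),
            np.arange(1),
            SigmaNormSpec(sigma=1.0),
            0.0,
            0.0,
        )
        assert loss == pytest.approx(np.log(2.0))

    def test_weight_penalty_strictly_increases_loss(self, rng):
        params = init_params([4, 3, 2, 3, 4], 2, seed=0)
        X = rng.normal(size=(5, 4))
        st = forward(params, X)
        Y = np.eye(2)[rng.integers(0, 2, 5)]
        spec = SigmaNormSpec(sigma=1.0)
        l0 = source_loss(params, st, Y, np.arange(5), spec, 0.0, 0.0)
        l1 = source_loss(params, st, Y, np.arange(5), spec, 0.1, 0.0)
        assert l1 > l0


class TestObjectives:
    def test_total_objective_is_sum_of_parts(self, rng):
        params, X, Y, src, V, C, coeffs, spec = _toy_problem(rng)
        st = forward(params, X)
        from dadpc.possibilistic import dpc_objective

        j1 = reconstruction_loss(st, X, spec, square=True)
        j2 = source_loss(params, st, Y, src, spec, 0.01, 0.01, tau=0.5, square=True)
        j3 = dpc_objective(st.bottleneck(params), C, V, spec, 0.5)
        total = total_objective(
            params, X, Y, src, V, C, spec, 0.01, 0.01, 0.5, tau=0.5
        )
        assert total == pytest.approx(j1 + j2 + j3, rel=1e-10)

    @pytest.mark.parametrize("activation", ["tanh", "relu"])
    def test_surrogate_gradients_match_finite_differences(self, rng, activation):
        """Backprop on the 4-layer toy net agrees with central differences."""
        params, X, Y, src, V, C, coeffs, spec = _toy_problem(rng, activation=activation)
        lam = (0.01, 0.01, 0.5)
        args = (X, Y, src, V, C, coeffs, *lam)
        g = surrogate_gradients(params, *args, tau=0.5).flatten()
        x0 = _pack(params)
        eps = 1e-6
        fd = np.zeros_like(x0)
        for j in range(len(x0)):
            e = np.zeros_like(x0)
            e[j] = eps
            fp = surrogate_objective(_unpack(params, x0 + e), *args, tau=0.5)
            fm = surrogate_objective(_unpack(params, x0 - e), *args, tau=0.5)
            fd[j] = (fp - fm) / (2 * eps)
        denom = np.abs(g) + np.abs(fd) + 1e-8
        assert np.max(np.abs(g - fd) / denom) < 1e-4

    def test_descent_under_frozen_reweighting(self, rng):
        """Full-batch gradient steps with frozen coefficients do not increase
        the surrogate at a small step size."""
        params, X, Y, src, V, C, coeffs, spec = _toy_problem(rng)
        lam = (0.01, 0.01, 0.5)
        args = (X, Y, src, V, C, coeffs, *lam)
        prev = surrogate_objective(params, *args)
        lr = 1e-3
        for _ in range(200):
            g = surrogate_gradients(params, *args)
            for m in range(params.n_layers):
                params.weights[m] -= lr * g.dW[m]
                params.biases[m] -= lr * g.db[m]
            params.head_W -= lr * g.dhead_W
            params.head_b -= lr * g.dhead_b
            cur = surrogate_objective(params, *args)
            assert cur <= prev + 1e-9 * max(1, abs(prev))
            prev = cur


class TestSerialization:
    def test_roundtrip(self, rng, tmp_path):
        params = init_params([4, 3, 2, 3, 4], 3, seed=2)
        path = tmp_path / "model.npz"
        save_params(params, path, meta={"note": "test"})
        loaded = load_params(path)
        for a, b in zip(params.weights, loaded.weights):
            assert np.array_equal(a, b)
        assert np.array_equal(params.head_W, loaded.head_W)
        assert loaded.activation == "tanh"
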