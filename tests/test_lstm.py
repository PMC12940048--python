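import copy

import numpy as np
import pytest

from bold.lstm import (
    LSTMError,
    LSTMHyper,
    LSTMParams,
    bce_loss,
    cell_step,
    forward,
    init_params,
    loss_and_gradients,
    predict,
    train,
)
from bold.preprocess import FeatureTable

GATES = ("F", "I", "C", "O")


def zero_params(units=2, input_dim=2):
    return LSTMParams(
        weights={g: np.zeros((units, units + input_dim)) for g in GATES},
        biases={g: np.zeros(units) for g in GATES},
        head_w=np.zeros(units),
        head_b=0.0,
        units=units,
        input_dim=input_dim,
    )


class TestCellStep:
    def test_zero_fixed_point(self):
        p = zero_params()
        h, c, gates = cell_step(np.zeros(2), np.zeros(2), np.zeros(2), p)
        for g in ("F", "I", "O"):
            np.testing.assert_allclose(gates[g], 0.5)
        np.testing.assert_allclose(gates["C"], 0.0)
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_hand_value_with_carried_state(self):
        # zero weights, C_prev = 2 -> C_t = 0.5*2 = 1, H_t = 0.5*tanh(1)
        p = zero_params()
        h, c, _ = cell_step(np.zeros(2), np.full(2, 2.0), np.zeros(2), p)
        np.testing.assert_allclose(c, 1.0)
        np.testing.assert_allclose(h, 0.5 * np.tanh(1.0), rtol=1e-12)
        assert h[0, 0] == pytest.approx(0.380797, abs=1e-6)

    def test_cell_update_identity(self):
        # the state update C_t = F*C_prev + I*C~ as a pure function:
        # F=1, I=0 preserves memory exactly; F=0, I=1 copies the candidate
        c_prev = np.array([0.3, -1.2])
        cand = np.array([0.9, 0.1])
        np.testing.assert_array_equal(1.0 * c_prev + 0.0 * cand, c_prev)
        np.testing.assert_array_equal(0.0 * c_prev + 1.0 * cand, cand)

    def test_gate_ranges_on_random_inputs(self):
        rng = np.random.default_rng(0)
        p = init_params(4, 3, seed=1)
        for _ in range(20):
            _, _, gates = cell_step(rng.normal(size=4), rng.normal(size=4), rng.normal(size=3), p)
            for g in ("F", "I", "O"):
                assert ((gates[g] > 0) & (gates[g] < 1)).all()
            assert ((gates["C"] > -1) & (gates["C"] < 1)).all()

    def test_shape_mismatch_errors(self):
        p = zero_params(units=2, input_dim=2)
        with pytest.raises(LSTMError):
            cell_step(np.zeros(2), np.zeros(2), np.zeros(3), p)


class TestForward:
    def test_zero_head_gives_half(self):
        p = init_params(3, 2, seed=0)
        p.head_w[:] = 0.0
        p.head_b = 0.0
        probs = forward(np.random.default_rng(1).random((5, 2)), p)
        np.testing.assert_allclose(probs, 0.5)

    def test_output_in_open_interval(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            p = init_params(3, 4, seed=seed)
            probs = forward(rng.random((100, 4)), p)
            assert ((probs > 0) & (probs < 1)).all()

    def test_purity(self):
        p = init_params(3, 2, seed=5)
        X = np.random.default_rng(3).random((4, 2))
        np.testing.assert_array_equal(forward(X, p), forward(X, p))

    def test_timesteps_mode(self):
        p = init_params(3, 1, seed=0, sequence_mode="timesteps")
        probs = forward(np.random.default_rng(0).random((6, 4)), p)
        assert probs.shape == (6,)

    def test_serialization_round_trip(self):
        p = init_params(3, 2, seed=9)
        back = LSTMParams.from_json(p.to_json())
        X = np.random.default_rng(4).random((5, 2))
        np.testing.assert_allclose(forward(X, back), forward(X, p))


class TestGradients:
    @pytest.mark.parametrize("mode,features", [("row", 2), ("timesteps", 3)])
    def test_analytic_matches_finite_differences(self, mode, features):
        """Central finite differences vs BPTT on a 3-unit instance."""
        rng = np.random.default_rng(0)
        input_dim = features if mode == "row" else 1
        p = init_params(3, input_dim, seed=1, sequence_mode=mode)
        X = rng.random((5, features))
        y = np.array([0, 1, 1, 0, 1])
        _, grads = loss_and_gradients(p, X, y)

        flat_g = np.concatenate(
            [grads["weights"][g].ravel() for g in GATES]
            + [grads["biases"][g] for g in GATES]
            + [grads["head_w"], np.array([grads["head_b"]])]
        )
        flat_p = p.flatten()

        def with_vector(vec):
            q = copy.deepcopy(p)
            i = 0
            for g in GATES:
                n = q.weights[g].size
                q.weights[g] = vec[i: i + n].reshape(q.weights[g].shape)
                i += n
            for g in GATES:
                n = q.biases[g].size
                q.biases[g] = vec[i: i + n]
                i += n
            q.head_w = vec[i: i + q.head_w.size]
            i += q.head_w.size
            q.head_b = float(vec[i])
            return q

        eps = 1e-6
        numeric = np.zeros_like(flat_p)
        for i in range(len(flat_p)):
            e = np.zeros_like(flat_p)
            e[i] = eps
            lp, _ = loss_and_gradients(with_vector(flat_p + e), X, y)
            lm, _ = loss_and_gradients(with_vector(flat_p - e), X, y)
            numeric[i] = (lp - lm) / (2 * eps)
        rel = np.abs(flat_g - numeric) / np.maximum(1e-8, np.abs(flat_g) + np.abs(numeric))
        assert rel.max() < 1e-4


def _tables(seed=0, n=200):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 2))
    y = (X[:, 0] + 0.2 * X[:, 1] > 0.6).astype(int)  # linearly separable
    t = FeatureTable(["a", "b"], X, y)
    idx = rng.permutation(n)
    return t.take_rows(idx[: int(0.8 * n)]), t.take_rows(idx[int(0.8 * n):])


class TestTraining:
    def test_learns_linearly_separable_data(self):
        hits = 0
        for seed in range(3):
            tr, va = _tables(seed)
            hyper = LSTMHyper(lr=0.01, batch_size=32, units=8, dropout=0.0)
            params, history = train(tr, va, hyper, max_epochs=200, patience=50, seed=seed)
            labels, _ = predict(tr, params)
            hits += float((labels == tr.outcome).mean()) >= 0.99
        assert hits >= 2

    def test_early_stopping_on_worsening_validation(self):
        # validation labels inverted w.r.t. the training rule: any learning
        # on the training set worsens validation loss immediately
        tr, va = _tables(1)
        va_inv = FeatureTable(va.attribute_names, va.values, 1 - va.outcome)
        hyper = LSTMHyper(lr=0.05, batch_size=16, units=4, dropout=0.0)
        params, history = train(tr, va_inv, hyper, max_epochs=50, patience=1, seed=0)
        assert history.stopped_epoch == 2
        assert history.best_epoch == 1

    def test_returned_params_match_best_recorded_epoch(self):
        tr, va = _tables(2)
        hyper = LSTMHyper(lr=0.02, batch_size=32, units=6, dropout=0.2)
        params, history = train(tr, va, hyper, max_epochs=30, patience=5, seed=3)
        val_loss = bce_loss(forward(va.values, params), va.outcome)
        assert val_loss == pytest.approx(min(history.val_loss), abs=1e-12)

    def test_single_class_training_rejected(self):
        tr, va = _tables(3)
        bad = FeatureTable(tr.attribute_names, tr.values, np.zeros(tr.n_rows, dtype=int))
        with pytest.raises(LSTMError):
            train(bad, va, LSTMHyper(), max_epochs=2, patience=1, seed=0)

    def test_training_determinism(self):
        tr, va = _tables(4)
        hyper = LSTMHyper(lr=0.01, batch_size=16, units=4, dropout=0.3)
        p1, h1 = train(tr, va, hyper, max_epochs=10, patience=10, seed=7)
        p2, h2 = train(tr, va, hyper, max_epochs=10, patience=10, seed=7)
        np.testing.assert_array_equal(p1.flatten(), p2.flatten())
        assert h1.val_loss == h2.val_loss


class TestPredict:
    def test_threshold_boundary_and_extremes(self):
        p = init_params(3, 2, seed=0)
        p.head_w[:] = 0.0
        p.head_b = 0.0  # every probability exactly 0.5
        X = np.random.default_rng(0).random((4, 2))
        labels, probs = predict(X, p, threshold=0.5)
        assert (labels == 1).all()  # >= convention at the boundary
        labels0, _ = predict(X, p, threshold=0.0)
        assert (labels0 == 1).all()
        labels1, _ = predict(X, p, threshold=1.0)
        assert (labels1 == 0).all()

    def test_threshold_sweep_monotone(self):
        p = init_params(4, 3, seed=2)
        X = np.random.default_rng(5).random((50, 3))
        prev = None
        for thr in np.linspace(0, 1, 11):
            labels, _ = predict(X, p, threshold=thr)
            if prev is not None:
                assert (labels <= prev).all()  # raising the bar only removes positives
            prev = labels
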