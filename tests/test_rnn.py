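"""Recurrent classifier: forward equations, BPTT gradients, online fitting."""

import numpy as np
import pytest

from aadrl import RNNParams, RNNTrainConfig, init_rnn, rnn_predict, rnn_step
from aadrl.labels import LEFT, RIGHT
from aadrl.rnn import (rnn_fit_step, rnn_forward_window, rnn_window_gradients,
                       run_rnn_episode)
from aadrl.states import StateSequence


class TestInit:
    def test_seeded_determinism(self):
        cfg = RNNTrainConfig(n_layers=2, n_hidden=5, seed=4)
        a, b = init_rnn(cfg, 3), init_rnn(cfg, 3)
        for wa, wb in zip(a.W_sh + a.W_hh + [a.W_ho], b.W_sh + b.W_hh + [b.W_ho]):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seeds_differ(self):
        a = init_rnn(RNNTrainConfig(n_layers=1, n_hidden=5, seed=1), 3)
        b = init_rnn(RNNTrainConfig(n_layers=1, n_hidden=5, seed=2), 3)
        assert not np.array_equal(a.W_sh[0], b.W_sh[0])

    def test_magnitudes_bounded_by_init_scale(self):
        p = init_rnn(RNNTrainConfig(n_layers=3, n_hidden=7, seed=0), 11)
        assert np.max(np.abs(p.W_sh[0])) <= 1 / np.sqrt(11)
        assert np.max(np.abs(p.W_hh[0])) <= 1 / np.sqrt(7)


class TestForward:
    def test_hand_computed_scalar_step(self):
        """h = tanh(0.5) ~ 0.46212, o = 2h ~ 0.92424."""
        params = RNNParams([np.array([[1.0]])], [np.array([[0.0]])],
                           np.array([[2.0]]))
        o, h = rnn_step(params, np.array([0.5]), [np.zeros(1)])
        assert h[0][0] == pytest.approx(0.462117, abs=1e-6)
        assert o[0] == pytest.approx(0.924234, abs=1e-6)

    def test_zero_weights_give_zero_output(self):
        params = RNNParams([np.zeros((4, 3))], [np.zeros((4, 4))], np.zeros((2, 4)))
        o, h = rnn_step(params, np.ones(3), [np.ones(4)])
        np.testing.assert_array_equal(o, 0.0)
        np.testing.assert_array_equal(h[0], 0.0)

    def test_hidden_activations_strictly_inside_unit_interval(self):
        params = init_rnn(RNNTrainConfig(n_layers=2, n_hidden=6, seed=0), 4)
        _, h = rnn_step(params, 3.0 * np.ones(4), [np.zeros(6), np.zeros(6)])
        for layer in h:
            assert np.all(np.abs(layer) < 1.0)

    def test_shape_mismatch_rejected(self):
        params = init_rnn(RNNTrainConfig(n_layers=1, n_hidden=4, seed=0), 3)
        with pytest.raises(ValueError):
            rnn_step(params, np.ones(5), [np.zeros(4)])

    @pytest.mark.parametrize("w_ho,expected", [
        ([[2.0], [0.5]], LEFT),     # o ~ (0.9, 0.2)  -> left
        ([[0.5], [2.0]], RIGHT),    # o ~ (0.2, 0.9)  -> right
        ([[1.0], [1.0]], LEFT),     # exact tie       -> left by rule
    ])
    def test_prediction_argmax_and_tie_rule(self, w_ho, expected):
        params = RNNParams([np.array([[1.0]])], [np.array([[0.0]])],
                           np.array(w_ho))
        label, _ = rnn_predict(params, np.array([0.5]), [np.zeros(1)])
        assert label == expected


class TestGradients:
    @pytest.mark.parametrize("n_layers,k", [(1, 3), (2, 2)])
    def test_bptt_gradients_match_finite_differences(self, n_layers, k):
        cfg = RNNTrainConfig(n_layers=n_layers, n_hidden=3, seed=6)
        params = init_rnn(cfg, 4)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((k, 4))
        labels = np.array([0, 1, 0][:k])
        h0 = [rng.standard_normal(3) * 0.3 for _ in range(n_layers)]
        loss, gW_sh, gW_hh, gW_ho = rnn_window_gradients(params, X, labels, h0)

        def loss_only():
            l, *_ = rnn_window_gradients(params, X, labels, h0)
            return l

        eps = 1e-6

        def check(W, G):
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = W[i]
                W[i] = orig + eps
                lp = loss_only()
                W[i] = orig - eps
                lm = loss_only()
                W[i] = orig
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd) + abs(G[i]), 1e-8)
                assert abs(fd - G[i]) / denom < 1e-4

        for l in range(n_layers):
            check(params.W_sh[l], gW_sh[l])
            check(params.W_hh[l], gW_hh[l])
        check(params.W_ho, gW_ho)


class TestFitStep:
    def test_below_threshold_leaves_params_unchanged(self):
        cfg = RNNTrainConfig(n_layers=1, n_hidden=2, stop_threshold=1e-3, seed=0)
        # weights that already reproduce the one-hot target almost exactly
        t = np.tanh(5.0)
        params = RNNParams([np.array([[5.0], [-5.0]])],
                           [np.zeros((2, 2))],
                           np.array([[1.0 / t, 0.0], [0.0, 0.0]]))
        X = np.array([[1.0], [1.0]])
        labels = np.array([0, 0])
        loss0, *_ = rnn_window_gradients(params, X, labels,
                                         [np.zeros(2)])
        assert loss0 < 1e-3
        out, loss = rnn_fit_step(params, X, labels, cfg)
        np.testing.assert_array_equal(out.W_sh[0], params.W_sh[0])
        np.testing.assert_array_equal(out.W_ho, params.W_ho)
        assert loss == loss0

    def test_loss_decreases_on_separable_windows(self):
        """Monotone descent checked over 20 seeds."""
        improved = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = RNNTrainConfig(n_layers=1, n_hidden=6, learning_rate=0.02,
                                 max_inner_iters=30, seed=seed)
            params = init_rnn(cfg, 2)
            labels = np.array([0, 1, 0])
            X = np.column_stack([np.where(labels == 0, 1.0, -1.0),
                                 rng.standard_normal(3) * 0.1])
            before, *_ = rnn_window_gradients(params, X, labels,
                                              [np.zeros(6)])
            _, after = rnn_fit_step(params, X, labels, cfg)
            improved += after < before
        assert improved == 20

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises(self):
        cfg = RNNTrainConfig(n_layers=1, n_hidden=4, learning_rate=1e6,
                             max_inner_iters=50, seed=0)
        params = init_rnn(cfg, 2)
        X = np.array([[1.0, 2.0]] * 3)
        with pytest.raises(FloatingPointError):
            rnn_fit_step(params, X, np.array([0, 1, 0]), cfg)


class TestEpisode:
    def _seq(self, T=80, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(T) < 0.5).astype(np.int8)
        F = np.column_stack([np.where(y == 0, 1.0, -1.0)
                             + 0.1 * rng.standard_normal(T),
                             rng.standard_normal(T) * 0.1])
        return StateSequence(F, y, np.arange(T) * 125.0, 125.0)

    def test_deterministic_for_fixed_seed(self):
        cfg = RNNTrainConfig(n_layers=1, n_hidden=5, max_inner_iters=10, seed=2)
        seq = self._seq()
        p1, t1 = run_rnn_episode(seq, cfg)
        p2, t2 = run_rnn_episode(seq, cfg)
        np.testing.assert_array_equal(t1.pred, t2.pred)
        np.testing.assert_array_equal(p1.W_ho, p2.W_ho)

    def test_predictions_precede_label_use(self):
        """Changing the label of step t cannot change the prediction at t
        (no label leakage into the current decision)."""
        cfg = RNNTrainConfig(n_layers=1, n_hidden=5, max_inner_iters=10, seed=2)
        seq = self._seq()
        _, trace = run_rnn_episode(seq, cfg)
        flipped = seq.with_labels(np.concatenate([seq.labels[:-1],
                                                  [1 - seq.labels[-1]]]))
        _, trace_f = run_rnn_episode(flipped, cfg)
        np.testing.assert_array_equal(trace.pred, trace_f.pred)

    def test_learns_separable_stream(self):
        cfg = RNNTrainConfig(n_layers=1, n_hidden=5, max_inner_iters=20, seed=0)
        seq = self._seq(T=150, seed=1)
        _, trace = run_rnn_episode(seq, cfg)
        assert np.mean(trace.pred[50:] == trace.true[50:]) > 0.9
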