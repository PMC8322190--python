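"""Deep Q-learning: replay memory, Q-networks, update rule, episodes."""

import dataclasses

import numpy as np
import pytest

from aadrl import (DQLConfig, Experience, QNetworkDNN, QNetworkRNN,
                   ReplayMemory, dql_update, q_forward, remember,
                   run_dql_episode, sample_batch)
from aadrl.dqlearn import (_loss_and_grads_dnn, _loss_and_grads_rnn,
                           greedy_rollout, init_q_network)
from aadrl.states import StateSequence


def _exp(v, a=0, r=1, nxt=None):
    return Experience(np.asarray(v, dtype=float), a, r, nxt)


class TestReplayMemory:
    def test_fifo_eviction(self):
        mem = ReplayMemory(capacity=3)
        for i in range(4):
            remember(mem, _exp([i]))
        assert len(mem) == 3
        stored = [e.s[0] for e in mem]
        assert stored == [1.0, 2.0, 3.0]   # first inserted is gone, order kept

    def test_single_insert(self):
        mem = ReplayMemory(capacity=5)
        remember(mem, _exp([7]))
        assert len(mem) == 1

    def test_sample_whole_memory_when_exact(self):
        mem = ReplayMemory(capacity=4)
        for i in range(4):
            remember(mem, _exp([i]))
        batch = sample_batch(mem, 4, seed=0)
        assert sorted(e.s[0] for e in batch) == [0.0, 1.0, 2.0, 3.0]

    def test_sample_seeded_determinism(self):
        mem = ReplayMemory(capacity=50)
        for i in range(50):
            remember(mem, _exp([i]))
        a = [e.s[0] for e in sample_batch(mem, 10, seed=3)]
        b = [e.s[0] for e in sample_batch(mem, 10, seed=3)]
        assert a == b

    def test_sample_uniformity(self):
        """Selection frequency of every item within 3 sigma of uniform over
        10^4 batch draws (binomial check)."""
        mem = ReplayMemory(capacity=100)
        for i in range(100):
            remember(mem, _exp([i]))
        rng = np.random.default_rng(11)
        counts = np.zeros(100)
        n_draws = 10_000
        for _ in range(n_draws):
            for e in sample_batch(mem, 10, rng):
                counts[int(e.s[0])] += 1
        p = 0.1
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 3 * sigma)

    def test_insufficient_experiences_signal(self):
        mem = ReplayMemory(capacity=10)
        remember(mem, _exp([0]))
        with pytest.raises(LookupError):
            sample_batch(mem, 2, seed=0)


class TestQForward:
    def test_zero_weights_give_zero_values(self):
        dnn = QNetworkDNN([np.zeros((3, 2)), np.zeros((2, 3))],
                          [np.zeros(3), np.zeros(2)])
        q, h = q_forward(dnn, np.ones(2))
        np.testing.assert_array_equal(q, 0.0)
        assert h is None
        rnn = QNetworkRNN([np.zeros((3, 2))], [np.zeros((3, 3))],
                          np.zeros((2, 3)), [np.zeros(3)], np.zeros(2))
        q, h = q_forward(rnn, np.ones(2))
        np.testing.assert_array_equal(q, 0.0)
        np.testing.assert_array_equal(h[0], 0.0)

    def test_single_unit_sigmoid_toy(self):
        """Input 0 -> hidden sigmoid(0) = 0.5 -> output 0.5 * w_out."""
        w_out = 0.8
        dnn = QNetworkDNN([np.array([[1.0]]), np.array([[w_out], [0.0]])],
                          [np.zeros(1), np.zeros(2)])
        q, _ = q_forward(dnn, np.zeros(1))
        assert q[0] == pytest.approx(0.5 * w_out)
        assert q[1] == pytest.approx(0.0)

    def test_recurrent_hidden_state_advances(self):
        cfg = DQLConfig(n_hidden=4, n_hidden_layers=1, seed=0)
        net = init_q_network("rnn", 3, cfg)
        s = np.array([0.3, -0.2, 1.0])
        q1, h1 = q_forward(net, s)
        q2, h2 = q_forward(net, s, h1)
        assert not np.allclose(h1[0], h2[0])


class TestGradients:
    @pytest.mark.parametrize("agent_kind", ["dnn", "rnn"])
    def test_batch_loss_gradients_match_finite_differences(self, agent_kind):
        rng = np.random.default_rng(5)
        cfg = DQLConfig(n_hidden=4, n_hidden_layers=2, seed=2)
        net = init_q_network(agent_kind, 3, cfg)
        X = rng.standard_normal((4, 3))
        a_idx = np.array([0, 1, 1, 0])
        y = rng.standard_normal(4)
        H_prev = [rng.standard_normal((4, 4)) * 0.4 for _ in range(2)]

        if agent_kind == "rnn":
            loss, (gW_sh, gW_hh, gW_ho, gbs, gb_o) = _loss_and_grads_rnn(
                net, X, a_idx, y, H_prev)
            weights = (list(zip(net.W_sh, gW_sh)) + list(zip(net.W_hh, gW_hh))
                       + [(net.W_ho, gW_ho)] + list(zip(net.bs, gbs))
                       + [(net.b_o, gb_o)])

            def loss_only():
                l, _ = _loss_and_grads_rnn(net, X, a_idx, y, H_prev)
                return l
        else:
            loss, grads, gbs = _loss_and_grads_dnn(net, X, a_idx, y)
            weights = list(zip(net.Ws, grads)) + list(zip(net.bs, gbs))

            def loss_only():
                l, _, _ = _loss_and_grads_dnn(net, X, a_idx, y)
                return l

        eps = 1e-6
        for W, G in weights:
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


class TestUpdate:
    def test_zero_residual_leaves_network_unchanged(self):
        """gamma=0 and Q(s,a) already equal to r: loss 0, no movement."""
        net = QNetworkDNN([np.zeros((2, 2)), np.zeros((2, 2))],
                          [np.zeros(2), np.array([1.0, -1.0])])
        before = net.copy()
        batch = [_exp([0.3, -0.5], a=0, r=1), _exp([1.0, 0.2], a=1, r=-1)]
        cfg = DQLConfig(gamma=0.0, n_hidden=2, n_hidden_layers=1)
        _, loss = dql_update(net, net.copy(), batch, cfg)
        assert loss == pytest.approx(0.0, abs=1e-12)
        for w, w0 in zip(net.Ws + net.bs, before.Ws + before.bs):
            np.testing.assert_array_equal(w, w0)

    def test_loss_is_nonnegative_and_finite(self, small_dql_cfg):
        rng = np.random.default_rng(0)
        net = init_q_network("rnn", 3, small_dql_cfg)
        batch = [Experience(rng.standard_normal(3), int(rng.integers(2)),
                            1 if rng.random() < 0.5 else -1, None,
                            h=[np.zeros(8)], h_next=None)
                 for _ in range(8)]
        _, loss = dql_update(net, net.copy(), batch, small_dql_cfg)
        assert np.isfinite(loss) and loss >= 0

    def test_contextual_bandit_reaches_optimal_policy(self):
        """Two-state bandit, reward +1 for matching action: the greedy
        policy becomes optimal in >= 95% of seeds."""
        s0, s1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        successes = 0
        for seed in range(20):
            cfg = DQLConfig(n_hidden=8, n_hidden_layers=1, gamma=0.0,
                            batch_size=8, capacity=50, seed=seed)
            net = init_q_network("dnn", 2, cfg)
            mem = ReplayMemory(cfg.capacity)
            rng = np.random.default_rng(seed)
            for t in range(150):
                s, label = (s0, 0) if rng.random() < 0.5 else (s1, 1)
                a = int(rng.integers(2))
                remember(mem, _exp(s, a=a, r=1 if a == label else -1))
                if len(mem) >= cfg.batch_size:
                    dql_update(net, net.copy(), sample_batch(mem, cfg.batch_size, rng), cfg)
            q0, _ = q_forward(net, s0)
            q1, _ = q_forward(net, s1)
            successes += (np.argmax(q0) == 0) and (np.argmax(q1) == 1)
        assert successes >= 19


class TestEpisode:
    def test_fixed_seed_reproduces_trace(self, toy_separable_seq, small_dql_cfg):
        _, t1 = run_dql_episode(toy_separable_seq, "rnn", small_dql_cfg)
        _, t2 = run_dql_episode(toy_separable_seq, "rnn", small_dql_cfg)
        np.testing.assert_array_equal(t1.pred, t2.pred)
        np.testing.assert_array_equal(t1.rewards, t2.rewards)

    @pytest.mark.parametrize("agent_kind", ["dnn", "rnn"])
    def test_learns_separable_toy(self, toy_separable_seq, small_dql_cfg, agent_kind):
        _, trace = run_dql_episode(toy_separable_seq, agent_kind, small_dql_cfg)
        late = slice(len(trace) // 2, None)
        assert np.mean(trace.pred[late] == trace.true[late]) > 0.85

    def test_capacity_one_reduces_to_online_td(self, toy_separable_seq):
        """With capacity 1, batch 1 and no exploration, the episode is
        step-by-step TD on the latest experience; an explicit online loop
        produces the identical network and predictions."""
        cfg = DQLConfig(batch_size=1, capacity=1, epsilon_start=0.0,
                        epsilon_end=0.0, gamma=0.0, n_hidden=6,
                        n_hidden_layers=1, max_inner_iters=5, seed=4)
        seq = toy_separable_seq
        net_ep, trace = run_dql_episode(seq, "dnn", cfg)

        net = init_q_network("dnn", seq.n_features, cfg)
        target = net.copy()
        preds = []
        n_updates = 0
        from aadrl.env import AttentionEnv
        env = AttentionEnv(seq)
        env.reset()
        for t in range(len(seq)):
            s = seq.features[t]
            q, _ = q_forward(net, s)
            a = int(np.argmax(q))
            preds.append(a)
            _, r, done = env.step(a)
            s_next = None if done else seq.features[t + 1]
            e = Experience(s, a, r, s_next)
            net, _ = dql_update(net, target, [e], cfg)
            n_updates += 1
            if n_updates % cfg.target_sync_every == 0:
                target = net.copy()
        np.testing.assert_array_equal(trace.pred, np.array(preds, dtype=np.int8))
        for w, w2 in zip(net_ep.Ws + net_ep.bs, net.Ws + net.bs):
            np.testing.assert_allclose(w, w2, atol=1e-12)

    def test_stored_rewards_respect_contract(self, toy_separable_seq, small_dql_cfg):
        mem = ReplayMemory(small_dql_cfg.capacity)
        run_dql_episode(toy_separable_seq, "rnn", small_dql_cfg, mem=mem)
        assert all(e.r in (1, -1) for e in mem)

    def test_greedy_rollout_is_pure_prediction(self, toy_separable_seq, small_dql_cfg):
        net, _ = run_dql_episode(toy_separable_seq, "rnn", small_dql_cfg)
        p1 = greedy_rollout(net, toy_separable_seq)
        p2 = greedy_rollout(net, toy_separable_seq)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (len(toy_separable_seq),)

    def test_unknown_agent_kind_rejected(self, toy_separable_seq, small_dql_cfg):
        with pytest.raises(ValueError):
            run_dql_episode(toy_separable_seq, "cnn", small_dql_cfg)
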