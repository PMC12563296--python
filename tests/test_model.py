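"""Attention, gating, fusion and loss — hand-computed micro-checks."""

import dataclasses
import math

import numpy as np
import pytest

from dama.autodiff import Tensor
from dama.graph import Graph
from dama.influence import build_ifm, build_pim
from dama.model import (DAMAModel, ModelConfig, base_gate, decay_attention,
                        feedback_gate, fuse_and_classify, layer_norm,
                        model_loss, prepare_batch)
from dama.sampling import SamplingConfig, sample_all
from dama.synthetic import generate_planted_partition


def qk(vals):
    """(n, 1 head, 1 dim) tensor from a list of scalars."""
    return Tensor(np.asarray(vals, dtype=float).reshape(-1, 1, 1))


class TestDecayAttention:
    def test_singleton_weight_is_one(self):
        alpha = decay_attention(qk([1.0, 2.0]), qk([1.0, 2.0]),
                                dst=np.array([0]), src=np.array([1]),
                                dist=np.array([1.0]),
                                lam=Tensor(0.3), n_nodes=2)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_zero_inner_products_give_uniform_weights(self):
        # q = 0 kills every logit, so distances cannot matter
        alpha = decay_attention(qk([0.0, 5.0, -3.0]), qk([1.0, 2.0, 7.0]),
                                dst=np.array([0, 0]), src=np.array([1, 2]),
                                dist=np.array([1.0, 3.0]),
                                lam=Tensor(0.3), n_nodes=3)
        np.testing.assert_allclose(alpha.data[:, 0], [0.5, 0.5])

    def test_two_member_distance_decay_ratio(self):
        # equal keys, logit s=1, distances 1 and 2, λ=0.3:
        # weights = softmax([e^-0.3, e^-0.6])  (straight-line evaluation)
        alpha = decay_attention(qk([1.0, 1.0, 1.0]), qk([1.0, 1.0, 1.0]),
                                dst=np.array([0, 0]), src=np.array([1, 2]),
                                dist=np.array([1.0, 2.0]),
                                lam=Tensor(0.3), n_nodes=3)
        logits = np.array([math.exp(-0.3), math.exp(-0.6)])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(alpha.data[:, 0], expected, rtol=1e-12)
        assert alpha.data[0, 0] == pytest.approx(0.54784, abs=1e-4)

    def test_rows_sum_to_one_on_random_batch(self):
        rng = np.random.default_rng(1)
        n, e, heads = 6, 14, 3
        q = Tensor(rng.standard_normal((n, heads, 4)))
        k = Tensor(rng.standard_normal((n, heads, 4)))
        dst = rng.integers(0, n, e)
        src = rng.integers(0, n, e)
        alpha = decay_attention(q, k, dst, src,
                                rng.integers(1, 4, e).astype(float),
                                Tensor(0.3), n)
        sums = np.zeros((n, heads))
        np.add.at(sums, dst, alpha.data)
        present = np.unique(dst)
        np.testing.assert_allclose(sums[present], 1.0, rtol=1e-12)


class TestAggregation:
    def test_identical_members_give_convex_fixed_point(self):
        from dama.model import aggregate_hop

        v = Tensor(np.tile(np.array([[2.0, -1.0]]), (3, 1)).reshape(3, 1, 2))
        alpha = Tensor(np.array([[0.3], [0.7]]))
        agg = aggregate_hop(v, alpha, dst=np.array([0, 0]),
                            src=np.array([1, 2]), n_nodes=3)
        np.testing.assert_allclose(agg.data[0], [2.0, -1.0])

    def test_hand_weighted_sum_three_members(self):
        from dama.model import aggregate_hop

        vals = np.arange(8, dtype=float).reshape(4, 1, 2)
        w = np.array([[0.2], [0.5], [0.3]])
        agg = aggregate_hop(Tensor(vals), Tensor(w),
                            dst=np.array([0, 0, 0]), src=np.array([1, 2, 3]),
                            n_nodes=4)
        expected = 0.2 * vals[1, 0] + 0.5 * vals[2, 0] + 0.3 * vals[3, 0]
        np.testing.assert_allclose(agg.data[0], expected)

    def test_layer_norm_zero_row_stays_zero(self):
        x = Tensor(np.zeros((2, 4)))
        out = layer_norm(x, Tensor(np.ones(4)), Tensor(np.zeros(4)))
        np.testing.assert_allclose(out.data, 0.0)


class TestGates:
    def test_zero_routing_matrix_gives_uniform_gate(self):
        g = base_gate(np.array([[5.0, 2.0], [1.0, 0.0]]),
                      Tensor(np.zeros((3, 2))))
        np.testing.assert_allclose(g.data, 1 / 3)

    def test_simplex_property(self):
        rng = np.random.default_rng(2)
        g = base_gate(rng.standard_normal((10, 2)) * 5,
                      Tensor(rng.standard_normal((4, 2))))
        assert np.all(g.data > 0)
        np.testing.assert_allclose(g.data.sum(axis=1), 1.0, rtol=1e-12)

    def test_hand_softmax_row(self):
        w_r = Tensor(np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]]))
        g = base_gate(np.array([[1.0, 0.0]]), w_r)
        np.testing.assert_allclose(
            g.data[0], [0.57611688, 0.21194156, 0.21194156], atol=1e-7)

    def test_constant_batch_features_zero_the_feedback_gate(self):
        h = Tensor(np.tile(np.array([[1.0, 2.0]]), (5, 1)))
        dg = feedback_gate(h, Tensor(np.ones((3, 2))))
        np.testing.assert_allclose(dg.data, 0.0, atol=1e-5)

    def test_zero_projection_zeros_the_gate(self):
        h = Tensor(np.random.default_rng(3).standard_normal((6, 4)))
        dg = feedback_gate(h, Tensor(np.zeros((2, 4))))
        np.testing.assert_allclose(dg.data, 0.0)

    def test_hand_population_std_example(self):
        # batch [[0,0],[2,2]]: population std = [1,1]; Wf row [1,1] -> tanh(2)
        h = Tensor(np.array([[0.0, 0.0], [2.0, 2.0]]))
        w_f = Tensor(np.array([[1.0, 1.0], [0.5, 0.0]]))
        dg = feedback_gate(h, w_f)
        assert dg.data[0] == pytest.approx(math.tanh(2.0), abs=1e-6)
        assert dg.data[1] == pytest.approx(math.tanh(0.5), abs=1e-6)


def tiny_params(rng, d, c):
    return {
        "fuse_w1": Tensor(rng.standard_normal((d, d)) * 0.3, requires_grad=True),
        "fuse_b1": Tensor(np.zeros(d), requires_grad=True),
        "fuse_w2": Tensor(rng.standard_normal((d, d)) * 0.3, requires_grad=True),
        "fuse_b2": Tensor(np.zeros(d), requires_grad=True),
        "clf_w1": Tensor(rng.standard_normal((d, 3)) * 0.3, requires_grad=True),
        "clf_b1": Tensor(np.zeros(3), requires_grad=True),
        "clf_w2": Tensor(rng.standard_normal((3, c)) * 0.3, requires_grad=True),
        "clf_b2": Tensor(np.zeros(c), requires_grad=True),
    }


class TestFuseClassify:
    def test_zero_gates_reduce_to_bias_pathway(self):
        rng = np.random.default_rng(4)
        params = tiny_params(rng, 4, 2)
        hops = [Tensor(rng.standard_normal((3, 4))) for _ in range(2)]
        scores = fuse_and_classify(hops, Tensor(np.zeros((3, 2))), params)
        # zero fusion input for every node -> identical rows
        np.testing.assert_allclose(scores.data - scores.data[0][None, :],
                                   0.0, atol=1e-12)

    def test_one_hot_gate_selects_single_hop(self):
        rng = np.random.default_rng(5)
        params = tiny_params(rng, 4, 2)
        hops = [Tensor(rng.standard_normal((3, 4))) for _ in range(2)]
        gates = Tensor(np.tile(np.array([[1.0, 0.0]]), (3, 1)))
        got = fuse_and_classify(hops, gates, params)
        direct = fuse_and_classify([hops[0]], Tensor(np.ones((3, 1))), params)
        np.testing.assert_allclose(got.data, direct.data, atol=1e-12)

    def test_matches_straight_line_numpy_forward(self):
        rng = np.random.default_rng(6)
        params = tiny_params(rng, 4, 2)
        hops = [Tensor(rng.standard_normal((2, 4))) for _ in range(3)]
        gates_arr = rng.uniform(-0.5, 0.5, (2, 3))
        got = fuse_and_classify(hops, Tensor(gates_arr), params).data
        fused = sum(gates_arr[:, k:k + 1] * hops[k].data for k in range(3))
        z = np.maximum(fused @ params["fuse_w1"].data, 0)
        z = z @ params["fuse_w2"].data
        z = np.maximum(z @ params["clf_w1"].data, 0)
        expected = z @ params["clf_w2"].data
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestLoss:
    def test_uniform_scores_give_log_c(self):
        n, c = 5, 4
        scores = Tensor(np.zeros((n, c)))
        labels = np.array([0, 1, 2, 3, 0])
        loss = model_loss(scores, labels, np.ones(n, dtype=bool), None, 0.0)
        assert float(loss.data) == pytest.approx(math.log(c))

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        labels = np.array([0, 1, 1])
        scores = np.full((3, 2), -50.0)
        scores[np.arange(3), labels] = 50.0
        loss = model_loss(Tensor(scores), labels, np.ones(3, dtype=bool), None, 0.0)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_adds_node_averaged_gate_l1(self):
        labels = np.array([0, 1])
        scores = Tensor(np.zeros((2, 2)))
        gates = Tensor(np.array([[0.5, -0.25], [0.1, 0.2]]))
        mask = np.ones(2, dtype=bool)
        base = float(model_loss(scores, labels, mask, gates, 0.0).data)
        full = float(model_loss(scores, labels, mask, gates, 2.0).data)
        assert full - base == pytest.approx(2.0 * (0.75 + 0.3) / 2)

    def test_empty_training_mask_rejected(self):
        with pytest.raises(ValueError):
            model_loss(Tensor(np.zeros((2, 2))), np.array([0, 1]),
                       np.zeros(2, dtype=bool), None, 0.0)


def small_pipeline(seed=0, **model_kw):
    g = generate_planted_partition([10, 10], 0.7, 0.05, seed=seed)
    ifm = build_ifm(build_pim(g), g)
    nbrs = sample_all(g, ifm, SamplingConfig())
    cfg = ModelConfig(n_heads=2, head_dim=4, fusion_hidden=8, clf_hidden=4,
                      dropout=0.0, **model_kw)
    batch = prepare_batch(g, nbrs, ifm, cfg.max_hops)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((g.n_nodes, 5))
    return g, x, batch, cfg


class TestModelForward:
    def test_gate_invariants_on_forward(self):
        g, x, batch, cfg = small_pipeline(seed=1)
        model = DAMAModel(x.shape[1], 2, cfg, seed=1)
        scores, g_final, hops = model.forward(x, batch)
        assert scores.data.shape == (g.n_nodes, 2)
        assert np.all(np.abs(g_final.data) < 1.0)
        assert all(np.isfinite(h.data).all() for h in hops)

    def test_no_msg_ablation_changes_parameters_and_output(self):
        g, x, batch, cfg = small_pipeline(seed=2)
        full = DAMAModel(x.shape[1], 2, cfg, seed=2)
        nomsg = DAMAModel(x.shape[1], 2,
                          dataclasses.replace(cfg, no_msg=True), seed=2)
        assert nomsg.n_parameters() < full.n_parameters()
        missing = set(full.params) - set(nomsg.params)
        assert missing == {"w_r", "w_f"}
        s_full, gf, _ = full.forward(x, batch)
        s_nomsg, gn, _ = nomsg.forward(x, batch)
        assert gf is not None and gn is None
        assert not np.allclose(s_full.data, s_nomsg.data)

    def test_attention_lambda_receives_gradient(self):
        """Distance-heterogeneous neighbourhoods make the decay learnable."""
        g, x, batch, cfg = small_pipeline(seed=3)
        assert any(np.unique(d).size > 1 for d in batch.dist if d.size)
        model = DAMAModel(x.shape[1], 2, cfg, seed=3)
        scores, g_final, _ = model.forward(x, batch)
        loss = model_loss(scores, g.labels, np.ones(g.n_nodes, dtype=bool),
                          g_final, cfg.kappa)
        loss.backward()
        assert model.params["lam"].grad is not None
        assert abs(float(model.params["lam"].grad)) > 0

    def test_kappa_pressure_shrinks_gates(self):
        """Mean |final gate| at convergence is non-increasing in κ."""
        from dama.training import Adam

        means = []
        for kappa in (0.0, 1e-2, 1.0):
            g, x, batch, cfg = small_pipeline(seed=4, kappa=kappa)
            model = DAMAModel(x.shape[1], 2, cfg, seed=4)
            opt = Adam(model.params, lr=1e-2)
            for _ in range(150):
                opt.zero_grad()
                scores, g_final, _ = model.forward(x, batch)
                loss = model_loss(scores, g.labels,
                                  np.ones(g.n_nodes, dtype=bool),
                                  g_final, kappa)
                loss.backward()
                opt.step()
            _, g_final, _ = model.forward(x, batch)
            means.append(float(np.abs(g_final.data).mean()))
        assert means[1] <= means[0] + 1e-6
        assert means[2] <= means[1] + 1e-6

    def test_checkpoint_roundtrip_reproduces_predictions(self, tmp_path):
        g, x, batch, cfg = small_pipeline(seed=5)
        model = DAMAModel(x.shape[1], 2, cfg, seed=5)
        path = str(tmp_path / "ckpt.json")
        model.save(path)
        clone = DAMAModel.load(path)
        s1, _, _ = model.forward(x, batch)
        s2, _, _ = clone.forward(x, batch)
        np.testing.assert_array_equal(s1.data, s2.data)
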