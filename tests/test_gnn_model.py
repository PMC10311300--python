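"""Model-level contracts: attention aggregation, residual block update,
heterogeneous reduction, head scoring, serialization, determinism."""

import numpy as np
import pytest

from netalign import autodiff as ad
from netalign.autodiff import Tensor
from netalign.gnn_model import (AlignerModel, GraphFeatures, ModelConfig,
                                across_message, attention_weights, bce_loss,
                                block_update, pair_norm, within_message)
from netalign.network_io import AnchorSet, ValidationError, build_joint_graph
from conftest import net_from_edges, toy_features

rng = np.random.default_rng(0)


def toy_model(jg, seed=0, n_blocks=2, hidden=8, pos_dim=1, **kw):
    cfg = ModelConfig(hidden_dim=hidden, n_blocks=n_blocks,
                      anchor_types=tuple(jg.anchor_types), pos_dim=pos_dim,
                      dropout=0.0, seed=seed, **kw)
    return AlignerModel(cfg, jg.n1, jg.n2)


class TestWithinMessage:
    def test_single_neighbour_passes_embedding_through(self):
        net = net_from_edges([("a", "b"), ("b", "c")])  # a has only b
        adj = net.adjacency()
        h = Tensor(rng.normal(size=(3, 4)))
        m = within_message(h, adj, Tensor(1.3))
        i_a, i_b = net.index["a"], net.index["b"]
        np.testing.assert_allclose(m.v[i_a], h.v[i_b])

    def test_identical_neighbours_average(self):
        net = net_from_edges([("a", "b"), ("a", "c")])
        adj = net.adjacency()
        h_v = rng.normal(size=(3, 5))
        h_v[net.index["c"]] = h_v[net.index["b"]]
        m = within_message(Tensor(h_v), adj, Tensor(2.0))
        np.testing.assert_allclose(m.v[net.index["a"]],
                                   h_v[net.index["b"]])

    def test_zero_temperature_gives_neighbour_mean(self):
        net = net_from_edges([("a", "b"), ("a", "c"), ("a", "d")])
        adj = net.adjacency()
        h_v = rng.normal(size=(4, 3))
        m = within_message(Tensor(h_v), adj, Tensor(0.0))
        nb = [net.index[x] for x in "bcd"]
        np.testing.assert_allclose(m.v[net.index["a"]],
                                   h_v[nb].mean(axis=0))

    def test_isolated_in_adjacency_gets_zero(self):
        import scipy.sparse as sp
        adj = sp.csr_matrix(np.array([[0, 1], [1, 0.]]))
        padded = sp.block_diag((adj, sp.csr_matrix((1, 1))), format="csr")
        m = within_message(Tensor(rng.normal(size=(3, 4))), padded,
                           Tensor(1.0))
        np.testing.assert_array_equal(m.v[2], 0.0)


class TestAttentionWeights:
    @pytest.mark.parametrize("mode", ["channel", "scalar"])
    def test_normalised_and_consistent_with_messages(self, mode):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        adj = net.adjacency()
        h_v = rng.normal(size=(4, 3))
        temp = 0.7
        W = attention_weights(h_v, adj, temp, mode)
        deg = adj.toarray().sum(axis=1)
        sums = W.sum(axis=1)
        for i in range(4):
            expect = 1.0 if deg[i] else 0.0
            np.testing.assert_allclose(sums[i], expect, atol=1e-12)
        m = within_message(Tensor(h_v), adj, Tensor(temp), mode)
        np.testing.assert_allclose(m.v, np.einsum("ijc,jc->ic", W, h_v),
                                   atol=1e-12)


class TestAcrossMessage:
    def test_no_anchor_gives_zero_and_singleton_passes_through(
            self, toy_joint_graph):
        jg = toy_joint_graph
        h_v = rng.normal(size=(jg.n, 4))
        mu = across_message(Tensor(h_v), jg.anchor_adjacency("ortholog"),
                            Tensor(1.0))
        # only (a,u) is an ortholog anchor
        ia, iu = jg.index["sp1:a"], jg.index["sp2:u"]
        np.testing.assert_allclose(mu.v[ia], h_v[iu])
        np.testing.assert_allclose(mu.v[iu], h_v[ia])
        for node in ("sp1:b", "sp1:c", "sp2:v", "sp2:w"):
            np.testing.assert_array_equal(mu.v[jg.index[node]], 0.0)


class TestBlockUpdate:
    def test_zero_mlps_reduce_to_residual(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg)
        for k, p in model.params.items():
            if k.startswith("block0."):
                p.v = np.zeros_like(p.v)
        h = Tensor(rng.normal(size=(jg.n, 8)))
        m = Tensor(rng.normal(size=(jg.n, 8)))
        mus = {r: Tensor(rng.normal(size=(jg.n, 8)))
               for r in jg.anchor_types}
        out = block_update(h, m, mus, model.params, "block0")
        np.testing.assert_array_equal(out.v, h.v)

    def test_single_type_equals_homogeneous_formula(self):
        g1 = net_from_edges([("a", "b"), ("b", "c")], "species1")
        g2 = net_from_edges([("u", "v")], "species2")
        jg = build_joint_graph(g1, g2, [AnchorSet("ortholog", {("a", "u")})])
        model = toy_model(jg, n_blocks=1)
        h = Tensor(rng.normal(size=(jg.n, 8)))
        gamma = model.params["block0.gamma"]
        omega = model.params["block0.ac.ortholog.omega"]
        m = within_message(h, jg.within_adjacency(), gamma)
        mu = across_message(h, jg.anchor_adjacency("ortholog"), omega)
        het = block_update(h, m, {"ortholog": mu}, model.params, "block0")

        def mlp(x, pfx):
            p = model.params
            return (x @ p[f"{pfx}.W1"] + p[f"{pfx}.b1"]).relu() \
                @ p[f"{pfx}.W2"] + p[f"{pfx}.b2"]

        homog = h + mlp(h + m, "block0.within") \
            + mlp(h + mu, "block0.ac.ortholog")
        np.testing.assert_array_equal(het.v, homog.v)


class TestPairNorm:
    def test_zero_mean_and_unit_scale(self):
        h = Tensor(rng.normal(size=(10, 6)) * 3 + 2)
        out = pair_norm(h, scale=1.0)
        np.testing.assert_allclose(out.v.mean(axis=0), 0.0, atol=1e-12)
        msq = (out.v ** 2).sum(axis=1).mean()
        assert msq == pytest.approx(1.0, rel=1e-6)


class TestForward:
    def test_interblock_pairnorm_statistics(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg, n_blocks=3)
        feats = toy_features(jg)
        captured = []
        model.forward(feats, capture=captured)
        assert len(captured) == 2  # between blocks only, not after last
        for h in captured:
            np.testing.assert_allclose(h.mean(axis=0), 0.0, atol=1e-5)
            assert (h ** 2).sum(axis=1).mean() == pytest.approx(1.0, rel=1e-5)

    def test_single_block_is_one_update_of_init_features(
            self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg, n_blocks=1)
        feats = toy_features(jg)
        out = model.forward(feats)
        h0 = model.init_features(feats)
        m = within_message(h0, feats.within_adj, model.params["block0.gamma"])
        mus = {r: across_message(h0, feats.anchor_adj[r],
                                 model.params[f"block0.ac.{r}.omega"])
               for r in jg.anchor_types}
        expect = block_update(h0, m, mus, model.params, "block0")
        np.testing.assert_array_equal(out.v, expect.v)

    def test_deterministic_across_runs(self, toy_joint_graph):
        jg = toy_joint_graph
        feats = toy_features(jg)
        h1 = toy_model(jg, seed=3).forward(feats)
        h2 = toy_model(jg, seed=3).forward(feats)
        np.testing.assert_array_equal(h1.v, h2.v)

    def test_init_features_width_and_zero_map(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg, hidden=8)
        feats = toy_features(jg)
        h0 = model.init_features(feats)
        assert h0.shape == (jg.n, 8)
        for k in list(model.params):
            if k.startswith("proj."):
                model.params[k].v = np.zeros_like(model.params[k].v)
        np.testing.assert_array_equal(model.init_features(feats).v, 0.0)


class TestScoring:
    def test_scores_in_open_interval_and_duplicates_identical(
            self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg)
        feats = toy_features(jg)
        pairs = [("a", "u"), ("b", "w"), ("a", "u")]
        s = model.score_pairs(feats, pairs)
        assert np.all((s > 0) & (s < 1))
        assert s[0] == s[2]

    def test_batched_equals_per_pair(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg)
        feats = toy_features(jg)
        pairs = [("a", "u"), ("b", "v"), ("c", "w")]
        batched = model.score_pairs(feats, pairs)
        single = [model.score_pairs(feats, [p])[0] for p in pairs]
        np.testing.assert_allclose(batched, single)

    def test_zero_head_scores_half(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg)
        for k in model.head_param_names():
            model.params[k].v = np.zeros_like(model.params[k].v)
        feats = toy_features(jg)
        s = model.score_pairs(feats, [("a", "u"), ("c", "v")])
        np.testing.assert_allclose(s, 0.5)

    def test_wrong_species_order_rejected(self, toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg)
        feats = toy_features(jg)
        with pytest.raises(ValidationError):
            model.score_pairs(feats, [("u", "a")])


class TestBCELoss:
    def test_closed_forms(self):
        assert bce_loss(np.array([0.5, 0.5]),
                        np.array([1.0, 0.0])) == pytest.approx(np.log(2))
        assert bce_loss(np.array([0.9]),
                        np.array([1.0])) == pytest.approx(-np.log(0.9))

    def test_perfect_scores_below_clamp_floor(self):
        loss = bce_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert 0 <= loss <= -np.log(1 - 1e-12) + 1e-15

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))


class TestSerialization:
    def test_round_trip_reproduces_scores_exactly(self, tmp_path,
                                                  toy_joint_graph):
        jg = toy_joint_graph
        model = toy_model(jg, seed=11)
        feats = toy_features(jg)
        pairs = [("a", "v"), ("b", "u")]
        before = model.score_pairs(feats, pairs)
        model.save(tmp_path / "ckpt.npz")
        back = AlignerModel.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(back.score_pairs(feats, pairs), before)

    def test_config_round_trip(self, tmp_path, toy_joint_graph):
        model = toy_model(toy_joint_graph, n_blocks=3, hidden=10)
        model.save(tmp_path / "m.npz")
        back = AlignerModel.load(tmp_path / "m.npz")
        assert back.config == model.config
        assert set(back.params) == set(model.params)


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(hidden_dim=7)
        with pytest.raises(ValidationError):
            ModelConfig(n_blocks=0)
        with pytest.raises(ValidationError):
            ModelConfig(anchor_types=())
        with pytest.raises(ValidationError):
            ModelConfig(attention="softmax?")
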