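import dataclasses

import numpy as np
import pytest

import pathorm as pm
from pathorm.core_io import ValidationError
from pathorm.gae import (
    EncoderVariant,
    _forward_all,
    _graph_operator,
    _loss_and_grad_z,
    init_params,
    load_model,
    save_model,
)
from pathorm.hetgraph import HeteroGraph


def _graph(adj, feats, m):
    n = adj.shape[0] - m
    return HeteroGraph(
        adjacency=adj,
        node_features=feats,
        m=m,
        n=n,
        site_index=[f"s{i}" for i in range(m)],
        disease_index=[f"d{j}" for j in range(n)],
    )


def _path_graph():
    adj = np.array([[0.0, 1.0], [1.0, 0.0]])
    feats = np.array([[1.0], [2.0]])
    return _graph(adj, feats, 1)


class TestGnnForward:
    def test_gin_identity_mlp_sums_neighbours(self):
        g = _path_graph()
        p = {"W1": np.eye(1), "b1": np.zeros(1), "W2": np.eye(1), "b2": np.zeros(1)}
        out = pm.gnn_forward(g, g.node_features, p, "gin", activation="identity")
        np.testing.assert_allclose(out, [[3.0], [3.0]])

    def test_gcn_renormalized_averaging(self):
        g = _graph(np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([[1.0], [3.0]]), 1)
        p = {"W": np.eye(1), "b": np.zeros(1)}
        out = pm.gnn_forward(g, g.node_features, p, "gcn", activation="identity")
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    def test_gin_no_edges_is_identity(self):
        g = _graph(np.zeros((3, 3)), np.arange(6.0).reshape(3, 2), 2)
        p = {"W1": np.eye(2), "b1": np.zeros(2), "W2": np.eye(2), "b2": np.zeros(2)}
        out = pm.gnn_forward(g, g.node_features, p, "gin", activation="identity")
        np.testing.assert_allclose(out, g.node_features)

    def test_sage_isolated_node_mean_is_zero(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        g = _graph(adj, np.ones((3, 2)), 2)
        p = {"W1": np.zeros((2, 2)), "W2": np.eye(2), "b": np.zeros(2)}
        out = pm.gnn_forward(g, g.node_features, p, "sage", activation="identity")
        np.testing.assert_allclose(out[2], [0.0, 0.0])  # no neighbours

    @pytest.mark.parametrize("variant", ["gcn", "sage", "gin"])
    def test_matches_dense_brute_force(self, variant):
        """Layer output equals the per-node formula on random graphs <=5 nodes."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = int(rng.integers(2, 6))
            m = max(1, t - 1)
            adj = (rng.random((t, t)) < 0.5).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            H = rng.standard_normal((t, 3))
            g = _graph(adj, H, m)
            params = init_params(EncoderVariant(variant), 3, 4, 1, seed)[0]
            got = pm.gnn_forward(g, H, params, variant, activation="relu")
            expected = np.empty((t, 4))
            for vtx in range(t):
                nb = np.flatnonzero(adj[vtx])
                if variant == "gcn":
                    z = np.zeros(3)
                    dv = len(nb) + 1
                    for u in list(nb) + [vtx]:
                        du = adj[u].sum() + 1
                        z += H[u] / np.sqrt(dv * du)
                    expected[vtx] = z @ params["W"] + params["b"]
                elif variant == "sage":
                    mean_nb = H[nb].mean(axis=0) if len(nb) else np.zeros(3)
                    expected[vtx] = H[vtx] @ params["W1"] + mean_nb @ params["W2"] + params["b"]
                else:
                    agg = H[vtx] + H[nb].sum(axis=0)
                    expected[vtx] = agg @ params["W1"] + params["b1"]
            if variant == "gin":
                # normalise per feature over nodes, then ReLU and second layer
                mu, var = expected.mean(axis=0), expected.var(axis=0)
                zhat = (expected - mu) / np.sqrt(var + 1e-5)
                h1 = np.maximum(params["gamma"] * zhat + params["beta"], 0.0)
                expected = h1 @ params["W2"] + params["b2"]
            np.testing.assert_allclose(got, np.maximum(expected, 0.0), atol=1e-6)


class TestEncode:
    def test_zero_features_zero_embedding(self):
        g = _graph(np.zeros((3, 3)), np.zeros((3, 2)), 2)
        cfg = pm.EncoderConfig(variant="gcn", layers=3, hidden_dim=4, seed=0)
        params = init_params(cfg.variant, 2, 4, 3, 0)
        emb = pm.encode(g, cfg, params)
        np.testing.assert_array_equal(emb.H, 0.0)

    def test_deterministic_across_runs(self, tiny_graph):
        g, _ = tiny_graph
        cfg = pm.EncoderConfig(variant="gin", hidden_dim=8, seed=3)
        params = init_params(cfg.variant, g.node_features.shape[1], 8, 3, 3)
        h1 = pm.encode(g, cfg, params).H
        h2 = pm.encode(g, cfg, params).H
        np.testing.assert_array_equal(h1, h2)

    def test_single_layer_matches_gnn_forward(self):
        g = _path_graph()
        p = {"W1": np.eye(1), "b1": np.zeros(1), "W2": np.eye(1), "b2": np.zeros(1)}
        cfg = pm.EncoderConfig(variant="gin", layers=1, hidden_dim=1)
        emb = pm.encode(g, cfg, [p])
        out = pm.gnn_forward(g, g.node_features, p, "gin", activation="identity")
        np.testing.assert_allclose(emb.H, out)


class TestDecode:
    def test_zero_embeddings_score_half(self):
        s = pm.decode(np.zeros((2, 3)), np.zeros((4, 3)))
        np.testing.assert_allclose(s.values, 0.5)

    @pytest.mark.parametrize(
        "hs,hd,expected",
        [([1.0, 0.0], [1.0, 0.0], 0.7311), ([2.0], [-1.0], 0.1192)],
    )
    def test_logistic_of_inner_product(self, hs, hd, expected):
        s = pm.decode(np.array([hs]), np.array([hd]))
        assert s.values[0, 0] == pytest.approx(expected, abs=1e-4)

    def test_monotone_in_inner_product(self, rng):
        h_d = rng.standard_normal((1, 4))
        base = rng.standard_normal(4)
        scores = [
            pm.decode((base + t * h_d[0]).reshape(1, -1), h_d).values[0, 0]
            for t in np.linspace(0, 2, 5)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            pm.decode(np.zeros((1, 2)), np.zeros((1, 3)))


class TestWceLoss:
    def test_balanced_toy(self):
        assoc = pm.AssociationTable(
            {("s0", "d0")}, {("s0", "d1")}, ["s0"], ["d0", "d1"]
        )
        scores = np.full((1, 2), 0.5)
        assert pm.wce_loss(scores, assoc) == pytest.approx(0.6931, abs=1e-4)

    def test_imbalanced_toy(self):
        assoc = pm.AssociationTable(
            {("s0", "d0")}, {("s0", "d1"), ("s0", "d2")}, ["s0"], ["d0", "d1", "d2"]
        )
        scores = np.array([[0.8, 0.4, 0.4]])
        assert pm.wce_loss(scores, assoc) == pytest.approx(0.4893, abs=1e-4)

    def test_perfect_predictions_near_zero(self):
        assoc = pm.AssociationTable(
            {("s0", "d0")}, {("s0", "d1")}, ["s0"], ["d0", "d1"]
        )
        scores = np.array([[1.0 - 1e-9, 1e-9]])
        assert pm.wce_loss(scores, assoc) == pytest.approx(0.0, abs=1e-5)

    def test_reduces_to_unweighted_when_balanced(self, rng):
        sites = [f"s{i}" for i in range(3)]
        diseases = [f"d{j}" for j in range(4)]
        pos = {("s0", "d0"), ("s1", "d1"), ("s2", "d2")}
        neg = {("s0", "d1"), ("s1", "d2"), ("s2", "d3")}
        assoc = pm.AssociationTable(pos, neg, sites, diseases)
        X = rng.uniform(0.05, 0.95, (3, 4))
        got = pm.wce_loss(X, assoc)
        idx_p = assoc.pair_indices(sorted(pos))
        idx_n = assoc.pair_indices(sorted(neg))
        expected = -(
            np.log(X[idx_p[:, 0], idx_p[:, 1]]).sum()
            + np.log(1 - X[idx_n[:, 0], idx_n[:, 1]]).sum()
        ) / 12
        assert got == pytest.approx(expected)

    def test_empty_positives_rejected(self):
        assoc = pm.AssociationTable(set(), {("s0", "d0")}, ["s0"], ["d0"])
        with pytest.raises(ValidationError):
            pm.wce_loss(np.full((1, 1), 0.5), assoc)


class TestFgmPerturbation:
    @pytest.mark.parametrize(
        "grad,eps,expected",
        [([3.0, 4.0], 1.0, [0.6, 0.8]), ([0.0, 2.0], 0.5, [0.0, 0.5])],
    )
    def test_normalization(self, grad, eps, expected):
        r, skipped = pm.fgm_perturbation(np.array(grad), eps)
        assert not skipped
        np.testing.assert_allclose(r, expected)

    def test_zero_gradient_skips(self):
        r, skipped = pm.fgm_perturbation(np.zeros((2, 2)), 0.5)
        assert skipped
        np.testing.assert_array_equal(r, 0.0)

    def test_norm_equals_epsilon(self, rng):
        for _ in range(20):
            g = rng.standard_normal((5, 3))
            eps = float(rng.uniform(0.01, 2.0))
            r, _ = pm.fgm_perturbation(g, eps)
            assert np.linalg.norm(r) == pytest.approx(eps, abs=1e-9)


class TestTrain:
    def _setup(self, tiny_graph):
        g, assoc = tiny_graph
        enc = pm.EncoderConfig(variant="gin", hidden_dim=6, seed=1)
        tr = pm.TrainConfig(epochs=10, seed=1)
        return g, assoc, enc, tr

    def test_disabled_adversarial_losses_equal_clean(self, tiny_graph):
        g, assoc, enc, tr = self._setup(tiny_graph)
        model = pm.train(g, assoc, enc, pm.AdvConfig(enabled=False), tr)
        assert model.loss_history["clean"] == model.loss_history["adv"]

    def test_same_seed_identical_history(self, tiny_graph):
        g, assoc, enc, tr = self._setup(tiny_graph)
        m1 = pm.train(g, assoc, enc, pm.AdvConfig(enabled=True), tr)
        m2 = pm.train(g, assoc, enc, pm.AdvConfig(enabled=True), tr)
        assert m1.loss_history == m2.loss_history
        for p1, p2 in zip(m1.params, m2.params):
            for k in p1:
                np.testing.assert_array_equal(p1[k], p2[k])

    def test_adversarial_loss_at_least_clean_first_order(self):
        """FGM moves along the loss gradient, so for small eps the perturbed
        loss should not fall below the clean loss at the same parameters."""
        wins = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            t = 6
            adj = (rng.random((t, t)) < 0.5).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            g = _graph(adj, rng.standard_normal((t, 3)), 3)
            assoc = pm.AssociationTable(
                {("s0", "d0"), ("s2", "d1")},
                {("s1", "d0"), ("s0", "d2")},
                g.site_index,
                g.disease_index,
            )
            enc = pm.EncoderConfig(variant="gcn", hidden_dim=4, seed=seed)
            model = pm.train(
                g, assoc, enc,
                pm.AdvConfig(enabled=True, epsilon=1e-2),
                pm.TrainConfig(epochs=1, seed=seed),
            )
            if model.loss_history["adv"][0] >= model.loss_history["clean"][0] - 1e-12:
                wins += 1
        assert wins >= 95

    def test_loss_decreases_with_training(self, tiny_graph):
        g, assoc, enc, _ = self._setup(tiny_graph)
        model = pm.train(g, assoc, enc, pm.AdvConfig(enabled=False),
                         pm.TrainConfig(epochs=300, seed=1))
        h = model.loss_history["clean"]
        assert h[-1] < h[0]

    def test_target_layer_beyond_depth_rejected(self, tiny_graph):
        g, assoc, enc, tr = self._setup(tiny_graph)
        with pytest.raises(ValidationError):
            pm.train(g, assoc, enc, pm.AdvConfig(enabled=True, target_layers=(4,)), tr)


class TestPredict:
    def test_empty_pairs(self, tiny_graph):
        g, assoc = tiny_graph
        model = pm.train(g, assoc, pm.EncoderConfig(hidden_dim=4, seed=0),
                         pm.AdvConfig(enabled=False), pm.TrainConfig(epochs=2))
        assert pm.predict(model, g, []).shape == (0,)

    def test_full_matrix_consistency_and_duplicates(self, tiny_graph):
        g, assoc = tiny_graph
        model = pm.train(g, assoc, pm.EncoderConfig(hidden_dim=4, seed=0),
                         pm.AdvConfig(enabled=False), pm.TrainConfig(epochs=2))
        pairs = [(s, d) for s in g.site_index for d in g.disease_index]
        got = pm.predict(model, g, pairs + [pairs[0]])
        full = pm.score_matrix(model, g).values
        np.testing.assert_array_equal(got[:-1], full.ravel())
        assert got[-1] == got[0]

    def test_unknown_id_rejected(self, tiny_graph):
        g, assoc = tiny_graph
        model = pm.train(g, assoc, pm.EncoderConfig(hidden_dim=4, seed=0),
                         pm.AdvConfig(enabled=False), pm.TrainConfig(epochs=2))
        with pytest.raises(ValidationError):
            pm.predict(model, g, [("sX", "d0")])


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_graph, tmp_path):
        g, assoc = tiny_graph
        model = pm.train(g, assoc, pm.EncoderConfig(variant="sage", hidden_dim=4, seed=0),
                         pm.AdvConfig(enabled=False), pm.TrainConfig(epochs=2))
        save_model(model, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        for p1, p2 in zip(model.params, loaded.params):
            for k in p1:
                np.testing.assert_allclose(p1[k], p2[k])
        s1 = pm.score_matrix(model, g).values
        s2 = pm.score_matrix(loaded, g).values
        np.testing.assert_allclose(s1, s2)
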