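"""Model-layer oracles, attention normalization, and training sanity."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse as sp
from scipy.special import expit

from medhg import hetgraph as hg
from medhg._autodiff import Tensor
from medhg.iehgcn import (SELF, IEHGCNClassifier, LayerParams, bce_loss,
                          project, train, tune, type_attention)


def _toy_layer(rng, types, rels, d_in, d_out, d_a):
    """Random LayerParams for explicit type/relation rosters."""
    lp = LayerParams()
    for t in types:
        lp.w_self[t] = Tensor(rng.normal(0, 0.5, (d_in, d_out)), requires_grad=True)
        lp.w_query[t] = Tensor(rng.normal(0, 0.5, (d_out, d_a)), requires_grad=True)
        lp.w_attn[t] = Tensor(rng.normal(0, 0.5, (2 * d_a, 1)), requires_grad=True)
        lp.w_key[(t, SELF)] = Tensor(rng.normal(0, 0.5, (d_out, d_a)),
                                     requires_grad=True)
    for (s, t) in rels:
        lp.w_rel[(s, t)] = Tensor(rng.normal(0, 0.5, (d_in, d_out)),
                                  requires_grad=True)
        lp.w_key[(t, s)] = Tensor(rng.normal(0, 0.5, (d_out, d_a)),
                                  requires_grad=True)
    return lp


class TestProject:
    def test_identity_adjacency_identity_weights(self):
        H = {"A": Tensor(np.arange(6.0).reshape(3, 2)),
             "B": Tensor(np.ones((3, 2)))}
        lp = LayerParams(w_self={"A": Tensor(np.eye(2))},
                         w_rel={("B", "A"): Tensor(np.eye(2))})
        Z = project(H, lp, {("A", "B"): sp.eye(3, format="csr")})
        np.testing.assert_allclose(Z[("A", SELF)].value, H["A"].value)
        np.testing.assert_allclose(Z[("A", "B")].value, H["B"].value)

    def test_zero_adjacency_row_gives_zero_message(self):
        H = {"A": Tensor(np.zeros((2, 2))), "B": Tensor(np.ones((3, 2)))}
        A_hat = sp.csr_matrix(np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 0.0]]))
        lp = LayerParams(w_self={"A": Tensor(np.eye(2))},
                         w_rel={("B", "A"): Tensor(np.eye(2))})
        Z = project(H, lp, {("A", "B"): A_hat})
        np.testing.assert_array_equal(Z[("A", "B")].value[1], [0.0, 0.0])

    def test_matches_dense_matrix_product_oracle(self):
        rng = np.random.default_rng(4)
        Hb = rng.normal(size=(4, 3))
        A = rng.integers(0, 2, (2, 4)).astype(float)
        A_hat = A / np.maximum(A.sum(1, keepdims=True), 1)
        W = rng.normal(size=(3, 2))
        lp = LayerParams(w_self={"A": Tensor(np.eye(2))},
                         w_rel={("B", "A"): Tensor(W)})
        Z = project({"A": Tensor(np.zeros((2, 2))), "B": Tensor(Hb)},
                    lp, {("A", "B"): sp.csr_matrix(A_hat)})
        np.testing.assert_allclose(Z[("A", "B")].value, A_hat @ Hb @ W,
                                   atol=1e-12)


class TestTypeAttention:
    def test_self_only_gives_coefficient_one(self):
        rng = np.random.default_rng(0)
        lp = _toy_layer(rng, ["A"], [], 2, 2, 3)
        Z_self = Tensor(rng.normal(size=(5, 2)))
        coeffs, order = type_attention(Z_self, {}, lp, "A")
        assert order == [SELF]
        np.testing.assert_allclose(coeffs.value, np.ones((5, 1)))

    def test_identical_blocks_shared_keys_split_evenly(self):
        rng = np.random.default_rng(1)
        lp = _toy_layer(rng, ["A"], [("B", "A")], 2, 2, 3)
        lp.w_key[("A", "B")] = lp.w_key[("A", SELF)]
        Z_self = Tensor(rng.normal(size=(5, 2)))
        coeffs, _ = type_attention(Z_self, {"B": Tensor(Z_self.value.copy())},
                                   lp, "A")
        np.testing.assert_allclose(coeffs.value, 0.5, atol=1e-12)

    def test_matches_scalar_formula_oracle(self):
        """Coefficients equal direct evaluation of
        softmax(ELU([Z_r W_k || Z W_q] w_a)) per node."""
        rng = np.random.default_rng(2)
        lp = _toy_layer(rng, ["A"], [("B", "A")], 2, 3, 2)
        Z_self = Tensor(rng.normal(size=(4, 3)))
        Z_b = Tensor(rng.normal(size=(4, 3)))
        coeffs, order = type_attention(Z_self, {"B": Z_b}, lp, "A")

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        q = Z_self.value @ lp.w_query["A"].value
        logits = []
        for rel, z in [(SELF, Z_self.value), ("B", Z_b.value)]:
            k = z @ lp.w_key[("A", rel)].value
            logits.append(elu(np.hstack([k, q]) @ lp.w_attn["A"].value))
        L = np.hstack(logits)
        e = np.exp(L - L.max(axis=1, keepdims=True))
        expected = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(coeffs.value, expected, atol=1e-12)

    def test_rows_sum_to_one_on_random_graph(self, small_graph):
        model = IEHGCNClassifier(hidden_dim=8, attn_dim=4, seed=0)
        model.initialize(small_graph)
        _, attention = model.forward(small_graph)
        for layer in attention:
            for target, rels in layer.items():
                total = np.sum([c for c in rels.values()], axis=0)
                np.testing.assert_allclose(total, 1.0, atol=1e-6)


class TestLayerForwardOracle:
    def test_five_node_fixture_matches_stepwise_dense_oracle(self):
        """Full layer equals project -> attention -> weighted sum -> ELU
        computed stepwise with dense numpy arithmetic."""
        from medhg.iehgcn import layer_forward
        rng = np.random.default_rng(5)
        n_a, n_b, d = 5, 3, 2
        H = {"A": Tensor(rng.normal(size=(n_a, d))),
             "B": Tensor(rng.normal(size=(n_b, d)))}
        A_ab = rng.integers(0, 2, (n_a, n_b)).astype(float)
        A_hat_ab = A_ab / np.maximum(A_ab.sum(1, keepdims=True), 1)
        A_hat_ba = A_ab.T / np.maximum(A_ab.T.sum(1, keepdims=True), 1)
        norm_adj = {("A", "B"): sp.csr_matrix(A_hat_ab),
                    ("B", "A"): sp.csr_matrix(A_hat_ba)}
        lp = _toy_layer(rng, ["A", "B"], [("B", "A"), ("A", "B")], d, d, 3)

        schema = hg.NodeSchema(ids={"A": list(range(n_a)), "B": list(range(n_b))})
        graph = hg.HetGraph(schema=schema, relations={})
        H_next, _ = layer_forward(H, lp, graph, norm_adj)

        def elu(x):
            return np.where(x > 0, x, np.expm1(x))

        for tgt, src, A_hat in [("A", "B", A_hat_ab), ("B", "A", A_hat_ba)]:
            z_self = H[tgt].value @ lp.w_self[tgt].value
            z_rel = A_hat @ H[src].value @ lp.w_rel[(src, tgt)].value
            q = z_self @ lp.w_query[tgt].value
            l_self = elu(np.hstack([z_self @ lp.w_key[(tgt, SELF)].value, q])
                         @ lp.w_attn[tgt].value)
            l_rel = elu(np.hstack([z_rel @ lp.w_key[(tgt, src)].value, q])
                        @ lp.w_attn[tgt].value)
            L = np.hstack([l_self, l_rel])
            e = np.exp(L - L.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            expected = elu(a[:, :1] * z_self + a[:, 1:] * z_rel)
            np.testing.assert_allclose(H_next[tgt].value, expected, atol=1e-8)

    def test_homogeneous_mean_aggregation_equivalence(self):
        """The neighbor block of a single-relation layer is exactly the
        dense mean-aggregation GCN update D^-1 A H W."""
        rng = np.random.default_rng(6)
        n, d = 6, 3
        Hv = rng.normal(size=(n, d))
        A = rng.integers(0, 2, (n, n)).astype(float)
        np.fill_diagonal(A, 0)
        W = rng.normal(size=(d, d))
        deg = np.maximum(A.sum(1, keepdims=True), 1)
        lp = LayerParams(w_self={"A": Tensor(np.eye(d))},
                         w_rel={("A", "A"): Tensor(W)})
        Z = project({"A": Tensor(Hv)}, lp, {("A", "A"): sp.csr_matrix(A / deg)})
        np.testing.assert_allclose(Z[("A", "A")].value, (A / deg) @ Hv @ W,
                                   atol=1e-10)


class TestPredictAndLoss:
    def test_two_class_softmax_is_sigmoid_of_logit_difference(self):
        z = np.array([[0.0, 0.0], [0.0, 10.0], [3.0, -1.0]])
        e = np.exp(z - z.max(axis=1, keepdims=True))
        p1 = (e / e.sum(axis=1, keepdims=True))[:, 1]
        np.testing.assert_allclose(p1, expit(z[:, 1] - z[:, 0]), atol=1e-12)
        assert p1[0] == pytest.approx(0.5)
        assert p1[1] == pytest.approx(expit(10.0))

    def test_predict_proba_rows_sum_to_one(self, small_graph, prepared):
        splits, labels, _, _ = prepared
        lab = labels.set_index("encounter_id")["plos"]
        model = IEHGCNClassifier(hidden_dim=8, attn_dim=4, max_epochs=2, seed=0)
        model.fit(small_graph, lab, splits)
        P = model.predict_proba(small_graph)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert ((P > 0) & (P < 1)).all()

    def test_bce_examples_and_summation_oracle(self):
        assert bce_loss([1], [1 - 1e-7]) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-9)
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10)
        p = rng.uniform(0.01, 0.99, 10)
        direct = -np.mean([yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                           for yi, pi in zip(y, p)])
        assert bce_loss(y, p) == pytest.approx(direct, abs=1e-12)
        with pytest.raises(ValueError):
            bce_loss([1, 0], [0.5])


def _separable_toy(n=20, seed=0):
    """20 encounters, one perfectly informative feature, one nurse hub."""
    rng = np.random.default_rng(seed)
    enc_ids = [f"e{i}" for i in range(n)]
    y = np.array([0, 1] * (n // 2))
    feats = pd.DataFrame(
        {"signal": np.where(y == 1, 1.0, -1.0) + 0.01 * rng.normal(size=n),
         "noise": rng.normal(size=n)}, index=enc_ids)
    enc = pd.DataFrame({"encounter_id": enc_ids,
                        "patient_id": enc_ids,
                        "postop_los": 1.0, "death_offset": np.nan})
    asg = pd.DataFrame({"encounter_id": enc_ids, "provider_id": "n1",
                        "role": "nurse"})
    trf = pd.DataFrame(columns=["encounter_id", "unit_type",
                                "sequence_index", "duration"])
    graph = hg.build_heterograph(enc, asg, trf, feats)
    return graph, y


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self):
        """The model fits a linearly separable 20-encounter toy exactly
        (the feature also separates it for a logistic fit)."""
        from sklearn.linear_model import LogisticRegression
        graph, y = _separable_toy()
        X = graph.enc_features
        assert LogisticRegression(C=1e6).fit(X, y).score(X, y) == 1.0
        model = IEHGCNClassifier(hidden_dim=8, attn_dim=4, lr=1e-2,
                                 max_epochs=200, seed=1)
        model.fit(graph, y)
        assert (model.predict(graph) == y).mean() == 1.0

    def test_loss_nonincreasing_over_first_epochs(self):
        graph, y = _separable_toy()
        model = IEHGCNClassifier(hidden_dim=8, attn_dim=4, lr=1e-2,
                                 max_epochs=5, seed=2)
        model.fit(graph, y)
        losses = model.train_report_.epoch_losses
        assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        graph, y = _separable_toy()
        model = IEHGCNClassifier(hidden_dim=4, attn_dim=2, lr=0.0,
                                 weight_decay=0.0, max_epochs=3, seed=3)
        model.initialize(graph)
        before = [p.value.copy() for p in model._parameters()]
        model.fit(graph, y)
        after = [p.value.copy() for p in model._parameters()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_same_seed_reruns_are_bit_identical(self):
        graph, y = _separable_toy()
        runs = []
        for _ in range(2):
            m = IEHGCNClassifier(hidden_dim=6, attn_dim=3, lr=5e-3,
                                 max_epochs=8, dropout=0.2, seed=4)
            m.fit(graph, y)
            runs.append(m.train_report_.epoch_losses)
        assert runs[0] == runs[1]

    def test_empty_training_split_rejected(self):
        graph, y = _separable_toy()
        with pytest.raises(ValueError):
            IEHGCNClassifier(seed=0).fit(graph, y, {"train": [],
                                                    "validation": []})

    def test_early_stopping_on_validation_auroc(self):
        graph, y = _separable_toy()
        ids = graph.schema.ids[hg.ENC]
        splits = {"train": ids[:14], "validation": ids[14:]}
        model = IEHGCNClassifier(hidden_dim=6, attn_dim=3, lr=1e-2,
                                 max_epochs=300, patience=5, seed=5)
        model.fit(graph, y, splits)
        r = model.train_report_
        assert r.stopping_reason in ("early_stopping", "max_epochs")
        assert r.best_val_auroc == max(r.val_aurocs)


def test_isolated_encounter_forward_pass_is_finite():
    """An encounter with no providers and no transfers has all-zero
    adjacency rows; the forward pass stays total and finite."""
    enc = pd.DataFrame({"encounter_id": ["e1", "e2"], "patient_id": ["p1", "p2"],
                        "postop_los": [1.0, 2.0], "death_offset": [np.nan] * 2})
    asg = pd.DataFrame({"encounter_id": ["e1"], "provider_id": ["n1"],
                        "role": ["nurse"]})
    trf = pd.DataFrame(columns=["encounter_id", "unit_type",
                                "sequence_index", "duration"])
    feats = pd.DataFrame({"x": [0.5, -0.5]}, index=["e1", "e2"])
    graph = hg.build_heterograph(enc, asg, trf, feats)
    model = IEHGCNClassifier(hidden_dim=4, attn_dim=2, seed=0)
    model.initialize(graph)
    logits, attention = model.forward(graph)
    assert np.isfinite(logits.value).all()
    for layer in attention:
        for rels in layer.values():
            assert all(np.isfinite(v).all() for v in rels.values())
    probs = model.predict_proba(graph)
    assert np.isfinite(probs).all()


class TestTune:
    def test_single_trial_and_single_point_space(self):
        graph, y = _separable_toy()
        ids = graph.schema.ids[hg.ENC]
        splits = {"train": ids[:14], "validation": ids[14:]}
        space = {"lr": ("choice", [1e-2]), "hidden_dim": ("choice", [4])}
        best, log = tune(graph, y, splits, search_space=space, n_trials=1,
                         seed=0, fixed={"max_epochs": 3, "attn_dim": 2})
        assert best == {"lr": 1e-2, "hidden_dim": 4}
        assert len(log) == 1

    def test_reproducible_best_score(self):
        graph, y = _separable_toy()
        ids = graph.schema.ids[hg.ENC]
        splits = {"train": ids[:14], "validation": ids[14:]}
        space = {"lr": ("loguniform", 1e-3, 1e-1),
                 "hidden_dim": ("choice", [4, 8])}
        out = []
        for _ in range(2):
            best, log = tune(graph, y, splits, search_space=space, n_trials=4,
                             strategy="tpe", seed=1,
                             fixed={"max_epochs": 3, "attn_dim": 2})
            out.append((best, [t["score"] for t in log]))
        assert out[0] == out[1]
        with pytest.raises(ValueError):
            tune(graph, y, splits, n_trials=0)
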