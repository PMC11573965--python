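"""GAT model mechanics: attention normalization, gradients, training, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meshgat import GATConfig, GATModel, build_model, train_gat, evaluate_metrics, kfold_cv
from meshgat.gat import _directed_edges, stratified_split, ablation_grid, training_loss_curve
from meshgat.graph import SampleGraph


def random_graph(n, p, seed, labels=None):
    rng = np.random.default_rng(seed)
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                      if rng.random() < p]).reshape(-1, 2)
    if labels is None:
        labels = np.where(rng.random(n) < 0.5, "benign", "malignant")
    return SampleGraph(np.arange(1, n + 1), labels, edges,
                       np.ones(len(edges)), 0.0)


class TestAttention:
    @pytest.mark.parametrize("activation", ["elu", "relu", "tanh"])
    def test_alpha_sums_to_one_per_node_head_layer(self, activation):
        g = random_graph(25, 0.2, seed=1)
        cfg = GATConfig(activation=activation, hidden_units=8,
                        attention_layers=3, heads=4, seed=2)
        model = GATModel(cfg, feature_dim=6)
        X = np.random.default_rng(0).normal(size=(25, 6))
        ei = _directed_edges(g)
        for alpha in model.attention_coefficients(X, ei):
            assert np.all(alpha >= 0)
            sums = ei.reduce_by_recv(alpha)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_attends_to_itself(self):
        g = random_graph(6, 0.0, seed=0)  # no edges at all
        cfg = GATConfig(hidden_units=4, attention_layers=1, heads=2, seed=1)
        model = GATModel(cfg, feature_dim=3)
        X = np.random.default_rng(1).normal(size=(6, 3))
        ei = _directed_edges(g)
        alphas = model.attention_coefficients(X, ei)
        np.testing.assert_allclose(alphas[0], 1.0, atol=1e-12)

    def test_permutation_equivariance(self):
        n = 18
        g = random_graph(n, 0.3, seed=3)
        cfg = GATConfig(hidden_units=6, attention_layers=2, heads=3, seed=4)
        model = GATModel(cfg, feature_dim=5)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n, 5))
        ei = _directed_edges(g)
        out = model.forward(X, ei)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g2 = SampleGraph(g.node_ids, g.labels[perm],
                         inv[g.edges], g.weights, 0.0)
        out2 = model.forward(X[perm], _directed_edges(g2))
        np.testing.assert_allclose(out2, out[perm], atol=1e-6)


class TestModel:
    def test_forward_probabilities(self):
        g = random_graph(20, 0.25, seed=7)
        model = build_model(GATConfig(seed=0, hidden_units=8,
                                      attention_layers=2, heads=2), 10)
        probs = model.forward(
            np.random.default_rng(2).normal(size=(20, 10)), _directed_edges(g)
        )
        assert probs.shape == (20, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_same_initial_output(self):
        g = random_graph(15, 0.3, seed=8)
        X = np.random.default_rng(3).normal(size=(15, 4))
        ei = _directed_edges(g)
        a = build_model(GATConfig(seed=11, hidden_units=4, attention_layers=1), 4)
        b = build_model(GATConfig(seed=11, hidden_units=4, attention_layers=1), 4)
        np.testing.assert_array_equal(a.forward(X, ei), b.forward(X, ei))

    def test_gradients_match_finite_differences(self):
        g = random_graph(10, 0.35, seed=9)
        cfg = GATConfig(activation="elu", hidden_units=3, attention_layers=2,
                        heads=2, seed=5)
        model = GATModel(cfg, feature_dim=4)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 4))
        y = rng.integers(0, 2, 10)
        onehot = np.eye(2)[y]
        ei = _directed_edges(g)

        def loss():
            p = model.forward(X, ei)
            return -np.mean(np.log(np.clip(p[np.arange(10), y], 1e-12, None)))

        probs, cache = model.forward(X, ei, return_cache=True)
        grads = model.backward(cache, (probs - onehot) / 10, ei)
        eps = 1e-6
        for key in ("W_in", "a_src0", "a_dst1", "W_att1", "W_out"):
            P = model.params[key]
            flat = P.reshape(-1)
            for idx in np.random.default_rng(7).choice(flat.size, 5, replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GATConfig(activation="gelu").validate()
        with pytest.raises(ValueError):
            GATConfig(hidden_units=0).validate()
        with pytest.raises(ValueError):
            build_model(GATConfig(), feature_dim=0)

    def test_save_load_round_trip(self, tmp_path):
        g = random_graph(12, 0.3, seed=10)
        model = build_model(GATConfig(seed=1, hidden_units=4, attention_layers=1), 6)
        model.scaler_mean = np.arange(6.0)
        X = np.random.default_rng(4).normal(size=(12, 6))
        ei = _directed_edges(g)
        ref = model.forward(X, ei)
        model.save(tmp_path / "model")
        loaded = GATModel.load(tmp_path / "model")
        np.testing.assert_array_equal(loaded.forward(X, ei), ref)
        np.testing.assert_array_equal(loaded.scaler_mean, model.scaler_mean)


class TestMetrics:
    def test_fn_zero_pattern(self):
        rep = evaluate_metrics(tp=46, tn=105, fp=1, fn=0)
        assert rep.sensitivity == 100.0 and rep.fnr == 0.0 and rep.npv == 100.0
        assert rep.precision == pytest.approx(100 * 46 / 47, abs=1e-9)
        assert rep.precision == pytest.approx(97.87, abs=0.01)

    def test_perfect_prediction(self):
        rep = evaluate_metrics(tp=10, tn=20, fp=0, fn=0)
        assert rep.accuracy == 100.0 and rep.f1 == 100.0 and rep.mcc == 100.0

    def test_undefined_ratio_is_nan_not_zero(self):
        rep = evaluate_metrics(tp=0, tn=5, fp=0, fn=0)
        assert np.isnan(rep.sensitivity) and np.isnan(rep.precision)
        assert rep.mcc == 0.0 and rep.mcc_degenerate

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda t: sum(t) > 0))
    def test_complement_identities(self, counts):
        tp, tn, fp, fn = counts
        rep = evaluate_metrics(tp, tn, fp, fn)
        if not np.isnan(rep.sensitivity):
            assert rep.sensitivity + rep.fnr == pytest.approx(100.0, abs=1e-9)
        if not np.isnan(rep.specificity):
            assert rep.specificity + rep.fpr == pytest.approx(100.0, abs=1e-9)
        if not np.isnan(rep.precision):
            assert rep.precision + rep.fdr == pytest.approx(100.0, abs=1e-9)
        # every metric recomputable from the stored confusion matrix
        again = evaluate_metrics(rep.tp, rep.tn, rep.fp, rep.fn)
        assert again.as_dict() == rep.as_dict()


class TestTraining:
    def test_stratified_split_partitions(self):
        labels = np.array(["benign"] * 40 + ["malignant"] * 20)
        tr, va, te = stratified_split(labels, 0.7, 0.15, seed=0)
        all_idx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(all_idx, np.arange(60))
        assert len(set(tr) & set(va)) == 0 and len(set(va) & set(te)) == 0

    def test_loss_decreases(self, small_table, small_graph):
        cfg = GATConfig(hidden_units=8, attention_layers=1, heads=2,
                        learning_rate=1e-3, seed=0)
        losses = training_loss_curve(small_table, small_graph, cfg, n_epochs=50)
        assert losses[-1] < losses[0]

    def test_separable_classes_learned(self, small_table, small_graph):
        cfg = GATConfig(attention_layers=2, heads=4, learning_rate=1e-3,
                        epochs=60, seed=3)
        _, rep = train_gat(small_table, small_graph, cfg)
        assert rep.test_accuracy >= 85.0
        assert rep.train_accuracy >= 85.0

    def test_cv_partition_and_determinism(self, small_table, small_graph):
        cfg = GATConfig(attention_layers=1, heads=2, hidden_units=8,
                        learning_rate=1e-3, epochs=20, seed=1)
        cv1 = kfold_cv(small_table, small_graph, cfg, k=3, seed=5)
        cv2 = kfold_cv(small_table, small_graph, cfg, k=3, seed=5)
        np.testing.assert_array_equal(cv1["fold_assignment"], cv2["fold_assignment"])
        assert sorted(np.unique(cv1["fold_assignment"])) == [0, 1, 2]
        assert cv1["fold_accuracies"] == cv2["fold_accuracies"]

    def test_cv_k_exceeding_class_size_rejected(self, small_table, small_graph):
        with pytest.raises(ValueError, match="class size"):
            kfold_cv(small_table, small_graph, GATConfig(), k=50)


class TestAblation:
    def test_single_axis_row_count(self, small_table, small_graph):
        cfg = GATConfig(attention_layers=1, heads=2, hidden_units=4,
                        learning_rate=1e-3, epochs=5, seed=0)
        rows, winner = ablation_grid(
            small_table, small_graph, {"activation": ["elu", "relu", "tanh"]},
            base_config=cfg, seed=0,
        )
        assert len(rows) == 3
        assert winner.activation in ("elu", "relu", "tanh")

    def test_full_seven_stage_grid_has_19_rows(self, small_table, small_graph):
        from meshgat.gat import ABLATION_AXES_DEFAULT

        cfg = GATConfig(attention_layers=1, heads=2, hidden_units=4,
                        learning_rate=1e-3, epochs=2, seed=0)
        rows, _ = ablation_grid(small_table, small_graph,
                                ABLATION_AXES_DEFAULT, base_config=cfg, seed=0)
        assert len(rows) == 19
        assert set(rows["stage"]) == set(ABLATION_AXES_DEFAULT)
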