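import numpy as np
import pytest

from toopanel import (
    MLPConfig,
    TrainConfig,
    fit_ktsp_multiclass,
    fit_logistic_ovr,
    fit_mlp,
    load_model,
    predict_ktsp,
    predict_mlp,
    predict_proba,
    save_model,
    score_tsp_pairs,
)
from toopanel.classifiers import LinearOvRModel


def _separable_toy(rng, n=40):
    X = rng.normal(0, 0.3, size=(n, 2))
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X[: n // 2, 0] += 3.0
    X[n // 2 :, 1] += 3.0
    return X, y


def _multiclass_blobs(rng, n_classes=4, per_class=30, n_feat=12, shift=3.0):
    X = rng.normal(0, 1.0, size=(n_classes * per_class, n_feat))
    y = []
    for c in range(n_classes):
        rows = slice(c * per_class, (c + 1) * per_class)
        X[rows, c * 2 : c * 2 + 2] += shift
        y += [f"cls{c}"] * per_class
    return X, np.array(y)


FEATS = [f"f{i}" for i in range(12)]


class TestLogisticOvR:
    def test_separable_training_accuracy(self, rng):
        X, y = _separable_toy(rng)
        model = fit_logistic_ovr(X, y, ["f0", "f1"])
        pred = predict_proba(model, X, ["f0", "f1"])
        assert pred.predicted_labels == list(y)

    def test_deterministic_under_seed(self, rng):
        X, y = _separable_toy(rng)
        cfg = TrainConfig(seed=7)
        m1 = fit_logistic_ovr(X, y, ["f0", "f1"], cfg)
        m2 = fit_logistic_ovr(X, y, ["f0", "f1"], cfg)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.intercepts, m2.intercepts)

    def test_heldout_accuracy_on_strong_markers(self, rng):
        X, y = _multiclass_blobs(rng, per_class=40)
        tr = np.arange(len(y)) % 2 == 0
        model = fit_logistic_ovr(X[tr], y[tr], FEATS)
        pred = predict_proba(model, X[~tr], FEATS)
        acc = np.mean(np.array(pred.predicted_labels) == y[~tr])
        assert acc >= 0.95

    def test_zero_variance_feature_dropped(self, rng):
        X, y = _separable_toy(rng)
        X = np.column_stack([X, np.full(len(y), 5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_logistic_ovr(X, y, ["f0", "f1", "const"])
        assert model.dropped_features == ["const"]
        assert model.feature_ids == ["f0", "f1"]

    def test_feature_permutation_invariance(self, rng):
        X, y = _separable_toy(rng)
        model = fit_logistic_ovr(X, y, ["f0", "f1"])
        fwd = predict_proba(model, X, ["f0", "f1"])
        rev = predict_proba(model, X[:, ::-1], ["f1", "f0"])
        np.testing.assert_allclose(fwd.class_scores, rev.class_scores)

    def test_missing_feature_raises(self, rng):
        X, y = _separable_toy(rng)
        model = fit_logistic_ovr(X, y, ["f0", "f1"])
        with pytest.raises(ValueError, match="missing"):
            predict_proba(model, X[:, :1], ["f0"])


class TestPredictProba:
    def _manual_model(self, weights, intercepts, labels):
        f = [f"f{i}" for i in range(weights.shape[1])]
        return LinearOvRModel(
            class_labels=labels,
            feature_ids=f,
            weights=weights,
            intercepts=intercepts,
            feature_means=np.zeros(weights.shape[1]),
            feature_sds=np.ones(weights.shape[1]),
        )

    def test_zero_weights_give_uniform_scores(self):
        model = self._manual_model(np.zeros((3, 2)), np.zeros(3), ["a", "b", "c"])
        pred = predict_proba(model, np.array([[1.0, -2.0]]), ["f0", "f1"])
        np.testing.assert_allclose(pred.class_scores, [[1 / 3] * 3])
        assert pred.predicted_labels == ["a"]  # lexicographic tie-break

    def test_hand_computed_sigmoid_normalization(self):
        w = np.array([[1.0, -1.0], [0.5, 2.0]])
        b = np.array([0.1, -0.2])
        model = self._manual_model(w, b, ["a", "b"])
        x = np.array([[0.4, 0.7]])
        raw = w @ x[0] + b
        sig = 1 / (1 + np.exp(-raw))
        expected = sig / sig.sum()
        pred = predict_proba(model, x, ["f0", "f1"])
        np.testing.assert_allclose(pred.class_scores[0], expected, atol=1e-12)

    def test_normalization_never_changes_argmax(self, rng):
        for _ in range(1000):
            c, f = rng.integers(2, 6), rng.integers(1, 5)
            w = rng.normal(size=(c, f))
            b = rng.normal(size=c)
            x = rng.normal(size=(1, f))
            model = self._manual_model(w, b, [f"c{i}" for i in range(c)])
            pred = predict_proba(model, x, [f"f{i}" for i in range(f)])
            raw = w @ x[0] + b
            sig = 1 / (1 + np.exp(-raw))
            assert pred.predicted_labels[0] == f"c{np.argmax(sig)}"

    def test_rows_sum_to_one(self, rng):
        model = self._manual_model(rng.normal(size=(4, 3)), rng.normal(size=4),
                                   ["a", "b", "c", "d"])
        pred = predict_proba(model, rng.normal(size=(20, 3)), ["f0", "f1", "f2"])
        np.testing.assert_allclose(pred.class_scores.sum(axis=1), 1.0, atol=1e-9)


class TestMLP:
    def test_softmax_rows_and_architecture(self, rng):
        X, y = _multiclass_blobs(rng, n_classes=3, per_class=20)
        cfg = MLPConfig(epochs=150, seed=0)
        model = fit_mlp(X, y, FEATS, cfg)
        assert model.w_hidden.shape == (12, 128)
        assert model.w_out.shape == (128, 3)
        pred = predict_mlp(model, X, FEATS)
        np.testing.assert_allclose(pred.class_scores.sum(axis=1), 1.0, atol=1e-9)

    def test_loss_decreases_on_separable_toy(self, rng):
        X, y = _multiclass_blobs(rng, n_classes=3, per_class=20)
        model = fit_mlp(X, y, FEATS, MLPConfig(epochs=120, batch_size=0, seed=1))
        curve = model.loss_curve[:100]
        assert len(curve) >= 20
        diffs = np.diff(curve)
        assert (diffs <= 1e-3).all()
        assert curve[-1] < curve[0]

    def test_heldout_accuracy_easy_multiclass(self, rng):
        X, y = _multiclass_blobs(rng, n_classes=4, per_class=40)
        tr = np.arange(len(y)) % 2 == 0
        model = fit_mlp(X[tr], y[tr], FEATS, MLPConfig(epochs=400, seed=2))
        pred = predict_mlp(model, X[~tr], FEATS)
        assert np.mean(np.array(pred.predicted_labels) == y[~tr]) >= 0.90


def _brute_force_tsp(X, y, feats):
    labels = sorted(set(y))
    out = {}
    for i in range(X.shape[1]):
        for j in range(X.shape[1]):
            if i == j:
                continue
            ps = []
            for lab in labels:
                rows = [s for s in range(len(y)) if y[s] == lab]
                ps.append(sum(X[s, i] < X[s, j] for s in rows) / len(rows))
            out[(feats[i], feats[j])] = abs(ps[0] - ps[1])
    return out


class TestTSP:
    def test_direct_count_arithmetic(self):
        # V_0 < V_1 in 10/10 class-1 samples, 2/10 class-2 samples: dP = 0.8
        X = np.zeros((20, 2))
        X[:10, 1] = 1.0  # class 1: V0 < V1 always
        X[10:, 1] = -1.0
        X[10:12, 1] = 1.0  # 2 of 10 class-2 samples
        y = np.array(["c1"] * 10 + ["c2"] * 10)
        pairs = score_tsp_pairs(X, y, ["gA", "gB"])
        top = pairs[0]
        assert (top.gene_low, top.gene_high) == ("gA", "gB")
        assert top.delta_p == pytest.approx(0.8)

    def test_identical_distributions_score_zero(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (12, 1))
        y = np.array(["a"] * 6 + ["b"] * 6)
        pairs = score_tsp_pairs(X, y, ["g0", "g1", "g2"])
        assert all(p.delta_p == 0.0 for p in pairs)

    def test_matches_brute_force_enumeration(self, rng):
        feats = [f"g{i}" for i in range(15)]
        X = rng.normal(size=(12, 15))
        y = np.array(["a"] * 6 + ["b"] * 6)
        got = {(p.gene_low, p.gene_high): p.delta_p for p in score_tsp_pairs(X, y, feats)}
        expected = _brute_force_tsp(X, y, feats)
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-12)

    def test_rank_invariance_under_monotone_transforms(self, rng):
        feats = [f"g{i}" for i in range(8)]
        X = rng.normal(size=(16, 8))
        y = np.array(["a"] * 8 + ["b"] * 8)
        model = fit_ktsp_multiclass(X, y, feats, pairs_per_classifier=3)
        base = predict_ktsp(model, X, feats)
        # strictly monotone per-sample maps: scale/offset + cubing
        Xt = X.copy()
        for s in range(16):
            a = rng.uniform(0.5, 3.0)
            b = rng.normal()
            Xt[s] = a * X[s] ** 3 + b
        trans = predict_ktsp(model, Xt, feats)
        assert base.predicted_labels == trans.predicted_labels
        np.testing.assert_array_equal(base.class_scores, trans.class_scores)

    def test_perfect_pair_selected_first(self, rng):
        X = rng.normal(0, 0.1, size=(24, 5))
        X[:12, 0] = X[:12, 1] - 1.0   # class a: g0 < g1 always
        X[12:, 0] = X[12:, 1] + 1.0   # class b: never
        y = np.array(["a"] * 12 + ["b"] * 12)
        feats = [f"g{i}" for i in range(5)]
        model = fit_ktsp_multiclass(X, y, feats, pairs_per_classifier=1)
        pair = model.classifiers[("a", "b")][0]
        assert {pair.gene_low, pair.gene_high} == {"g0", "g1"}
        assert pair.delta_p == pytest.approx(1.0)
        pred = predict_ktsp(model, X, feats)
        assert pred.predicted_labels == list(y)

    def test_gene_disjoint_greedy_selection(self, rng):
        feats = [f"g{i}" for i in range(10)]
        X = rng.normal(size=(20, 10))
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_ktsp_multiclass(X, y, feats, pairs_per_classifier=4)
        genes = [g for p in model.classifiers[("a", "b")] for g in (p.gene_low, p.gene_high)]
        assert len(genes) == len(set(genes))

    def test_multiclass_vote_oracle(self, rng):
        X, y = _multiclass_blobs(rng, n_classes=4, per_class=10, shift=2.0)
        model = fit_ktsp_multiclass(X, y, FEATS, pairs_per_classifier=3)
        pred = predict_ktsp(model, X, FEATS)
        # independent re-evaluation of every vote on every sample
        labels = model.class_labels
        for s in range(X.shape[0]):
            votes = {lab: 0 for lab in labels}
            for (a, b), pairs in model.classifiers.items():
                wins_a = 0
                for p in pairs:
                    i = FEATS.index(p.gene_low)
                    j = FEATS.index(p.gene_high)
                    ind = X[s, i] < X[s, j]
                    if ind == (p.p_class1 > p.p_class2):
                        wins_a += 1
                if wins_a * 2 > len(pairs):
                    votes[a] += 1
                elif wins_a * 2 < len(pairs):
                    votes[b] += 1
                else:
                    top = pairs[0]
                    i = FEATS.index(top.gene_low)
                    j = FEATS.index(top.gene_high)
                    ind = X[s, i] < X[s, j]
                    votes[a if ind == (top.p_class1 > top.p_class2) else b] += 1
            np.testing.assert_array_equal(
                pred.class_scores[s], [votes[lab] for lab in labels]
            )

    def test_pairs_per_classifier_validated(self, rng):
        X, y = _separable_toy(rng)
        with pytest.raises(ValueError):
            fit_ktsp_multiclass(X, y, ["f0", "f1"], pairs_per_classifier=0)


class TestSerialization:
    def test_linear_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = _multiclass_blobs(rng)
        model = fit_logistic_ovr(X, y, FEATS)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        p1 = predict_proba(model, X, FEATS)
        p2 = predict_proba(back, X, FEATS)
        np.testing.assert_array_equal(p1.class_scores, p2.class_scores)
        assert p1.predicted_labels == p2.predicted_labels

    def test_mlp_round_trip(self, rng, tmp_path):
        X, y = _multiclass_blobs(rng, n_classes=3, per_class=15)
        model = fit_mlp(X, y, FEATS, MLPConfig(epochs=50, seed=3))
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(
            predict_mlp(model, X, FEATS).class_scores,
            predict_mlp(back, X, FEATS).class_scores,
        )

    def test_ktsp_round_trip(self, rng, tmp_path):
        X, y = _multiclass_blobs(rng, n_classes=3, per_class=10)
        model = fit_ktsp_multiclass(X, y, FEATS, pairs_per_classifier=2)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(
            predict_ktsp(model, X, FEATS).class_scores,
            predict_ktsp(back, X, FEATS).class_scores,
        )
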