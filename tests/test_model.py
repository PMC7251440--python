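import numpy as np
import pytest

import plnnfc as pf
from plnnfc.model import init_model, forward_logits


class TestInit:
    def test_deterministic_under_seed(self):
        cfg = pf.ModelConfig(layer_widths=[10, 4, 3, 1], seed=42)
        m1, m2 = init_model(cfg), init_model(cfg)
        for a, b in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)

    def test_weight_shapes_chain(self):
        m = init_model(pf.ModelConfig(layer_widths=[10, 4, 3, 1]))
        assert [w.shape for w in m.weights] == [(4, 10), (3, 4), (1, 3)]
        assert m.bn[0] is not None and m.bn[1] is not None and m.bn[2] is None

    def test_bn_initialized_as_identity(self):
        m = init_model(pf.ModelConfig(layer_widths=[6, 3, 1]))
        bn = m.bn[0]
        assert np.all(bn.gamma == 1) and np.all(bn.beta == 0)
        assert np.all(bn.running_mean == 0) and np.all(bn.running_var == 1)

    def test_relu_slope_zero_warns_but_accepted(self):
        with pytest.warns(UserWarning, match="ReLU"):
            pf.ModelConfig(layer_widths=[4, 2, 1], leaky_slope=0.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            pf.ModelConfig(layer_widths=[4, 2, 3])  # output width != 1
        with pytest.raises(ValueError):
            pf.ModelConfig(layer_widths=[4, 2, 1], dropout_rate=1.0)


class TestForward:
    def test_zero_weights_give_half(self):
        m = init_model(pf.ModelConfig(layer_widths=[5, 3, 1]))
        for W in m.weights:
            W[:] = 0.0
        assert pf.forward(m, np.ones(5))[0] == pytest.approx(0.5)

    def test_matches_handrolled_layer_by_layer(self, small_model, rng):
        """Independent forward-pass oracle written from the block equations."""
        m = small_model
        X = rng.normal(size=(20, 10))
        alpha = m.config.leaky_slope
        eps = m.config.bn_epsilon
        expected = []
        for x in X:
            a = x
            for l in range(m.n_layers):
                z = m.weights[l] @ a + m.biases[l]
                if l < m.n_layers - 1:
                    bn = m.bn[l]
                    z = bn.gamma * (z - bn.running_mean) / np.sqrt(bn.running_var + eps) + bn.beta
                    a = np.where(z >= 0, z, alpha * z)
                else:
                    a = z
            expected.append(a[0])
        assert np.allclose(forward_logits(m, X), expected, atol=1e-12)

    def test_bn_gamma_scaling(self, small_model, rng):
        """Scaling gamma by c>0 scales that neuron's normalized pre-activation."""
        import copy

        m = copy.deepcopy(small_model)
        x = rng.normal(size=10)
        eps = m.config.bn_epsilon
        bn = m.bn[0]
        z = m.weights[0] @ x + m.biases[0]
        pre1 = bn.gamma * (z - bn.running_mean) / np.sqrt(bn.running_var + eps) + bn.beta
        bn.gamma = bn.gamma * 3.0
        bn.beta = bn.beta * 3.0
        pre2 = bn.gamma * (z - bn.running_mean) / np.sqrt(bn.running_var + eps) + bn.beta
        assert np.allclose(pre2, 3.0 * pre1)

    def test_nonfinite_input_rejected(self, small_model):
        x = np.zeros(10)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pf.forward(small_model, x)

    def test_dimension_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="features"):
            pf.forward(small_model, np.zeros(11))


class TestTrain:
    def test_separable_data_learned(self, rng):
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        cfg = pf.ModelConfig(layer_widths=[2, 8, 4, 1], dropout_rate=0.0,
                             epochs=100, learning_rate=5e-3, seed=1)
        m = pf.train(X, y, cfg)
        assert pf.evaluate(pf.forward(m, X), y).accuracy >= 0.95

    def test_loss_decreases(self, rng):
        X = rng.normal(size=(120, 4))
        y = (X[:, 0] > 0).astype(int)
        cfg = pf.ModelConfig(layer_widths=[4, 6, 1], dropout_rate=0.0,
                             epochs=30, learning_rate=1e-3, seed=2)
        m = pf.train(X, y, cfg)
        assert m.loss_history[-1] <= m.loss_history[0]

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        cfg = pf.ModelConfig(layer_widths=[3, 2, 1])
        with pytest.raises(ValueError, match="both classes"):
            pf.train(X, np.ones(20), cfg)

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        cfg = pf.ModelConfig(layer_widths=[3, 4, 1], epochs=10, seed=9, dropout_rate=0.3)
        m1, m2 = pf.train(X, y, cfg), pf.train(X, y, cfg)
        for a, b in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)

    def test_label_permutation_yields_chance_cv(self, tiny_cohort, rng):
        """Null-model check: permuted labels give held-out accuracy near 0.5."""
        _, ds = tiny_cohort
        y_perm = rng.permutation(ds.y)
        if y_perm.sum() == 0 or y_perm.sum() == y_perm.size:
            pytest.skip("degenerate permutation")
        cfg = pf.ModelConfig(layer_widths=[ds.d, 8, 4, 1], dropout_rate=0.1,
                             epochs=40, learning_rate=2e-3, seed=3)
        res = pf.cross_validate(ds.X, y_perm, cfg, k=5, seed=3)
        acc = res.summary()["accuracy"][0]
        assert abs(acc - 0.5) <= 0.15


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # TP=5, FN=5, TN=7, FP=3 constructed explicitly
        y = np.array([1] * 10 + [0] * 10)
        p = np.array([0.9] * 5 + [0.1] * 5 + [0.1] * 7 + [0.9] * 3)
        r = pf.evaluate(p, y)
        assert (r.tp, r.fn, r.tn, r.fp) == (5, 5, 7, 3)
        assert r.sensitivity == pytest.approx(0.5)
        assert r.specificity == pytest.approx(0.7)
        assert r.accuracy == pytest.approx(0.6)
        assert r.f1 == pytest.approx(10 / 18)

    def test_metric_identities(self, rng):
        p = rng.random(80)
        y = rng.integers(0, 2, 80)
        r = pf.evaluate(p, y)
        assert r.sensitivity * (r.tp + r.fn) == pytest.approx(r.tp)
        prev = (r.tp + r.fn) / 80
        assert r.accuracy == pytest.approx(prev * r.sensitivity + (1 - prev) * r.specificity)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        r = pf.evaluate(np.array([0.1, 0.9, 0.8, 0.2]), y)
        assert r.accuracy == r.sensitivity == r.specificity == r.f1 == 1.0
        assert r.auc == 1.0

    def test_constant_probs_auc_half(self):
        r = pf.evaluate(np.full(10, 0.5), np.array([0, 1] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_auc_matches_mann_whitney(self, rng):
        """Rank-statistic cross-check of the AUC."""
        from scipy.stats import mannwhitneyu

        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        u = mannwhitneyu(p[y == 1], p[y == 0]).statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert pf.evaluate(p, y).auc == pytest.approx(expected)

    def test_one_class_auc_missing(self):
        r = pf.evaluate(np.array([0.2, 0.8]), np.array([1, 1]))
        assert r.auc is None
        assert r.sensitivity == 0.5


class TestCrossValidate:
    def test_fold_sizes_partition(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 403 + [0] * 468)
        sizes = sorted(len(te) for _, te in
                       StratifiedKFold(5, shuffle=True, random_state=0).split(np.zeros((871, 1)), y))
        assert sizes == [174, 174, 174, 174, 175]

    def test_same_seed_same_folds(self, tiny_cohort):
        _, ds = tiny_cohort
        cfg = pf.ModelConfig(layer_widths=[ds.d, 4, 1], epochs=3, seed=1, dropout_rate=0.0)
        r1 = pf.cross_validate(ds.X, ds.y, cfg, k=3, seed=21)
        r2 = pf.cross_validate(ds.X, ds.y, cfg, k=3, seed=21)
        for a, b in zip(r1.test_indices, r2.test_indices):
            assert np.array_equal(a, b)
        assert np.array_equal(r1.oof_probs, r2.oof_probs)

    def test_n_below_k_rejected(self, rng):
        cfg = pf.ModelConfig(layer_widths=[2, 2, 1])
        with pytest.raises(ValueError, match="< k"):
            pf.cross_validate(rng.normal(size=(3, 2)), np.array([0, 1, 1]), cfg, k=5)

    def test_separable_cohort_high_accuracy(self, tiny_cohort):
        _, ds = tiny_cohort
        cfg = pf.ModelConfig(layer_widths=[ds.d, 8, 4, 1], dropout_rate=0.1,
                             epochs=60, learning_rate=2e-3, seed=4)
        res = pf.cross_validate(ds.X, ds.y, cfg, k=5, seed=4)
        assert res.summary()["accuracy"][0] >= 0.9
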