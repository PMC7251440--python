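import copy

import numpy as np
import pytest
from scipy.special import expit, logit  # noqa: F401  (expit used below)

import plnnfc as pf
from plnnfc.linearize import activation_pattern, bn_linear_form, local_linear
from plnnfc.model import forward_logits, init_model


class TestBnLinearForm:
    def test_identity_bn(self):
        m = init_model(pf.ModelConfig(layer_widths=[4, 3, 1], bn_epsilon=1e-5))
        m.bn[0].running_var[:] = 1.0 - 1e-5
        f = bn_linear_form(m)
        assert np.allclose(f.slopes[0], 1.0)
        assert np.allclose(f.intercepts[0], 0.0)

    def test_plugged_values(self):
        # gamma=2, beta=3, mean=1, var=4-eps -> slope 1, intercept 2
        m = init_model(pf.ModelConfig(layer_widths=[4, 1, 1], bn_epsilon=1e-5))
        bn = m.bn[0]
        bn.gamma[:] = 2.0
        bn.beta[:] = 3.0
        bn.running_mean[:] = 1.0
        bn.running_var[:] = 4.0 - 1e-5
        f = bn_linear_form(m)
        assert f.slopes[0][0] == pytest.approx(1.0)
        assert f.intercepts[0][0] == pytest.approx(2.0)

    def test_zero_variance_guarded_by_epsilon(self):
        m = init_model(pf.ModelConfig(layer_widths=[4, 1, 1], bn_epsilon=1e-5))
        m.bn[0].running_var[:] = 0.0
        f = bn_linear_form(m)
        assert f.slopes[0][0] == pytest.approx(1.0 / np.sqrt(1e-5))
        assert np.isfinite(f.slopes[0][0])


class TestActivationPattern:
    def test_all_positive_network(self):
        m = init_model(pf.ModelConfig(layer_widths=[3, 2, 2, 1]))
        for W, b in zip(m.weights, m.biases):
            W[:] = np.abs(W) + 0.1
            b[:] = 0.5
        pat = activation_pattern(m, np.ones(3))
        assert all(np.all(s == 1) for s in pat.states)

    def test_zero_preactivation_takes_slope_one_branch(self):
        m = init_model(pf.ModelConfig(layer_widths=[2, 1, 1], use_bn=False))
        m.weights[0][:] = 0.0
        m.biases[0][:] = 0.0
        pat = activation_pattern(m, np.array([1.0, -1.0]))
        assert pat.states[0][0] == 1

    def test_shared_pattern_shared_surrogate(self, small_model, rng):
        """Two instances in the same linear region get identical (w_hat, b_hat)."""
        m = small_model
        x = rng.normal(size=10)
        found = 0
        for _ in range(200):
            x2 = x + rng.normal(scale=1e-4, size=10)
            l1, l2 = local_linear(m, x), local_linear(m, x2)
            if l1.pattern == l2.pattern:
                assert np.array_equal(l1.w_hat, l2.w_hat)
                assert l1.b_hat == l2.b_hat
                found += 1
        assert found > 0


class TestExactness:
    """The central oracle: the folded linear form equals the network logit."""

    def test_untrained_model(self, small_model, rng):
        X = rng.normal(size=(100, 10))
        assert pf.verify_faithfulness(small_model, X) < 1e-7

    def test_trained_model(self, trained_tiny, tiny_cohort, rng):
        _, ds = tiny_cohort
        assert pf.verify_faithfulness(trained_tiny, ds.X) < 1e-7

    def test_bn_free_model(self, rng):
        cfg = pf.ModelConfig(layer_widths=[8, 5, 3, 1], use_bn=False, seed=2)
        m = init_model(cfg)
        X = rng.normal(size=(100, 8))
        assert pf.verify_faithfulness(m, X) < 1e-7

    def test_probability_agrees_with_surrogate(self, trained_tiny, tiny_cohort):
        _, ds = tiny_cohort
        for i in range(0, ds.n, 7):
            llm = local_linear(trained_tiny, ds.X[i])
            p_net = pf.forward(trained_tiny, ds.X[i])[0]
            assert expit(llm.w_hat @ ds.X[i] + llm.b_hat) == pytest.approx(p_net, abs=1e-7)

    def test_standardized_model_weights_in_raw_units(self, tiny_cohort):
        """With per-column z-scoring on, the folded weights still act on raw x."""
        _, ds = tiny_cohort
        cfg = pf.ModelConfig(layer_widths=[ds.d, 6, 1], epochs=10, standardize=True,
                             dropout_rate=0.0, seed=8)
        m = pf.train(ds.X, ds.y, cfg)
        assert pf.verify_faithfulness(m, ds.X) < 1e-7


class TestStructure:
    def test_single_layer_degenerate(self):
        """No hidden blocks: the surrogate IS the dense layer."""
        m = init_model(pf.ModelConfig(layer_widths=[5, 1], seed=3))
        llm = local_linear(m, np.zeros(5))
        assert np.array_equal(llm.w_hat, m.weights[0][0])
        assert llm.b_hat == m.biases[0][0]

    def test_all_negative_pattern_scales_by_alpha_squared(self, rng):
        """If both hidden layers sit on the negative branch, w_hat equals the
        all-positive-branch w_hat scaled by alpha^2 (two folded slopes)."""
        cfg = pf.ModelConfig(layer_widths=[6, 4, 3, 1], use_bn=False, seed=4,
                             leaky_slope=0.1)
        m = init_model(cfg)
        x = rng.normal(size=6)
        llm = local_linear(m, x)
        pos = copy.deepcopy(llm.pattern)
        for s in pos.states:
            s[:] = 1
        neg = copy.deepcopy(llm.pattern)
        for s in neg.states:
            s[:] = 0

        def whab(pattern):
            alpha = cfg.leaky_slope
            A, c = m.weights[0], m.biases[0].copy()
            for l in range(2):
                r = np.where(pattern.states[l] == 1, 1.0, alpha)
                A = r[:, None] * A
                c = r * c
                A = m.weights[l + 1] @ A
                c = m.weights[l + 1] @ c + m.biases[l + 1]
            return A[0]

        assert np.allclose(whab(neg), cfg.leaky_slope**2 * whab(pos))

    def test_gradient_agreement(self, trained_tiny, tiny_cohort):
        """Away from region boundaries w_hat is the logit's gradient."""
        _, ds = tiny_cohort
        x = ds.X[0]
        llm = local_linear(trained_tiny, x)
        h = 1e-6
        for j in range(0, ds.d, 9):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (forward_logits(trained_tiny, xp)[0] - forward_logits(trained_tiny, xm)[0]) / (2 * h)
            assert fd == pytest.approx(llm.w_hat[j], rel=1e-3, abs=1e-8)

    def test_scale_covariance_one_hidden(self, rng):
        """Doubling W1 (BN stats fixed) doubles the first-layer contribution."""
        cfg = pf.ModelConfig(layer_widths=[4, 3, 1], use_bn=False, seed=6)
        m = init_model(cfg)
        x = rng.normal(size=4) * 0.01  # small x: doubling W1 keeps the pattern
        l1 = local_linear(m, x)
        m2 = copy.deepcopy(m)
        m2.weights[0] *= 2.0
        l2 = local_linear(m2, 0.5 * x)  # same pre-activations -> same pattern
        assert l2.pattern == l1.pattern
        assert np.allclose(l2.w_hat, 2.0 * l1.w_hat)


class TestExport:
    def test_sorted_by_magnitude_with_index_ties(self):
        llm = pf.LocalLinearModel(
            w_hat=np.array([0.5, -0.5, 2.0, -3.0, 0.1, 0.0]),
            b_hat=0.0, pattern=pf.linearize.ActivationPattern([]))
        imap = pf.EdgeIndexMap(4)
        tbl = pf.export_instance_weights(llm, imap)
        assert tbl["k"].tolist() == [3, 2, 0, 1, 4, 5]  # |w| desc, index asc on ties
        assert tbl["weight"].sum() == pytest.approx(llm.w_hat.sum())

    def test_top_n_clamped_and_zero(self):
        llm = pf.LocalLinearModel(np.arange(6.0), 0.0, pf.linearize.ActivationPattern([]))
        imap = pf.EdgeIndexMap(4)
        assert len(pf.export_instance_weights(llm, imap, top_n=100)) == 6
        assert len(pf.export_instance_weights(llm, imap, top_n=0)) == 0

    def test_roi_pairs_match_map(self):
        llm = pf.LocalLinearModel(np.array([1.0, 0.0, 0.0]), 0.0,
                                  pf.linearize.ActivationPattern([]))
        tbl = pf.export_instance_weights(llm, pf.EdgeIndexMap(3), top_n=1)
        assert (tbl.loc[0, "roi_i"], tbl.loc[0, "roi_j"]) == (0, 1)
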