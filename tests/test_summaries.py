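import numpy as np
import pytest

from pairsel import (classification_metrics, combined_posterior_summary,
                     dimensionality_percentiles, inclusion_probabilities,
                     marginal_mean_coefficients, predict)
from pairsel.io import PairedDesign
from pairsel.model import (Chain, ChainSample, ChainSettings,
                           CoefficientState, ModelConfiguration, PriorSpec)


def _chain(samples, p=8):
    recs = [ChainSample(10 * (i + 1), cfg,
                        CoefficientState(b0, np.asarray(a, float),
                                         np.asarray(b, float), 1, 1))
            for i, (cfg, b0, a, b) in enumerate(samples)]
    return Chain(recs, ChainSettings(1000, 0, 10, 0), PriorSpec(kmax=p), p=p)


class TestInclusionProbabilities:
    def test_counting_example(self):
        samples = [
            (ModelConfiguration((7,), ()), 0.0, [1.0], [1.0]),
            (ModelConfiguration((7,), ()), 0.0, [1.0], [1.0]),
            (ModelConfiguration((), (7,)), 0.0, [1.0], []),
            (ModelConfiguration((), ()), 0.0, [], []),
        ]
        inc = inclusion_probabilities(_chain(samples))
        assert inc.p_any[7] == 0.75
        assert inc.p_singleton[7] == 0.25
        assert inc.p_couple[7] == 0.5

    def test_never_selected_is_zero_and_log_ratio_nan(self):
        inc = inclusion_probabilities(_chain(
            [(ModelConfiguration((0,), ()), 0.0, [1.0], [1.0])]))
        assert inc.p_any[3] == inc.p_singleton[3] == inc.p_couple[3] == 0
        assert np.isnan(inc.log_ratio[3])
        assert np.isnan(inc.log_ratio[0])  # singleton prob 0 for pair 0

    def test_equal_probabilities_give_zero_log_ratio(self):
        inc = inclusion_probabilities(_chain([
            (ModelConfiguration((2,), ()), 0.0, [1.0], [1.0]),
            (ModelConfiguration((), (2,)), 0.0, [1.0], []),
        ]))
        assert inc.log_ratio[2] == pytest.approx(0.0)

    def test_additivity_on_fitted_chain(self, short_chain):
        inc = inclusion_probabilities(short_chain)
        np.testing.assert_array_equal(inc.p_any,
                                      inc.p_singleton + inc.p_couple)


class TestMarginalMeans:
    def test_half_inclusion_halves_the_mean(self):
        samples = [
            (ModelConfiguration((), (3,)), 0.0, [2.0], []),
            (ModelConfiguration((), ()), 0.0, [], []),
        ]
        mm = marginal_mean_coefficients(_chain(samples))
        assert mm.mean_a[3] == 1.0
        assert mm.mean_a[0] == 0.0

    def test_matches_brute_force_loop(self, short_chain):
        mm = marginal_mean_coefficients(short_chain)
        p = short_chain.p
        acc_a = np.zeros(p)
        acc_b = np.zeros(p)
        for s in short_chain.samples:
            for pos, j in enumerate(s.config.included):
                acc_a[j] += s.coeffs.a[pos]
            for pos, j in enumerate(s.config.couples):
                acc_b[j] += s.coeffs.b[pos]
        M = len(short_chain)
        np.testing.assert_allclose(mm.mean_a, acc_a / M, atol=1e-12)
        np.testing.assert_allclose(mm.mean_b, acc_b / M, atol=1e-12)


class TestCombinedPosteriorSummary:
    def test_single_intensity_model_gives_one(self):
        ps = combined_posterior_summary(_chain(
            [(ModelConfiguration((), (2,)), 0.0, [5.0], [])]))
        assert ps.ps_a[2] == pytest.approx(1.0)

    def test_two_intensity_magnitudes(self):
        ps = combined_posterior_summary(_chain(
            [(ModelConfiguration((), (0, 1)), 0.0, [3.0, -1.0], [])]))
        assert ps.ps_a[0] == pytest.approx(0.375)
        assert ps.ps_a[1] == pytest.approx(0.125)

    def test_absent_component_is_zero(self):
        ps = combined_posterior_summary(_chain(
            [(ModelConfiguration((), (0,)), 0.0, [1.0], [])]))
        assert ps.ps_a[5] == 0.0
        assert ps.ps_b[0] == 0.0

    def test_normalization_identity(self, short_chain):
        """Summing PS within a source equals the chain average of 1/k' over
        models with at least one included component from that source (each
        model's scores total (1/k') * sum_j |b_j|/sum|b| = 1/k')."""
        ps = combined_posterior_summary(short_chain)
        M = len(short_chain)
        avg_a = sum(1 / s.config.k for s in short_chain.samples
                    if s.config.k > 0) / M
        avg_b = sum(1 / s.config.k_C for s in short_chain.samples
                    if s.config.k_C > 0) / M
        assert ps.ps_a.sum() == pytest.approx(avg_a, abs=1e-12)
        assert ps.ps_b.sum() == pytest.approx(avg_b, abs=1e-12)


class TestDimensionalityPercentiles:
    def test_constant_chain(self):
        samples = [(ModelConfiguration((0, 1), (2, 3, 4)), 0.0,
                    [1.0] * 5, [1.0, 1.0])] * 4
        vals = dimensionality_percentiles(_chain(samples), [1, 50, 99])
        np.testing.assert_array_equal(vals, [5, 5, 5])

    def test_median_of_1_to_100(self):
        samples = [(ModelConfiguration((), tuple(range(k))), 0.0, [1.0] * k, [])
                   for k in range(1, 101)]
        chain = _chain(samples, p=100)
        assert dimensionality_percentiles(chain, [50])[0] == 50

    def test_matches_sort_based_oracle(self, short_chain):
        qs = [2.5, 25, 50, 75, 97.5]
        got = dimensionality_percentiles(short_chain, qs)
        trace = np.sort(short_chain.k_trace())
        M = trace.size
        expected = [trace[max(1, int(np.ceil(q / 100 * M))) - 1] for q in qs]
        np.testing.assert_array_equal(got, expected)


class TestPredict:
    def _design(self, U, V):
        n = np.asarray(U).shape[0]
        return PairedDesign(np.zeros(n, dtype=int), U, V)

    def test_zero_eta_gives_half(self):
        chain = _chain([(ModelConfiguration((), ()), 0.0, [], [])], p=2)
        d = self._design(np.ones((3, 2)), np.ones((3, 2)))
        np.testing.assert_allclose(predict(chain, d), 0.5)

    def test_two_models_average(self):
        eta1 = np.log(0.2 / 0.8)
        eta2 = np.log(0.8 / 0.2)
        chain = _chain([
            (ModelConfiguration((), ()), eta1, [], []),
            (ModelConfiguration((), ()), eta2, [], []),
        ], p=2)
        d = self._design(np.ones((1, 2)), np.ones((1, 2)))
        assert predict(chain, d)[0] == pytest.approx(0.5)

    def test_matches_per_model_loop_and_order_invariance(self, short_chain,
                                                         toy_design):
        got = predict(short_chain, toy_design)
        acc = np.zeros(toy_design.n)
        for s in short_chain.samples:
            eta = np.full(toy_design.n, s.coeffs.beta0)
            for pos, j in enumerate(s.config.included):
                eta += s.coeffs.a[pos] * toy_design.U[:, j]
            for pos, j in enumerate(s.config.couples):
                eta += s.coeffs.b[pos] * toy_design.V[:, j]
            acc += 1 / (1 + np.exp(-eta))
        np.testing.assert_allclose(got, acc / len(short_chain), atol=1e-10)

        reversed_chain = Chain(
            [ChainSample(i + 1, s.config, s.coeffs) for i, s in
             enumerate(reversed(short_chain.samples))],
            short_chain.settings, short_chain.prior, short_chain.p,
            short_chain.pair_ids)
        np.testing.assert_allclose(predict(reversed_chain, toy_design), got,
                                   atol=1e-12)

    def test_pair_mismatch_rejected(self, short_chain):
        d = PairedDesign(np.zeros(2, dtype=int), np.ones((2, 2)),
                         np.ones((2, 2)))
        with pytest.raises(ValueError, match="pairs"):
            predict(short_chain, d)


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        m = classification_metrics(np.array([1.0, 0.0, 1.0, 0.0]), y)
        assert m["error_rate"] == 0.0
        assert m["brier"] == 0.0
        assert m["auc"] == 1.0

    def test_uninformative_half_probabilities(self):
        y = np.array([1, 1, 0, 0, 0])
        m = classification_metrics(np.full(5, 0.5), y)
        assert m["brier"] == pytest.approx(0.25)
        # 0.5 is not > cutoff, so everyone is assigned control
        assert m["error_rate"] == pytest.approx(2 / 5)

    def test_hand_computed_example(self):
        y = np.array([1, 1, 0, 0])
        probs = np.array([0.9, 0.6, 0.4, 0.1])
        m = classification_metrics(probs, y)
        assert m["error_rate"] == 0.0
        assert m["brier"] == pytest.approx((0.01 + 0.16 + 0.16 + 0.01) / 4)
        assert m["auc"] == 1.0

    def test_delong_interval_matches_pROC(self):
        """Frozen reference from R pROC ci.auc(method='delong')."""
        y = np.array([1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 1])
        probs = np.array([0.9, 0.8, 0.35, 0.6, 0.4, 0.2, 0.55, 0.45, 0.7,
                          0.3, 0.65, 0.5])
        m = classification_metrics(probs, y)
        assert m["auc"] == pytest.approx(0.9166666667, abs=1e-9)
        assert m["auc_ci"][0] == pytest.approx(0.7377472523, abs=1e-9)
        assert m["auc_ci"][1] == pytest.approx(1.0, abs=1e-12)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
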