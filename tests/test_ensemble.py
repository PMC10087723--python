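import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmameta.effect_transforms import InvalidInputError, StudyData
from bmameta.ensemble import (
    DegenerateEnsembleError, MixturePosterior, aggregate,
    averaged_weight_function, evidence_category, inclusion_bf,
    model_averaged_posterior, posterior_model_probs, summarize)
from bmameta.inference import FitSettings, fit_ensemble
from bmameta.model_space import build_ensemble


class TestPosteriorModelProbs:
    def test_equal_margliks_return_prior(self):
        prior = np.array([0.5, 0.3, 0.2])
        post = posterior_model_probs([-3.0, -3.0, -3.0], prior)
        assert np.allclose(post, prior, atol=1e-12)

    def test_odds_three_to_one(self):
        post = posterior_model_probs([math.log(3.0), 0.0], [0.5, 0.5])
        assert np.allclose(post, [0.75, 0.25], atol=1e-12)

    def test_shift_invariance(self):
        lm = np.array([-10.0, -12.0, -9.5])
        prior = np.array([0.2, 0.3, 0.5])
        a = posterior_model_probs(lm, prior)
        b = posterior_model_probs(lm + 123.4, prior)
        assert np.allclose(a, b, atol=1e-12)

    def test_sums_to_one_and_validates(self):
        post = posterior_model_probs([-1000.0, -1001.0], [0.5, 0.5])
        assert post.sum() == pytest.approx(1.0, abs=1e-10)
        with pytest.raises(InvalidInputError):
            posterior_model_probs([0.0], [0.5, 0.5])
        with pytest.raises(DegenerateEnsembleError):
            posterior_model_probs([-np.inf, -np.inf], [0.5, 0.5])


class TestInclusionBF:
    def test_no_update_is_one(self):
        p = [0.25, 0.25, 0.25, 0.25]
        assert inclusion_bf(p, p, [0, 1]) == pytest.approx(1.0)

    def test_complement_product_is_one(self):
        prior = np.array([0.4, 0.1, 0.3, 0.2])
        post = np.array([0.1, 0.2, 0.3, 0.4])
        bf = inclusion_bf(prior, post, [0, 2])
        bf_c = inclusion_bf(prior, post, [1, 3])
        assert bf * bf_c == pytest.approx(1.0, abs=1e-12)

    def test_invalid_subsets(self):
        p = [0.5, 0.5]
        with pytest.raises(InvalidInputError):
            inclusion_bf(p, p, [])
        with pytest.raises(InvalidInputError):
            inclusion_bf(p, p, [0, 1])

    def test_printed_table_probabilities(self):
        # prior and posterior model probability columns of the default
        # ensemble's published worked example, rounded to 3 decimals
        prior = np.array(
            [0.125] + [0.010] * 6 + [0.031] * 2
            + [0.125] + [0.010] * 6 + [0.031] * 2
            + [0.125] + [0.010] * 6 + [0.031] * 2
            + [0.125] + [0.010] * 6 + [0.031] * 2)
        post = np.array(
            [0.000, 0.000, 0.000, 0.012, 0.034, 0.001, 0.004, 0.281, 0.254,
             0.000, 0.000, 0.000, 0.014, 0.020, 0.006, 0.010, 0.021, 0.017,
             0.051, 0.007, 0.031, 0.030, 0.035, 0.018, 0.022, 0.047, 0.046,
             0.007, 0.001, 0.003, 0.005, 0.005, 0.003, 0.004, 0.004, 0.004])
        prior = prior / prior.sum()
        post = post / post.sum()
        bf10 = inclusion_bf(prior, post, list(range(18, 36)))
        assert bf10 == pytest.approx(0.479, abs=0.01)
        # restricted selection-vs-regression comparison
        sel = [i for i in range(36) if i % 9 in (1, 2, 3, 4, 5, 6)]
        reg = [i for i in range(36) if i % 9 in (7, 8)]
        pr = np.zeros(36)
        pr[sel + reg] = prior[sel + reg]
        po = np.zeros(36)
        po[sel + reg] = post[sel + reg]
        bf_sr = inclusion_bf(pr / pr.sum(), po / po.sum(), sel)
        assert bf_sr == pytest.approx(0.397, abs=0.02)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 1), min_size=4, max_size=8),
           st.lists(st.floats(0.01, 1), min_size=4, max_size=8),
           st.integers(1, 3))
    def test_reciprocal_property(self, prior_raw, post_raw, k):
        n = min(len(prior_raw), len(post_raw))
        prior = np.array(prior_raw[:n]) / sum(prior_raw[:n])
        post = np.array(post_raw[:n]) / sum(post_raw[:n])
        subset = list(range(k))
        comp = list(range(k, n))
        assert inclusion_bf(prior, post, subset) * \
            inclusion_bf(prior, post, comp) == pytest.approx(1.0, rel=1e-9)


class TestMixturePosterior:
    def test_pure_spike(self):
        mix = MixturePosterior(spike_weight=1.0, spike_value=0.0)
        s = summarize(mix)
        assert s["mean"] == 0.0
        assert (s["ci_lower"], s["ci_upper"]) == (0.0, 0.0)

    def test_spike_plus_slab_mean(self, rng):
        slab = rng.normal(0.1, 1e-4, size=200_000)
        mix = MixturePosterior(0.6, 0.0, [(0.4, slab)])
        assert mix.mean() == pytest.approx(0.04, abs=1e-4)

    def test_uniform_slab_ci_lower_bound_zero(self, rng):
        # 50% spike at 0 + 50% Uniform(1,2): 2.5% quantile hits the spike
        slab = rng.uniform(1.0, 2.0, size=100_000)
        mix = MixturePosterior(0.5, 0.0, [(0.5, slab)])
        lo, hi = mix.ci(0.95)
        assert lo == 0.0
        assert hi == pytest.approx(1.95, abs=0.01)

    def test_quantiles_of_explicit_mixture(self, rng):
        slab = rng.uniform(1.0, 2.0, size=200_000)
        mix = MixturePosterior(0.5, 0.0, [(0.5, slab)])
        # F(x) = 0.5 + 0.5 (x-1) on [1,2]; quantile(0.75) = 1.5
        assert mix.quantile([0.75])[0] == pytest.approx(1.5, abs=0.01)


class TestEvidenceCategory:
    def test_labels(self):
        assert evidence_category(1.0) == "undecided"
        assert evidence_category(10.0) == "evidence_presence"   # inclusive
        assert evidence_category(0.1) == "evidence_absence"     # inclusive
        assert evidence_category(0.05) == "evidence_absence"
        assert evidence_category(11.0) == "evidence_presence"

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            evidence_category(0.0)
        with pytest.raises(InvalidInputError):
            evidence_category(-2.0)


@pytest.fixture(scope="module")
def fitted_small():
    data = StudyData(y=[0.15, 0.3, 0.05, 0.2], se=[0.08, 0.12, 0.1, 0.09])
    ens = build_ensemble(include_bias=False)  # 4 models, fast
    fitted = fit_ensemble(ens, data,
                          FitSettings(chains=2, warmup=500, draws=1500, seed=7))
    return ens, fitted


class TestAggregate:

    def test_posterior_probs_sum_to_one(self, fitted_small):
        ens, fitted = fitted_small
        res = aggregate(ens, fitted)
        assert res.posterior_probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.per_model_bf[np.isfinite(res.per_model_bf)] > 0)

    def test_mean_in_convex_hull_of_model_means(self, fitted_small):
        ens, fitted = fitted_small
        res = aggregate(ens, fitted, back_transform=False)
        means = [0.0 if not fm.spec.has_effect else fm.mu_draws().mean()
                 for fm in fitted]
        assert min(means) - 1e-9 <= res.mu_analysis["mean"] <= max(means) + 1e-9

    def test_single_model_mixture_equals_model_posterior(self, fitted_small):
        ens, fitted = fitted_small
        fm = fitted[2]  # mu free, tau point
        mix = model_averaged_posterior([fm], [1.0], "mu")
        assert mix.spike_weight == 0.0
        assert mix.mean() == pytest.approx(fm.mu_draws().mean(), abs=1e-12)

    def test_averaged_weight_function(self):
        from bmameta.model_space import WeightFunctionSpec
        data = StudyData(y=[0.15, 0.3, 0.05, 0.2], se=[0.08, 0.12, 0.1, 0.09])
        ens = build_ensemble(weight_fns=[WeightFunctionSpec("one", (0.05,))],
                             include_regression=False)
        fitted = fit_ensemble(ens, data,
                              FitSettings(chains=2, warmup=400, draws=800, seed=9))
        res = aggregate(ens, fitted)
        wf = averaged_weight_function(ens, fitted, res.posterior_probs)
        # non-selection models count as omega = 1, so the average stays in
        # (0, 1] and is 1 at the most significant p-values
        assert np.all(wf["mean"] > 0) and np.all(wf["mean"] <= 1.0 + 1e-12)
        assert wf["mean"][0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(wf["ci_lower"] <= wf["mean"] + 1e-12)
        assert np.all(wf["mean"] <= wf["ci_upper"] + 1e-12)

    def test_no_bias_reduction_matches_plain_bma(self, fitted_small):
        # bias-model prior mass 0 -> plain spike/slab + fixed/random BMA
        ens, fitted = fitted_small
        res = aggregate(ens, fitted)
        assert math.isfinite(res.bf_effect) and res.bf_effect > 0
        assert math.isnan(res.bf_bias)  # no bias models to compare
        assert res.bf_selection_vs_petpeese is None
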