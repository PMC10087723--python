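import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import norm, invgamma

from bmameta.effect_transforms import Direction, StudyData
from bmameta.likelihoods import (
    ParameterVector, interval_index, interval_probs, log_prior, loglik_plain,
    loglik_regression, loglik_selection, loglik_model)
from bmameta.model_space import (
    BiasType, ModelSpec, PriorFamily, PriorSpec, Scale, WeightFunctionSpec,
    build_ensemble, cum_dirichlet_weights, default_weight_functions)


def make_model(effect=None, tau=None, bias=BiasType.NONE, wf=None, slope=None):
    point0 = PriorSpec(PriorFamily.POINT, (0.0,), Scale.RAW)
    return ModelSpec(id=1, effect=effect or point0, heterogeneity=tau or point0,
                     bias_type=bias, weight_fn=wf, slope_prior=slope,
                     prior_prob=1.0)


class TestLoglikPlain:
    def test_single_standard_normal(self):
        d = StudyData(y=[0.0], se=[1.0])
        assert loglik_plain(d, 0.0, 0.0) == pytest.approx(math.log(0.3989423), abs=1e-6)
        assert loglik_plain(d, 0.0, 0.0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_tau_zero_equals_fixed_effect(self):
        d = StudyData(y=[0.2, -0.1], se=[0.15, 0.25])
        fixed = float(np.sum(norm.logpdf(d.y, 0.1, d.se)))
        assert loglik_plain(d, 0.1, 0.0) == pytest.approx(fixed, abs=1e-12)

    def test_against_independent_density(self):
        d = StudyData(y=[0.2, 0.4], se=[0.1, 0.2])
        expected = float(np.sum(norm.logpdf(
            d.y, 0.3, np.sqrt(d.se ** 2 + 0.05 ** 2))))
        assert loglik_plain(d, 0.3, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_order_invariance(self):
        d1 = StudyData(y=[0.2, 0.4, -0.1], se=[0.1, 0.2, 0.3])
        d2 = StudyData(y=[-0.1, 0.2, 0.4], se=[0.3, 0.1, 0.2])
        assert loglik_plain(d1, 0.1, 0.2) == pytest.approx(
            loglik_plain(d2, 0.1, 0.2), abs=1e-12)


class TestIntervalProbs:
    def test_uniform_p_under_null_one_sided(self):
        wf = WeightFunctionSpec("one", (0.05,))
        probs = interval_probs(0.0, 0.0, 1.0, wf)
        assert np.allclose(probs, [0.05, 0.95], atol=1e-10)

    def test_uniform_p_under_null_two_sided(self):
        wf = WeightFunctionSpec("two", (0.05,))
        probs = interval_probs(0.0, 0.0, 1.0, wf)
        assert np.allclose(probs, [0.05, 0.95], atol=1e-10)

    def test_shifted_threshold(self):
        wf = WeightFunctionSpec("one", (0.05,))
        probs = interval_probs(1.0, 0.0, 1.0, wf)
        assert probs[0] == pytest.approx(norm.sf(norm.isf(0.05) - 1.0), abs=1e-9)
        assert probs[0] == pytest.approx(0.2595110, abs=1e-6)
        assert probs[1] == pytest.approx(0.7404890, abs=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(mu=st.floats(-2, 2), tau=st.floats(0, 1), se=st.floats(0.05, 2),
           wf_i=st.integers(0, 5))
    def test_sums_to_one(self, mu, tau, se, wf_i):
        wf = default_weight_functions()[wf_i]
        probs = interval_probs(mu, tau, se, wf)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(probs >= 0)


class TestIntervalIndex:
    def test_tie_goes_to_more_significant(self):
        wf = WeightFunctionSpec("one", (0.025, 0.05))
        se = 1.0
        y_at_cut = norm.isf(0.05)  # p exactly 0.05
        assert interval_index(np.array([y_at_cut]), np.array([se]), wf)[0] == 1

    def test_basic_membership(self):
        wf = WeightFunctionSpec("two", (0.05,))
        j = interval_index(np.array([3.0, 0.5]), np.array([1.0, 1.0]), wf)
        assert list(j) == [0, 1]


class TestLoglikSelection:
    def test_unit_weights_reduce_to_plain(self):
        d = StudyData(y=[0.2, 0.4, -0.3], se=[0.1, 0.2, 0.15])
        for wf in default_weight_functions():
            ll = loglik_selection(d, 0.1, 0.1, np.ones(wf.J), wf)
            assert ll == pytest.approx(loglik_plain(d, 0.1, 0.1), abs=1e-10)

    def test_hand_computed_single_study(self):
        # phi(0) * 0.5 / (1*0.05 + 0.5*0.95) = 0.3799450
        d = StudyData(y=[0.0], se=[1.0])
        wf = WeightFunctionSpec("two", (0.05,))
        ll = loglik_selection(d, 0.0, 0.0, np.array([1.0, 0.5]), wf)
        assert ll == pytest.approx(math.log(0.3799450), abs=1e-6)

    def test_zero_weight_observed_interval_is_minus_inf(self):
        d = StudyData(y=[0.0], se=[1.0])  # clearly non-significant
        wf = WeightFunctionSpec("two", (0.05,))
        assert loglik_selection(d, 0.0, 0.0, np.array([1.0, 0.0]), wf) == -np.inf

    def test_continuity_toward_unit_weights(self):
        d = StudyData(y=[0.3, 1.9], se=[0.5, 0.9])
        wf = WeightFunctionSpec("one", (0.05, 0.5))
        omega = np.array([1.0, 1.0 - 1e-8, 1.0 - 1e-8])
        ll = loglik_selection(d, 0.2, 0.1, omega, wf)
        assert ll == pytest.approx(loglik_plain(d, 0.2, 0.1), abs=1e-6)

    @pytest.mark.parametrize("wf_i", range(6))
    def test_weighted_density_normalizes(self, wf_i, rng):
        # exp(loglik) integrates to 1 over y for a single study
        wf = default_weight_functions()[wf_i]
        mu, tau, se = 0.23, 0.12, 0.4
        eta = rng.dirichlet(np.ones(wf.J))
        omega = cum_dirichlet_weights(eta)

        def dens(y):
            return math.exp(loglik_selection(
                StudyData(y=[y], se=[se]), mu, tau, omega, wf))

        total, err = integrate.quad(dens, -10, 10, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_order_invariance(self):
        wf = WeightFunctionSpec("one", (0.05,))
        d1 = StudyData(y=[0.2, 1.4], se=[0.1, 0.7])
        d2 = StudyData(y=[1.4, 0.2], se=[0.7, 0.1])
        om = np.array([1.0, 0.3])
        assert loglik_selection(d1, 0.1, 0.05, om, wf) == pytest.approx(
            loglik_selection(d2, 0.1, 0.05, om, wf), abs=1e-12)


class TestLoglikRegression:
    def test_zero_slope_reduces_to_plain(self):
        d = StudyData(y=[0.2, 0.4], se=[0.1, 0.2])
        for kind in ("pet", "peese"):
            assert loglik_regression(d, 0.1, 0.05, 0.0, kind) == pytest.approx(
                loglik_plain(d, 0.1, 0.05), abs=1e-12)

    def test_pet_mean_matches_datum(self):
        # mu + b*se = 0.1 + 2*0.1 = 0.3 = y  => density N(0; 0, 0.01)
        d = StudyData(y=[0.3], se=[0.1])
        ll = loglik_regression(d, 0.1, 0.0, 2.0, "pet")
        assert ll == pytest.approx(math.log(3.989423), abs=1e-6)

    def test_pet_equals_peese_at_unit_se(self):
        d = StudyData(y=[0.4], se=[1.0])
        assert loglik_regression(d, 0.1, 0.2, 0.7, "pet") == pytest.approx(
            loglik_regression(d, 0.1, 0.2, 0.7, "peese"), abs=1e-12)


class TestLogPrior:
    def test_standard_normal_at_zero(self):
        spec = make_model(effect=PriorSpec(PriorFamily.NORMAL, (0.0, 1.0), Scale.RAW))
        lp = log_prior(ParameterVector(mu=0.0), spec)
        assert lp == pytest.approx(-0.9189385, abs=1e-6)

    def test_inv_gamma_density(self):
        # InvGamma(1, 0.15) at tau = 0.15: (1/0.15) e^{-1}
        spec = make_model(tau=PriorSpec(PriorFamily.INV_GAMMA, (1.0, 0.15), Scale.RAW))
        lp = log_prior(ParameterVector(tau=0.15), spec)
        assert lp == pytest.approx(math.log((1.0 / 0.15) * math.exp(-1.0)), abs=1e-10)
        assert lp == pytest.approx(
            invgamma.logpdf(0.15, 1.0, scale=0.15), abs=1e-10)

    def test_negative_slope_outside_support(self):
        spec = make_model(bias=BiasType.PET,
                          slope=PriorSpec(PriorFamily.CAUCHY_POS, (1.0,), Scale.RAW))
        assert log_prior(ParameterVector(b=-0.1), spec) == -np.inf

    def test_half_cauchy_normalizes(self):
        spec = make_model(bias=BiasType.PET,
                          slope=PriorSpec(PriorFamily.CAUCHY_POS, (1.0,), Scale.RAW))

        def dens(b):
            return math.exp(log_prior(ParameterVector(b=b), spec))

        total, _ = integrate.quad(dens, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_transformed_effect_prior_normalizes(self):
        # Normal(0,1) declared on d, evaluated on z with the sinh Jacobian
        spec = make_model(effect=PriorSpec(PriorFamily.NORMAL, (0.0, 1.0),
                                           Scale.COHENS_D))

        def dens(z):
            return math.exp(log_prior(ParameterVector(mu=z), spec))

        total, _ = integrate.quad(dens, -5, 5, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_point_mass_mismatch(self):
        spec = make_model()
        assert log_prior(ParameterVector(mu=0.2), spec) == -np.inf
        assert log_prior(ParameterVector(mu=0.0), spec) == 0.0


class TestKernelAgreement:
    def test_compiled_kernel_matches_reference(self, five_studies, rng):
        # the sampler's compiled log-posterior equals reference loglik +
        # log prior + transform Jacobians at random points
        from bmameta import _kernels
        from bmameta.inference import _encode, _constrain, grid_logpost

        ens = build_ensemble()
        for spec in ens.models:
            enc = _encode(spec, five_studies)
            if enc.D == 0:
                continue
            X = rng.standard_normal((10, enc.D))
            kern = _kernels.logpost_many(X, *enc.args)
            ref = grid_logpost(spec, five_studies, X)
            assert np.allclose(kern, ref, atol=1e-10), spec.id

    def test_grid_logpost_matches_scalar_reference(self, five_studies, rng):
        # vectorized grid path vs scalar likelihood + prior composition
        from bmameta.inference import _encode, _constrain, grid_logpost

        ens = build_ensemble()
        for spec in [ens.models[18], ens.models[27], ens.models[25],
                     ens.models[30], ens.models[35]]:
            enc = _encode(spec, five_studies)
            X = 0.5 * rng.standard_normal((5, enc.D))
            lp_grid = grid_logpost(spec, five_studies, X)
            cons = _constrain(spec, enc, X)
            for i in range(X.shape[0]):
                theta = ParameterVector(
                    mu=cons.get("mu", np.zeros(5))[i],
                    tau=cons.get("tau", np.zeros(5))[i],
                    eta=cons["eta"][i] if "eta" in cons else None,
                    b=cons.get("b", np.zeros(5))[i])
                base = loglik_model(spec, five_studies, theta) + \
                    log_prior(theta, spec)
                # remaining difference is the unconstrained-transform Jacobian
                jac = lp_grid[i] - base
                assert np.isfinite(jac)
                # Jacobian must not depend on the data: recompute on other data
                other = StudyData(y=[0.5, -0.2], se=[0.3, 0.4])
                lp2 = grid_logpost(spec, other, X[i:i + 1])[0]
                base2 = loglik_model(spec, other, theta) + log_prior(theta, spec)
                assert lp2 - base2 == pytest.approx(jac, abs=1e-8)
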