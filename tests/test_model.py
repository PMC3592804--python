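"""Likelihood assembly, closed-form marginal, and the Model/Results API."""

import numpy as np
import pytest

from robustpk import (
    MCMCConfig,
    ModelSpec,
    ObservationBlock,
    PKDataset,
    PKMixedModel,
    ParameterState,
    conditional_loglik,
    marginal_normal_loglik,
    mvt_logpdf,
)
from robustpk.core import build_design_matrix, mvn_logpdf
from robustpk.exceptions import DataValidationError, PKDomainError


def make_state(data, beta=(0.4, -0.04, -0.2), b=None, s1=0.008, s2=0.008):
    b = np.zeros(data.n_subjects) if b is None else np.asarray(b, float)
    return ParameterState(beta=np.asarray(beta, float), b=b,
                          sigma1=s1, sigma2=s2)


class TestTypes:
    def test_constraint_violations_rejected(self):
        with pytest.raises(PKDomainError):
            ParameterState(beta=np.array([0.4, 0.04, -0.2]), b=np.zeros(2),
                           sigma1=0.01, sigma2=0.01)
        with pytest.raises(PKDomainError):
            ParameterState(beta=np.array([0.4, -0.04, -0.2]), b=np.zeros(2),
                           sigma1=-1.0, sigma2=0.01)

    def test_spec_validation(self):
        with pytest.raises(PKDomainError):
            ModelSpec(error_family="t", nu=2.0)
        with pytest.raises(PKDomainError):
            ModelSpec(error_family="poisson")

    def test_dataset_invariants(self):
        with pytest.raises(DataValidationError):
            ObservationBlock("A", np.array([1.0]), np.array([1.0]), 10.0)
        with pytest.raises(DataValidationError):
            ObservationBlock("A", np.array([2.0, 1.0]),
                             np.array([1.0, 1.0]), 10.0)
        with pytest.raises(DataValidationError):
            PKDataset([])


class TestConditionalLoglik:
    def test_single_observation_at_mean_normal(self):
        data = PKDataset([
            ObservationBlock("A", np.array([1.0, 2.0]),
                             np.exp([0.16, 0.22]), 10.0)])
        # log conc exactly at linear predictor for beta=(0.4,-0.04,-0.2)?
        # time 1: 0.4-0.04-0.2 = 0.16; time 2: 0.4-0.08-0.1 = 0.22
        state = make_state(data, s2=0.5)
        ll = conditional_loglik(data, state, ModelSpec(error_family="normal"))
        np.testing.assert_allclose(ll, 2 * (-0.5 * np.log(2 * np.pi * 0.5)),
                                   rtol=1e-12)

    def test_doubling_dataset_doubles_loglik(self, tiny_data, t_spec):
        state = make_state(tiny_data)
        doubled = PKDataset(list(tiny_data.subjects) + [
            ObservationBlock(s.subject_id + "_copy", s.times.copy(),
                             s.concentrations.copy(), s.dose)
            for s in tiny_data])
        state2 = make_state(doubled)
        np.testing.assert_allclose(
            conditional_loglik(doubled, state2, t_spec),
            2 * conditional_loglik(tiny_data, state, t_spec), rtol=1e-12)

    def test_t_family_composes_from_mvt_logpdf(self, tiny_data, t_spec):
        state = make_state(tiny_data, b=[0.05, -0.02])
        expected = 0.0
        for i, s in enumerate(tiny_data):
            X = build_design_matrix(s.times)
            mu = X @ state.beta + state.b[i]
            expected += mvt_logpdf(np.log(s.concentrations), mu,
                                   state.sigma2, t_spec.nu)
        np.testing.assert_allclose(
            conditional_loglik(tiny_data, state, t_spec), expected,
            rtol=1e-12)

    def test_invariant_to_subject_ordering(self, tiny_data, t_spec):
        state = make_state(tiny_data, b=[0.05, -0.02])
        flipped = PKDataset(list(tiny_data.subjects)[::-1])
        state_f = make_state(flipped, b=[-0.02, 0.05])
        np.testing.assert_allclose(
            conditional_loglik(tiny_data, state, t_spec),
            conditional_loglik(flipped, state_f, t_spec), rtol=1e-12)

    def test_gamma_family_requires_shape(self, tiny_data):
        state = make_state(tiny_data)
        with pytest.raises(PKDomainError):
            conditional_loglik(tiny_data, state,
                               ModelSpec(error_family="gamma"))


class TestMarginalNormalLoglik:
    def test_degenerate_random_effect_matches_conditional(self, tiny_data,
                                                          normal_spec):
        state = make_state(tiny_data, s2=0.3)
        # sigma1 -> 0 collapses the marginal onto the b=0 conditional
        marg = marginal_normal_loglik(tiny_data, state.beta, 0.0, 0.3,
                                      normal_spec)
        cond = conditional_loglik(tiny_data, state, normal_spec)
        np.testing.assert_allclose(marg, cond, rtol=1e-10)

    def test_compound_symmetric_covariance_matches_scipy(self, normal_spec):
        data = PKDataset([ObservationBlock(
            "A", np.array([1.0, 2.0]), np.array([1.2, 1.4]), 10.0)])
        beta = np.array([0.4, -0.04, -0.2])
        s1, s2 = 0.4, 0.6
        X = build_design_matrix(data.subjects[0].times)
        r = data.subjects[0].log_conc - X @ beta
        cov = s2 * np.eye(2) + s1 * np.ones((2, 2))
        from scipy.stats import multivariate_normal
        expected = multivariate_normal.logpdf(r, mean=np.zeros(2), cov=cov)
        np.testing.assert_allclose(
            marginal_normal_loglik(data, beta, s1, s2, normal_spec),
            expected, rtol=1e-10)

    def test_agrees_with_gauss_hermite_quadrature(self, tiny_data,
                                                  normal_spec):
        beta = np.array([0.4, -0.04, -0.2])
        s1, s2 = 0.05, 0.3
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        total = 0.0
        for s in tiny_data:
            X = build_design_matrix(s.times)
            vals = []
            for x in nodes:
                b = np.sqrt(2 * s1) * x
                vals.append(mvn_logpdf(s.log_conc, X @ beta + b, s2))
            from scipy.special import logsumexp
            total += logsumexp(np.array(vals) + np.log(weights)
                               - 0.5 * np.log(np.pi))
        np.testing.assert_allclose(
            marginal_normal_loglik(tiny_data, beta, s1, s2, normal_spec),
            total, atol=1e-6)


class TestModelAPI:
    def test_fit_returns_reproducible_results(self, example1_data, t_spec,
                                              fast_config):
        data, _ = example1_data
        model = PKMixedModel(data, spec=t_spec)
        r1 = model.fit(fast_config)
        r2 = model.fit(fast_config)
        np.testing.assert_array_equal(r1.chain.draws, r2.chain.draws)
        assert set(r1.params.index) >= {"beta0", "beta1", "beta2",
                                        "sigma1", "sigma2"}
        text = r1.summary()
        assert "beta0" in text and "acceptance" in text

    def test_from_dataframe_round_trip(self, tiny_data):
        model = PKMixedModel.from_dataframe(tiny_data.to_dataframe())
        assert model.data.subject_ids == tiny_data.subject_ids
        assert model.data.n_obs == tiny_data.n_obs

    def test_conf_int_brackets_mean(self, example1_data, t_spec, fast_config):
        data, _ = example1_data
        res = PKMixedModel(data, spec=t_spec).fit(fast_config)
        ci = res.conf_int()
        means = res.params
        for p in ("beta0", "beta1", "beta2", "sigma1", "sigma2"):
            assert ci.loc[p, "lower"] <= means[p] <= ci.loc[p, "upper"]
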