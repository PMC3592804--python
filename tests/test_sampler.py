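"""Metropolis-Hastings kernel, chain runner, summaries, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from robustpk import (
    MCMCConfig,
    ModelSpec,
    ParameterState,
    PriorSpec,
    mh_step,
    replicate_study,
    run_chain,
    summarize_chain,
)
from robustpk.sampler import (
    effective_sample_size,
    ess_and_trace,
    metropolis_step,
)
from robustpk.simulate import preset_example
from robustpk.exceptions import NumericalError, PKDomainError


class _ForcedRNG:
    """Deterministic stand-in emitting fixed normal/uniform streams."""

    def __init__(self, z, u=0.5):
        self.z, self.u = z, u

    def standard_normal(self, size=None):
        return self.z if size is None else np.full(size, self.z)

    def uniform(self, size=None):
        return self.u if size is None else np.full(size, self.u)


class TestMetropolisKernel:
    def test_identical_proposal_always_accepted(self):
        logpost = lambda x: -0.5 * x ** 2
        x, lp, acc = metropolis_step(logpost, 1.3, logpost(1.3), scale=0.0,
                                     rng=_ForcedRNG(0.0, u=0.999999))
        assert acc and x == 1.3

    def test_constraint_violation_rejected_regardless_of_u(self):
        # u -> 0 would accept anything; the sign constraint must veto first
        logpost = lambda x: 0.0
        x, lp, acc = metropolis_step(logpost, -0.04, 0.0, scale=1.0,
                                     rng=_ForcedRNG(+1.0, u=1e-300),
                                     constraint=lambda v: v < 0)
        assert not acc and x == -0.04

    def test_conjugate_normal_posterior_mean(self):
        # prior N(mu0, tau2), likelihood ybar ~ N(x, s2/n): closed form
        mu0, tau2, ybar, s2, n = 1.0, 2.0, 0.6, 1.5, 5
        post_var = 1.0 / (1.0 / tau2 + n / s2)
        post_mean = post_var * (mu0 / tau2 + n * ybar / s2)

        def logpost(x):
            return (-0.5 * (x - mu0) ** 2 / tau2
                    - 0.5 * n * (ybar - x) ** 2 / s2)

        rng = np.random.default_rng(42)
        x, lp = 0.0, logpost(0.0)
        draws = np.empty(40_000)
        for i in range(draws.size):
            x, lp, _ = metropolis_step(logpost, x, lp, scale=1.2, rng=rng)
            draws[i] = x
        kept = draws[2000:]
        ess = effective_sample_size(kept)
        mcse = kept.std(ddof=1) / np.sqrt(ess)
        assert abs(kept.mean() - post_mean) < 3 * mcse

    def test_stationary_distribution_on_discrete_target(self):
        """Binned chain frequencies match a 1-D target (chi-square)."""
        probs = np.array([1, 2, 3, 2, 1], dtype=float)
        probs /= probs.sum()
        logp = np.log(probs)
        rng = np.random.default_rng(3)
        x = 2
        counts = np.zeros(5)
        n_steps = 100_000
        samples = []
        for step in range(n_steps):
            prop = x + rng.choice([-1, 1])
            if 0 <= prop <= 4 and np.log(rng.uniform()) < logp[prop] - logp[x]:
                x = prop
            if step % 10 == 0:  # thin to de-correlate for the chi-square
                samples.append(x)
        samples = np.asarray(samples)
        counts = np.bincount(samples, minlength=5).astype(float)
        _, p = stats.chisquare(counts, probs * counts.sum())
        assert p > 0.01


class TestMhStep:
    @pytest.fixture
    def setup(self, tiny_data):
        state = ParameterState(beta=np.array([0.4, -0.04, -0.2]),
                               b=np.zeros(2), sigma1=0.01, sigma2=0.01)
        spec = ModelSpec(error_family="t", nu=4.0)
        return tiny_data, state, spec, PriorSpec(), MCMCConfig()

    def test_positive_beta1_proposal_rejected(self, setup):
        data, state, spec, priors, config = setup
        new, acc = mh_step(state, "beta1", data, spec, priors, config,
                           _ForcedRNG(+100.0, u=1e-300))
        assert not acc and new is state

    def test_blocks_update_only_their_coordinate(self, setup):
        data, state, spec, priors, config = setup
        rng = np.random.default_rng(0)
        for _ in range(20):
            new, acc = mh_step(state, "sigma2", data, spec, priors, config,
                               rng)
            if acc:
                break
        assert acc
        np.testing.assert_array_equal(new.beta, state.beta)
        np.testing.assert_array_equal(new.b, state.b)
        assert new.sigma1 == state.sigma1 and new.sigma2 != state.sigma2

    def test_random_effect_block(self, setup):
        data, state, spec, priors, config = setup
        rng = np.random.default_rng(1)
        new, acc = mh_step(state, ("b", 1), data, spec, priors, config, rng)
        if acc:
            assert new.b[0] == state.b[0] and new.b[1] != state.b[1]

    def test_unknown_block(self, setup):
        data, state, spec, priors, config = setup
        with pytest.raises(PKDomainError):
            mh_step(state, "gamma0", data, spec, priors, config,
                    np.random.default_rng(0))


class TestRunChain:
    def test_seeded_determinism(self, example1_data, t_spec, priors,
                                fast_config):
        data, _ = example1_data
        c1 = run_chain(data, t_spec, priors, fast_config)
        c2 = run_chain(data, t_spec, priors, fast_config)
        np.testing.assert_array_equal(c1.draws, c2.draws)
        assert c1.accept_rates == c2.accept_rates

    def test_retained_draws_respect_constraints(self, example1_data, t_spec,
                                                priors, fast_config):
        data, _ = example1_data
        chain = run_chain(data, t_spec, priors, fast_config)
        retained = chain.retained
        cols = chain.columns
        assert np.all(retained[:, cols.index("beta1")] < 0)
        assert np.all(retained[:, cols.index("beta2")] < 0)
        assert np.all(retained[:, cols.index("sigma1")] > 0)
        assert np.all(retained[:, cols.index("sigma2")] > 0)

    def test_posterior_centers_near_generating_values(self, example1_data,
                                                      priors):
        data, truth = example1_data
        cfg = MCMCConfig(n_iter=2500, burn_in=2000, summary_window=500,
                         seed=3)
        chain = run_chain(data, ModelSpec(error_family="t", nu=4), priors,
                          cfg)
        summ = summarize_chain(chain)
        # slopes are tightly identified; the intercept carries the
        # subject-mean randomness (sd ~ sqrt(sigma1/m) ~ 0.028)
        assert abs(summ.mean("beta1") - truth["beta1"]) < 0.005
        assert abs(summ.mean("beta2") - truth["beta2"]) < 0.02
        assert abs(summ.mean("beta0") - truth["beta0"]) < 0.1

    def test_bad_initials_raise_with_guidance(self, example1_data, priors):
        data, _ = example1_data
        cfg = MCMCConfig(n_iter=100, burn_in=50, summary_window=50,
                         init_sigma2=1e-320)
        with pytest.raises((NumericalError, PKDomainError)):
            run_chain(data, ModelSpec(error_family="t", nu=4), priors, cfg)

    def test_config_validation(self):
        with pytest.raises(PKDomainError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(PKDomainError):
            MCMCConfig(n_iter=100, burn_in=50, summary_window=60)


class TestSummarize:
    def _constant_chain(self, value=1.5, n=200):
        from robustpk.sampler import ChainResult

        cfg = MCMCConfig(n_iter=n, burn_in=0, summary_window=n)
        draws = np.full((n, 1), value)
        return ChainResult(draws=draws, columns=["beta0"], burn_in=0,
                           accept_rates={}, config=cfg, final_scales={},
                           subject_ids=[])

    def test_constant_chain_degenerate_summary(self):
        summ = summarize_chain(self._constant_chain())
        assert summ.mean("beta0") == 1.5
        assert summ.interval("beta0") == (1.5, 1.5)

    def test_percentiles_match_sort_oracle(self):
        from robustpk.sampler import ChainResult

        rng = np.random.default_rng(9)
        col = rng.normal(size=1000)
        cfg = MCMCConfig(n_iter=1000, burn_in=0, summary_window=1000)
        chain = ChainResult(draws=col[:, None], columns=["x"], burn_in=0,
                            accept_rates={}, config=cfg, final_scales={},
                            subject_ids=[])
        summ = summarize_chain(chain)
        s = np.sort(col)
        lo_oracle = np.percentile(s, 2.5)
        hi_oracle = np.percentile(s, 97.5)
        np.testing.assert_allclose(summ.interval("x"),
                                   (lo_oracle, hi_oracle), rtol=1e-12)

    def test_window_equal_to_retained_uses_everything(self):
        chain = self._constant_chain(n=50)
        full = summarize_chain(chain, window=50)
        assert full.window == 50

    def test_oversized_window_errors(self):
        with pytest.raises(PKDomainError):
            summarize_chain(self._constant_chain(n=50), window=51)


class TestESS:
    def test_iid_draws_near_full_length(self):
        x = np.random.default_rng(4).normal(size=4000)
        assert abs(effective_sample_size(x) - 4000) < 0.2 * 4000

    def test_constant_chain_has_no_information(self):
        assert effective_sample_size(np.ones(500)) == 1.0

    def test_ar1_matches_analytic_formula(self):
        rho, n = 0.9, 40_000
        rng = np.random.default_rng(5)
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert abs(effective_sample_size(x) - expected) < 0.25 * expected

    def test_agrees_with_arviz_on_mcmc_output(self, example1_data, t_spec,
                                              priors, fast_config):
        arviz = pytest.importorskip("arviz")
        data, _ = example1_data
        chain = run_chain(data, t_spec, priors, fast_config)
        diag = ess_and_trace(chain)
        x = diag.traces["beta1"].to_numpy()
        ours = diag.ess["beta1"]
        theirs = float(arviz.ess(x[None, :]))
        assert 0.4 < ours / max(theirs, 1.0) < 2.5


class TestReplicateStudy:
    def test_identical_seeds_zero_width_interval(self, priors):
        cfg = MCMCConfig(n_iter=400, burn_in=250, summary_window=150, seed=1)
        study = replicate_study(preset_example(1),
                                ModelSpec(error_family="t", nu=4), priors,
                                cfg, n_reps=2, seeds=[(5, 7), (5, 7)])
        summ = study.summary()
        np.testing.assert_array_equal(summ["lower"], summ["upper"])
        np.testing.assert_array_equal(summ["lower"], summ["mean"])

    def test_requires_two_replicates(self, priors):
        with pytest.raises(PKDomainError):
            replicate_study(preset_example(1), ModelSpec(error_family="t"),
                            priors, MCMCConfig(n_iter=100, burn_in=50,
                                               summary_window=50), n_reps=1)
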