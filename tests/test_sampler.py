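"""Gibbs sampler: conjugacy, draw laws, identification, imputation."""

import numpy as np
import pytest
from scipy import stats

from bcsm.covstruct import build_matrix, validate
from bcsm.sampler import (
    ChainState,
    LayerDesign,
    ModelSpec,
    PriorHyper,
    _stats_for,
    conditional_delta,
    conditional_Delta,
    conditional_mean_sigma2,
    conditional_sigma2,
    group_structure,
    impute_missing,
    prior_params,
    rescale_identify,
    run_chain,
    sample_delta,
    sample_Delta,
    sample_fixed_effects,
    sample_sigma2,
    suffstat_loglik_kernel,
    vague_prior,
)
from bcsm.simulate import SimConfig, simulate_dataset
from bcsm.simulate import testlet_layers as make_testlets
from bcsm.suffstats import RTDataset
from bcsm.tsig import TSIGParams, tsig_cdf, tsig_logpdf
from tests.conftest import make_dataset


@pytest.fixture
def fitted_state(rng, testlet_spec):
    config = SimConfig(
        n_per_group=(40,), p=6, layers=list(testlet_spec.layers),
        delta=(0.25,), Delta=(0.08, 0.02), sigma2=1.0,
    )
    data, _ = simulate_dataset(config, rng=rng)
    state = ChainState(
        mu_T=data.values.mean(axis=0, keepdims=True),
        sigma2=np.full((1, 6), 0.9),
        mean_sigma2=np.array([0.95]),
        delta=np.array([0.2]),
        Delta=np.array([[0.05, 0.01]]),
    )
    return data, state


class TestConjugacyAudit:
    """log(prior kernel x likelihood kernel) - log(posterior kernel) must be
    constant in the parameter: the claimed TSIG posteriors are exactly the
    prior-times-sufficient-statistic-likelihood for every conditional."""

    def _assert_constant(self, grid, log_prior, log_lik, log_post):
        diff = log_prior + log_lik - log_post
        assert np.all(np.isfinite(diff))
        assert np.ptp(diff) < 1e-8

    def test_delta_conditional(self, fitted_state, testlet_spec):
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        post = conditional_delta(testlet_spec, state, 0, stats_)
        pri = prior_params(post, testlet_spec.prior)
        grid = np.linspace(float(post.support_lower) + 1e-4, 1.0, 200)
        self._assert_constant(
            grid,
            tsig_logpdf(grid, pri),
            suffstat_loglik_kernel(grid, float(post.shift), stats_.n, stats_.ssb),
            tsig_logpdf(grid, post),
        )

    def test_sigma2_conditional(self, fitted_state, testlet_spec):
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        post = conditional_sigma2(testlet_spec, state, 0, stats_)
        k = 2
        pk = TSIGParams(float(np.asarray(post.alpha)), float(post.beta[k]),
                        float(post.shift[k]), 0.0)
        pri = prior_params(pk, testlet_spec.prior)
        grid = np.linspace(1e-3, 3.0, 200)
        self._assert_constant(
            grid,
            tsig_logpdf(grid, pri),
            suffstat_loglik_kernel(grid, float(pk.shift), stats_.n, stats_.ssw_k[k]),
            tsig_logpdf(grid, pk),
        )

    def test_mean_sigma2_conditional(self, fitted_state, testlet_spec):
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        post = conditional_mean_sigma2(testlet_spec, state, 0, stats_)
        pri = prior_params(post, testlet_spec.prior)
        grid = np.linspace(1e-3, 3.0, 200)
        self._assert_constant(
            grid,
            tsig_logpdf(grid, pri),
            suffstat_loglik_kernel(grid, float(post.shift), stats_.n, stats_.ssw / 6.0),
            tsig_logpdf(grid, post),
        )

    def test_layer_conditional(self, fitted_state, testlet_spec):
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        for d in range(2):
            post = conditional_Delta(testlet_spec, state, 0, d, stats_)
            pri = prior_params(post, testlet_spec.prior)
            grid = np.linspace(float(post.support_lower) + 1e-4, 1.0, 200)
            self._assert_constant(
                grid,
                tsig_logpdf(grid, pri),
                suffstat_loglik_kernel(grid, float(post.shift), stats_.n, stats_.ssb_d[d]),
                tsig_logpdf(grid, post),
            )

    def test_posterior_parameter_arithmetic(self, fitted_state, testlet_spec):
        """Shapes/scales are alpha0 + n/2 and beta0 + SS/2; the layer shift is
        the average error variance over the layer per item plus delta."""
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        post = conditional_delta(testlet_spec, state, 0, stats_)
        assert float(np.asarray(post.alpha)) == pytest.approx(1e-3 + stats_.n / 2)
        assert float(np.asarray(post.beta)) == pytest.approx(1e-3 + stats_.ssb / 2)
        post_d = conditional_Delta(testlet_spec, state, 0, 0, stats_)
        want_shift = state.sigma2[0, :3].mean() / 3.0 + state.delta[0]
        assert float(np.asarray(post_d.shift)) == pytest.approx(want_shift)


class TestDrawLaws:
    """Empirical CDF of repeated single-site draws matches the analytic TSIG
    conditional on fixed data."""

    def _ks_ok(self, draws, params):
        stat = stats.kstest(draws, lambda x: tsig_cdf(x, params)).statistic
        return stat < 1.95 / np.sqrt(len(draws))

    def test_delta_draw_law(self, fitted_state, testlet_spec, rng):
        data, state = fitted_state
        params = conditional_delta(testlet_spec, state, 0, _stats_for(data, testlet_spec, 0))
        draws = np.empty(4000)
        for i in range(draws.size):
            draws[i] = sample_delta(state, data, testlet_spec, 0, rng)
            state.delta[0] = 0.2  # hold the conditioning state fixed
        assert self._ks_ok(draws, params)

    def test_sigma2_draw_law_and_positivity(self, fitted_state, testlet_spec, rng):
        data, state = fitted_state
        params_vec = conditional_sigma2(testlet_spec, state, 0, _stats_for(data, testlet_spec, 0))
        k = 1
        params = TSIGParams(float(np.asarray(params_vec.alpha)), float(params_vec.beta[k]),
                            float(params_vec.shift[k]), 0.0)
        draws = np.empty(4000)
        for i in range(draws.size):
            draws[i] = sample_sigma2(state, data, testlet_spec, 0, rng, item=k)
            state.sigma2[0, k] = 0.9
        assert draws.min() > 0
        assert self._ks_ok(draws, params)

    def test_Delta_draw_law(self, fitted_state, testlet_spec, rng):
        data, state = fitted_state
        params = conditional_Delta(testlet_spec, state, 0, 1, _stats_for(data, testlet_spec, 0))
        draws = np.empty(4000)
        for i in range(draws.size):
            draws[i] = sample_Delta(state, data, testlet_spec, 0, 1, rng)
            state.Delta[0, 1] = 0.01
        assert self._ks_ok(draws, params)

    def test_fixed_effect_moments(self, fitted_state, testlet_spec, rng):
        data, state = fitted_state
        stats_ = _stats_for(data, testlet_spec, 0)
        sigma = build_matrix(group_structure(testlet_spec, state, 0))
        draws = np.empty((4000, 6))
        for i in range(draws.shape[0]):
            draws[i] = sample_fixed_effects(state, data, testlet_spec, rng)[0]
        se = np.sqrt(np.diag(sigma) / stats_.n / draws.shape[0])
        np.testing.assert_allclose(draws.mean(axis=0), stats_.item_means, atol=4 * se.max())
        np.testing.assert_allclose(
            np.cov(draws, rowvar=False), sigma / stats_.n, atol=6 * sigma.max() / stats_.n / np.sqrt(draws.shape[0]) * np.sqrt(2) * 10
        )


class TestIdentification:
    def test_single_group(self):
        mu = np.array([[1.0, 2.0, 3.0]])
        lam, mz = rescale_identify(mu)
        np.testing.assert_array_equal(lam, mu)
        assert mz[0] == 0.0

    def test_constant_shift_moves_into_group_mean(self):
        mu = np.array([[1.0, 2.0], [1.5, 2.5]])
        lam0, mz0 = rescale_identify(mu)
        shifted = mu.copy()
        shifted[1] += 3.0
        lam1, mz1 = rescale_identify(shifted)
        np.testing.assert_allclose(lam1, lam0)
        assert mz1[1] == pytest.approx(mz0[1] - 3.0)

    def test_roundtrip_and_equal_mean_intensities(self, rng):
        mu = rng.normal(size=(50, 3, 4))  # a whole chain
        lam, mz = rescale_identify(mu)
        np.testing.assert_allclose(lam - mz[:, :, None], mu, atol=1e-12)
        lbar = lam.mean(axis=2)
        np.testing.assert_allclose(lbar - lbar[:, [0]], 0.0, atol=1e-12)
        assert np.all(mz[:, 0] == 0.0)

    def test_all_groups_zero_rule(self):
        mu = np.array([[1.0, 2.0], [3.0, 4.0]])
        lam, mz = rescale_identify(mu, "all_groups_zero")
        np.testing.assert_array_equal(lam, mu)
        np.testing.assert_array_equal(mz, np.zeros(2))


class TestImputation:
    def test_fully_observed_is_noop(self, fitted_state, testlet_spec, rng):
        data, state = fitted_state
        out = impute_missing(state, data, testlet_spec, rng)
        np.testing.assert_array_equal(out, data.values)

    def test_conditional_moments_match_schur_oracle(self, rng):
        spec = ModelSpec(n_items=3, n_groups=1, prior=PriorHyper(1.0, 1.0))
        vals = np.array([[0.5, np.nan, np.nan]] * 1 + [[0.1, 0.2, 0.3]] * 4)
        miss = np.isnan(vals)
        data = RTDataset(values=vals, group_index=np.zeros(5, int), missing=miss)
        state = ChainState(
            mu_T=np.array([[0.0, 0.1, -0.1]]),
            sigma2=np.array([[1.0, 0.8, 1.2]]),
            mean_sigma2=np.array([1.0]),
            delta=np.array([0.4]),
            Delta=np.zeros((1, 0)),
        )
        sigma = build_matrix(group_structure(spec, state, 0))
        draws = np.empty((6000, 2))
        for i in range(draws.shape[0]):
            state.completed = None
            out = impute_missing(state, data, spec, rng)
            draws[i] = out[0, 1:]
        s_oo = sigma[:1, :1]
        s_mo = sigma[1:, :1]
        mean = state.mu_T[0][1:] + (s_mo / s_oo[0, 0]).ravel() * (0.5 - 0.0)
        cov = sigma[1:, 1:] - s_mo @ s_mo.T / s_oo[0, 0]
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=4 * np.sqrt(cov.max() / 6000))
        np.testing.assert_allclose(np.cov(draws, rowvar=False), cov, atol=0.08)

    def test_fully_missing_person_drawn_unconditionally(self, rng):
        spec = ModelSpec(n_items=2, n_groups=1, prior=PriorHyper(1.0, 1.0))
        vals = np.array([[np.nan, np.nan], [0.0, 0.0], [0.2, -0.2]])
        data = RTDataset(values=vals, group_index=np.zeros(3, int))
        state = ChainState(
            mu_T=np.array([[1.0, -1.0]]),
            sigma2=np.ones((1, 2)),
            mean_sigma2=np.array([1.0]),
            delta=np.array([0.0]),
            Delta=np.zeros((1, 0)),
        )
        draws = np.empty((3000, 2))
        for i in range(draws.shape[0]):
            state.completed = None
            draws[i] = impute_missing(state, data, spec, rng)[0]
        np.testing.assert_allclose(draws.mean(axis=0), [1.0, -1.0], atol=0.08)


class TestRunChain:
    def test_same_seed_bit_identical(self, testlet_spec, rng):
        config = SimConfig(n_per_group=(25,), p=6, layers=list(testlet_spec.layers),
                           delta=(0.2,), Delta=(0.05, 0.0), sigma2=1.0)
        data, _ = simulate_dataset(config, rng=rng)
        a = run_chain(data, testlet_spec, 200, 0.1, seed=42)
        b = run_chain(data, testlet_spec, 200, 0.1, seed=42)
        for k in a.samples:
            np.testing.assert_array_equal(a.samples[k], b.samples[k])

    def test_every_stored_state_is_positive_definite(self, testlet_spec, rng):
        config = SimConfig(n_per_group=(30,), p=6, layers=list(testlet_spec.layers),
                           delta=(0.2,), Delta=(0.05, -0.02), sigma2=1.0)
        data, _ = simulate_dataset(config, rng=rng)
        chains = run_chain(data, testlet_spec, 300, 0.1, seed=1)
        for it in range(0, 300, 29):
            state = ChainState(
                mu_T=chains.samples["mu_T"][it],
                sigma2=chains.samples["sigma2"][it],
                mean_sigma2=chains.samples["mean_sigma2"][it],
                delta=chains.samples["delta"][it],
                Delta=chains.samples["Delta"][it],
            )
            assert validate(group_structure(testlet_spec, state, 0)) == []

    def test_degenerate_constant_data_does_not_crash(self):
        spec = ModelSpec(n_items=3, n_groups=1, prior=PriorHyper(1e-3, 1e-3))
        data = make_dataset(np.full((20, 3), 1.7))
        chains = run_chain(data, spec, 150, 0.1, seed=0)
        s2 = chains.retained("sigma2")
        assert np.all(np.isfinite(s2))
        assert s2.mean() < 0.01  # collapses toward prior-dominated small values

    def test_missing_data_chain_runs_and_recovers_roughly(self, rng):
        config = SimConfig(n_per_group=(120,), p=6, layers=make_testlets(6, 2),
                           delta=(0.3,), Delta=(0.0, 0.0), sigma2=1.0,
                           missing_rate=0.1)
        data, truth = simulate_dataset(config, rng=rng)
        spec = ModelSpec(n_items=6, n_groups=1, layers=tuple(config.layers),
                         prior=PriorHyper(1e-3, 1e-3))
        chains = run_chain(data, spec, 400, 0.2, seed=3)
        assert abs(chains.retained("delta").mean() - 0.3) < 0.25
        assert np.isfinite(chains.retained("Delta")).all()

    def test_recovery_on_moderate_dataset(self, rng):
        config = SimConfig(n_per_group=(400,), p=12, layers=make_testlets(12, 2),
                           delta=(0.2,), Delta=(0.3, 0.0), sigma2=1.0)
        data, truth = simulate_dataset(config, rng=rng)
        spec = ModelSpec(n_items=12, n_groups=1, layers=tuple(config.layers),
                         prior=vague_prior(1e-3, 1e3))
        chains = run_chain(data, spec, 600, 0.2, seed=9)
        pm = chains.posterior_means()
        assert abs(pm["delta"][0] - 0.2) < 0.1
        assert abs(pm["Delta"][0, 0] - 0.3) < 0.12
        assert abs(pm["Delta"][0, 1]) < 0.08
        assert abs(pm["sigma2"].mean() - 1.0) < 0.1

    def test_tied_sigma2_equal_across_groups(self, rng):
        layers = make_testlets(4, 2, n_groups=2)
        config = SimConfig(n_per_group=(40, 50), p=4, layers=layers,
                           delta=(0.2, 0.2), Delta=(0.0, 0.0), sigma2=1.0)
        data, _ = simulate_dataset(config, rng=rng)
        spec = ModelSpec(n_items=4, n_groups=2, layers=tuple(layers),
                         prior=PriorHyper(1e-3, 1e-3),
                         tied_sigma2_items=(3,), tie_layers_across_groups=True)
        chains = run_chain(data, spec, 200, 0.1, seed=2)
        s2 = chains.samples["sigma2"]
        np.testing.assert_array_equal(s2[:, 0, 3], s2[:, 1, 3])
        assert not np.array_equal(s2[:, 0, 0], s2[:, 1, 0])
        D = chains.samples["Delta"]
        np.testing.assert_array_equal(D[:, 0, :], D[:, 1, :])

    def test_design_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            ModelSpec(
                n_items=4,
                layers=(
                    LayerDesign("a", np.array([[1.0, 1, 0, 0]])),
                    LayerDesign("b", np.array([[1.0, 1, 0, 0]])),
                ),
            )
        with pytest.raises(ValueError, match="distinct"):
            # duplicating the implicit all-ones speed layer is rejected
            ModelSpec(n_items=3, layers=(LayerDesign("dup", np.ones((1, 3))),))
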