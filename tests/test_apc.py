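"""Bayesian APC model: likelihood, priors, constraints, diagnostics, MCMC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import apcmort as m
from apcmort.apc import _deviance_at, _penalty_matrix


def random_params(grid, rng, scale=0.5):
    return m.APCParameters(
        mu=float(rng.normal(-9, scale)),
        alpha=rng.normal(0, scale, grid.n_age),
        beta=rng.normal(0, scale, grid.n_period),
        gamma=rng.normal(0, scale, grid.n_cohorts),
    )


class TestLogRate:
    def test_additive_decomposition(self, grid):
        zero = m.APCParameters(-9.0, np.zeros(10), np.zeros(6), np.zeros(15))
        assert m.log_rate(zero, 3, 4, grid) == -9.0
        p = m.APCParameters(-9.0, np.zeros(10), np.zeros(6), np.zeros(15))
        p.alpha[2] = 0.5
        p.beta[3] = -0.1
        p.gamma[m.cohort_index(3, 4, grid) - 1] = 0.2
        assert m.log_rate(p, 3, 4, grid) == pytest.approx(-8.4)

    def test_matrix_matches_cellwise_loop(self, grid, rng):
        p = random_params(grid, rng)
        mat = m.log_rate_matrix(p, grid)
        for a in range(1, grid.n_age + 1):
            for pp in range(1, grid.n_period + 1):
                assert mat[a - 1, pp - 1] == pytest.approx(
                    m.log_rate(p, a, pp, grid), rel=1e-14
                )


class TestLoglik:
    def make_counts(self, grid, rng, scale=1e5):
        deaths = rng.integers(0, 40, (grid.n_age, grid.n_period))
        py = rng.uniform(0.5, 2.0, (grid.n_age, grid.n_period)) * scale
        return m.StratumCounts(grid, "male", "low", deaths, py)

    def test_zero_counts_reduce_to_minus_expected(self, grid, rng):
        deaths = np.zeros((grid.n_age, grid.n_period), dtype=int)
        py = rng.uniform(1e4, 1e5, (grid.n_age, grid.n_period))
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        p = random_params(grid, rng)
        lam = np.exp(m.log_rate_matrix(p, grid))
        assert m.loglik(p, counts) == pytest.approx(-np.sum(py * lam), rel=1e-12)

    def test_single_cell_equals_poisson_pmf(self, grid):
        # D = 3 at mean N*lambda = 3
        p = m.APCParameters(
            np.log(0.003), np.zeros(10), np.zeros(6), np.zeros(15)
        )
        deaths = np.zeros((10, 6), dtype=int)
        deaths[0, 0] = 3
        py = np.full((10, 6), 1e-9)
        py[0, 0] = 1000.0
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        expected = stats.poisson.logpmf(3, 3.0) + np.sum(
            -py.ravel()[1:] * 0.003
        )
        assert m.loglik(p, counts) == pytest.approx(expected, rel=1e-9)

    def test_matches_cellwise_pmf_oracle(self, grid, rng):
        counts = self.make_counts(grid, rng)
        p = random_params(grid, rng)
        lam = counts.person_years * np.exp(m.log_rate_matrix(p, grid))
        oracle = stats.poisson.logpmf(counts.deaths, lam).sum()
        assert m.loglik(p, counts) == pytest.approx(oracle, rel=1e-10)


class TestRW2Prior:
    def test_linear_effects_leave_only_the_normalising_constant(self):
        e = 0.3 * np.arange(8) - 1.0
        expected = 6 * stats.norm.logpdf(0.0, scale=np.sqrt(0.25))
        assert m.rw2_logprior(e, 0.25) == pytest.approx(expected, rel=1e-12)

    def test_length_three_is_a_single_gaussian_term(self):
        assert m.rw2_logprior([0.0, 0.0, 1.0], 1.0) == pytest.approx(
            stats.norm.logpdf(1.0), rel=1e-12
        )

    @pytest.mark.parametrize("k", range(3, 21))
    def test_equals_second_difference_mvn_density(self, k, rng):
        e = rng.normal(0, 1, k)
        sigma2 = float(rng.uniform(0.05, 2.0))
        d2mat = np.zeros((k - 2, k))
        for i in range(k - 2):
            d2mat[i, i : i + 3] = (1, -2, 1)
        oracle = stats.multivariate_normal.logpdf(
            d2mat @ e, mean=np.zeros(k - 2), cov=sigma2 * np.eye(k - 2)
        )
        assert m.rw2_logprior(e, sigma2) == pytest.approx(oracle, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m.rw2_logprior([0.0, 1.0], 1.0)
        with pytest.raises(ValueError):
            m.rw2_logprior([0.0, 1.0, 2.0], 0.0)


class TestConstraints:
    def spec(self, grid, **kw):
        return m.APCModelSpec(grid=grid, **kw)

    def test_constrained_state_is_a_fixed_point(self, grid, rng):
        spec = self.spec(grid)
        p = m.apply_constraints(random_params(grid, rng), spec)
        q = m.apply_constraints(p, spec)
        assert q.mu == pytest.approx(p.mu, rel=1e-12)
        assert np.allclose(q.beta, p.beta, atol=1e-12)
        assert np.allclose(q.gamma, p.gamma, atol=1e-12)

    def test_reference_categories_zeroed(self, grid, rng):
        spec = self.spec(grid)
        q = m.apply_constraints(random_params(grid, rng), spec)
        r1, r2 = spec.ref_period_indices
        assert q.beta[r1 - 1] == pytest.approx(0.0, abs=1e-12)
        assert q.beta[r2 - 1] == pytest.approx(0.0, abs=1e-12)
        assert q.gamma[spec.ref_cohort_index - 1] == pytest.approx(0.0, abs=1e-12)
        assert q.alpha.mean() == pytest.approx(0.0, abs=1e-12)

    def test_linear_period_trend_absorbed_into_cohorts(self, grid, rng):
        spec = self.spec(grid)
        p = random_params(grid, rng)
        p.beta = 0.7 - 0.2 * np.arange(1, grid.n_period + 1)
        q = m.apply_constraints(p, spec)
        assert np.allclose(q.beta, 0.0, atol=1e-12)
        assert np.allclose(
            m.log_rate_matrix(q, grid), m.log_rate_matrix(p, grid), rtol=1e-12
        )

    def test_fitted_rates_invariant_on_random_states(self, grid, rng):
        spec = self.spec(grid)
        for _ in range(25):
            p = random_params(grid, rng, scale=1.5)
            q = m.apply_constraints(p, spec)
            before = m.log_rate_matrix(p, grid)
            after = m.log_rate_matrix(q, grid)
            assert np.allclose(after, before, rtol=1e-12, atol=1e-12)

    def test_submodel_levels_only(self, grid, rng):
        spec = self.spec(grid, include_cohort=False)
        p = random_params(grid, rng)
        q = m.apply_constraints(p, spec)
        assert q.beta[spec.ref_period_indices[0] - 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(
            m.log_rate_matrix(q, grid, spec), m.log_rate_matrix(p, grid, spec),
            rtol=1e-12,
        )

    def test_degenerate_grid_rejected(self):
        tiny = m.LexisGrid(
            age_lower_edges=(30, 35), period_start_years=(1976, 1981)
        )
        with pytest.raises(ValueError):
            m.APCModelSpec(grid=tiny)


class TestSplitRhat:
    def test_identical_chains_give_one(self):
        # identical chains have zero between-sequence variance; the split
        # statistic is sqrt((m-1)/m), i.e. 1 to within O(1/m)
        x = np.tile(np.sin(np.arange(400.0)), (4, 1))
        assert m.split_rhat(x) == pytest.approx(1.0, abs=0.005)

    def test_distinct_constant_chains_flagged_infinite(self):
        x = np.vstack([np.zeros(50), np.ones(50)])
        assert m.split_rhat(x) == np.inf

    def test_equal_constant_chains_are_not_nan(self):
        x = np.ones((3, 40))
        assert m.split_rhat(x) == 1.0

    def test_matches_textbook_variance_decomposition(self, rng):
        # AR(1) chains, explicit within/between computation as the oracle
        chains = np.empty((4, 400))
        for c in range(4):
            e = rng.normal(0, 1, 400)
            x = np.zeros(400)
            for t in range(1, 400):
                x[t] = 0.6 * x[t - 1] + e[t]
            chains[c] = x + c * 0.1
        half = 200
        seqs = chains.reshape(8, half)
        means = seqs.mean(axis=1)
        W = np.mean([s.var(ddof=1) for s in seqs])
        B = half * means.var(ddof=1)
        oracle = np.sqrt(((half - 1) / half * W + B / half) / W)
        assert m.split_rhat(chains) == pytest.approx(oracle, rel=1e-12)

    def test_agrees_with_arviz_cross_check(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.normal(0, 1, (4, 500)) + rng.normal(0, 0.2, (4, 1))
        theirs = float(az.rhat(az.convert_to_dataset(chains[..., None]))["x"][0])
        assert m.split_rhat(chains) == pytest.approx(theirs, abs=0.02)


def make_posterior_from_params(params, counts, spec, n=8):
    """Posterior whose every draw is the same state (degenerate)."""
    C, nk = 2, n
    dev = _deviance_at(params, counts, spec)
    return m.APCPosterior(
        spec=spec,
        counts=counts,
        mcmc=m.MCMCConfig(n_chains=C, n_keep_total=C * nk, seed=0),
        mu=np.full((C, nk), params.mu),
        alpha=np.broadcast_to(params.alpha, (C, nk, len(params.alpha))).copy(),
        beta=np.broadcast_to(params.beta, (C, nk, len(params.beta))).copy(),
        gamma=np.broadcast_to(params.gamma, (C, nk, len(params.gamma))).copy(),
        sigma2=np.full((C, nk, 3), 0.01),
        deviance=np.full((C, nk), dev),
        rhat=pd.Series(dtype=float),
        burn_in_used=0,
        converged=True,
    )


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self, grid, rng):
        spec = m.APCModelSpec(grid=grid)
        params = m.apply_constraints(random_params(grid, rng), spec)
        deaths = rng.integers(0, 30, (grid.n_age, grid.n_period))
        py = rng.uniform(1e4, 1e5, (grid.n_age, grid.n_period))
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        post = make_posterior_from_params(params, counts, spec)
        res = m.dic(post)
        assert res.pd == pytest.approx(0.0, abs=1e-8)
        assert res.dic == pytest.approx(res.dbar, abs=1e-8)

    def test_identity_dic_equals_dbar_plus_pd(self, male_low_posterior):
        res = m.dic(male_low_posterior)
        assert res.dic == pytest.approx(res.dbar + res.pd, rel=1e-12)
        assert np.isfinite(res.pd)

    def test_pd_near_free_parameter_count_with_weak_priors(self, male_low_posterior):
        # full model has 1 + (A-1) + (P-2) + (K-1) = 28 identified directions;
        # RW2 shrinkage keeps the effective count below that but well above
        # the age-only count (10)
        res = m.dic(male_low_posterior)
        assert 10 < res.pd < 30


class TestRelativeRisks:
    def test_reference_categories_are_exactly_one(self, male_low_posterior):
        rr = m.relative_risks(male_low_posterior)
        refs = rr[rr.is_reference]
        assert len(refs) == 3  # two period refs + central cohort
        assert np.allclose(refs.rr, 1.0, atol=1e-12)
        assert np.allclose(refs.hi95 - refs.lo95, 0.0, atol=1e-12)

    def test_log2_effect_gives_rr_two(self, grid, rng):
        spec = m.APCModelSpec(grid=grid)
        params = m.APCParameters(
            -9.0, np.zeros(grid.n_age), np.zeros(grid.n_period), np.zeros(grid.n_cohorts)
        )
        params.gamma[0] = np.log(2.0)
        deaths = np.ones((grid.n_age, grid.n_period), dtype=int)
        py = np.full((grid.n_age, grid.n_period), 1e5)
        counts = m.StratumCounts(grid, "male", "low", deaths, py)
        post = make_posterior_from_params(params, counts, spec)
        rr = m.relative_risks(post)
        first = rr[(rr.dimension == "cohort") & (rr["index"] == 1)].iloc[0]
        assert first.rr == pytest.approx(2.0, rel=1e-12)

    def test_matches_exp_then_summarise_oracle(self, male_low_posterior):
        rr = m.relative_risks(male_low_posterior)
        g = np.exp(male_low_posterior.gamma_draws())
        row = rr[(rr.dimension == "cohort") & (rr["index"] == 3)].iloc[0]
        assert row.rr == pytest.approx(g[:, 2].mean(), rel=1e-12)
        assert row.lo95 == pytest.approx(np.quantile(g[:, 2], 0.025), rel=1e-9)


class TestSampler:
    def small(self, seed=3):
        return m.MCMCConfig(
            n_chains=2,
            n_keep_total=400,
            min_burn_in=300,
            max_burn_in=900,
            check_every=300,
            seed=seed,
        )

    def test_identical_seed_gives_bit_identical_chains(self, male_low_counts):
        spec = m.APCModelSpec(grid=male_low_counts.grid)
        a = m.sample_posterior(male_low_counts, spec, self.small())
        b = m.sample_posterior(male_low_counts, spec, self.small())
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert a.burn_in_used == b.burn_in_used

    def test_every_retained_draw_satisfies_constraints(self, male_low_posterior):
        spec = male_low_posterior.spec
        r1, r2 = spec.ref_period_indices
        beta = male_low_posterior.beta_draws()
        gamma = male_low_posterior.gamma_draws()
        alpha = male_low_posterior.alpha_draws()
        assert np.allclose(beta[:, r1 - 1], 0.0, atol=1e-9)
        assert np.allclose(beta[:, r2 - 1], 0.0, atol=1e-9)
        assert np.allclose(gamma[:, spec.ref_cohort_index - 1], 0.0, atol=1e-9)
        assert np.allclose(alpha.mean(axis=1), 0.0, atol=1e-9)

    def test_chain_layout_covers_the_draw_budget(self, male_low_posterior):
        post = male_low_posterior
        assert post.n_chains * post.n_kept >= post.mcmc.n_keep_total

    def test_flat_signal_rr_intervals_cover_one(self, grid):
        rng = np.random.default_rng(42)
        py = np.full((grid.n_age, grid.n_period), 2e5)
        deaths = rng.poisson(py * 5e-4)
        counts = m.StratumCounts(grid, "female", "high", deaths, py)
        post = m.sample_posterior(
            counts, m.APCModelSpec(grid=grid), self.small(seed=9)
        )
        rr = m.relative_risks(post)
        free = rr[~rr.is_reference]
        assert np.all(free.lo95 <= 1.0) and np.all(free.hi95 >= 1.0)

    def test_convergence_failure_is_explicit(self, male_low_counts):
        mc = m.MCMCConfig(
            n_chains=2,
            n_keep_total=100,
            min_burn_in=100,
            max_burn_in=100,
            check_every=100,
            rhat_threshold=1.0000001,  # unattainable
            seed=1,
        )
        post = m.sample_posterior(
            male_low_counts, m.APCModelSpec(grid=male_low_counts.grid), mc
        )
        assert post.converged is False
        assert post.burn_in_used == 100


class TestPersistence:
    def test_save_load_round_trip(self, male_low_posterior, tmp_path):
        draws = tmp_path / "draws.csv"
        meta = tmp_path / "meta.json"
        m.apc.save_posterior(male_low_posterior, draws, meta)
        back = m.apc.load_posterior(draws, meta)
        assert np.allclose(back.gamma, male_low_posterior.gamma)
        assert np.allclose(back.deviance, male_low_posterior.deviance)
        assert back.spec.grid == male_low_posterior.spec.grid
        assert back.converged == male_low_posterior.converged


def test_penalty_matrix_matches_quadratic_form(rng):
    for k in (3, 7, 15):
        Q = _penalty_matrix(k)
        e = rng.normal(0, 1, k)
        assert e @ Q @ e == pytest.approx(np.sum(np.diff(e, n=2) ** 2), rel=1e-12)
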