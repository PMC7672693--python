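import numpy as np
import pytest
from scipy import stats

from dynherit import (
    MaternKernel,
    PhenotypePanel,
    RelationshipMatrix,
    TimeGrid,
    WhitenedState,
    breeding_values,
    cov_matrix,
    cov_sqrt,
    eigendecompose_grm,
    lengthscale_hyperprior,
    log_posterior,
    run_joint_mcmc,
    simulate_longitudinal,
    summarize,
)
from dynherit.joint_model import PosteriorDraws, split_chain_check
from tests.conftest import random_psd


@pytest.fixture(scope="module")
def sim_small():
    grid = TimeGrid(np.arange(1.0, 11.0))
    panel, truth = simulate_longitudinal(
        150, grid, np.full(10, 1.0), np.full(10, 1.0), seed=11
    )
    return panel, truth


class TestLogPosterior:
    def test_zero_eta_gives_unit_curves(self, rng):
        n, t = 4, 3
        g = random_psd(n, rng)
        y = rng.standard_normal((n, t))
        eig = eigendecompose_grm(g)
        z = eig.U.T @ y
        grid = TimeGrid(np.array([0.0, 1.0, 3.0]))
        hyper = lengthscale_hyperprior(grid)
        state = WhitenedState(np.zeros(t), np.zeros(t), hyper[0], hyper[0])
        lp = log_posterior(state, z, eig.xi, grid, hyper)
        # likelihood term with unit curves
        from dynherit import VarianceCurves, joint_loglik

        ll = joint_loglik(z, eig.xi, VarianceCurves(np.ones(t), np.ones(t)))
        prior = -t * np.log(2 * np.pi) + 2 * stats.norm.logpdf(hyper[0], *hyper)
        assert lp == pytest.approx(ll + prior, abs=1e-10)

    def test_matches_dense_oracle(self, rng):
        # monolithic evaluation: dense per-time-point MVN + exact priors
        n, t = 4, 3
        g = random_psd(n, rng)
        y = rng.standard_normal((n, t))
        grid = TimeGrid(np.array([0.0, 1.0, 2.5]))
        hyper = lengthscale_hyperprior(grid)
        eta_g = rng.standard_normal(t)
        eta_e = rng.standard_normal(t)
        llam_g, llam_e = 0.3, -0.2
        state = WhitenedState(eta_g, eta_e, llam_g, llam_e)
        eig = eigendecompose_grm(g)
        got = log_posterior(state, eig.U.T @ y, eig.xi, grid, hyper)

        sg = np.exp(cov_sqrt(cov_matrix(grid, MaternKernel(lengthscale=np.exp(llam_g)))) @ eta_g)
        se = np.exp(cov_sqrt(cov_matrix(grid, MaternKernel(lengthscale=np.exp(llam_e)))) @ eta_e)
        dense = sum(
            stats.multivariate_normal.logpdf(
                y[:, i], np.zeros(n), sg[i] * g + se[i] * np.eye(n)
            )
            for i in range(t)
        )
        dense += stats.multivariate_normal.logpdf(eta_g, np.zeros(t), np.eye(t))
        dense += stats.multivariate_normal.logpdf(eta_e, np.zeros(t), np.eye(t))
        dense += stats.norm.logpdf(llam_g, *hyper) + stats.norm.logpdf(llam_e, *hyper)
        assert got == pytest.approx(dense, abs=1e-8)

    def test_lambda_change_only_affects_likelihood_and_its_prior(self, rng):
        n, t = 3, 3
        g = np.eye(n)
        y = rng.standard_normal((n, t))
        grid = TimeGrid(np.array([0.0, 1.0, 3.0]))
        hyper = lengthscale_hyperprior(grid)
        eta = rng.standard_normal(t)
        eig = eigendecompose_grm(g)
        z = eig.U.T @ y
        s1 = WhitenedState(eta, np.zeros(t), 0.0, 0.0)
        s2 = WhitenedState(eta, np.zeros(t), 0.5, 0.0)
        lp1 = log_posterior(s1, z, eig.xi, grid, hyper)
        lp2 = log_posterior(s2, z, eig.xi, grid, hyper)
        # eta_E = 0 so sigma2_E stays all-ones; the difference comes only from
        # the sigma2_G curve (through C^{1/2}) and the lambda_G prior.
        assert lp1 != lp2
        # with eta_G = 0 as well nothing changes but the prior
        s3 = WhitenedState(np.zeros(t), np.zeros(t), 0.0, 0.0)
        s4 = WhitenedState(np.zeros(t), np.zeros(t), 0.5, 0.0)
        lp3 = log_posterior(s3, z, eig.xi, grid, hyper)
        lp4 = log_posterior(s4, z, eig.xi, grid, hyper)
        delta_prior = stats.norm.logpdf(0.5, *hyper) - stats.norm.logpdf(0.0, *hyper)
        assert lp4 - lp3 == pytest.approx(delta_prior, abs=1e-10)


class TestRunJointMCMC:
    def test_seed_reproducibility(self, sim_small):
        panel, truth = sim_small
        a = run_joint_mcmc(panel, truth.G_true, iterations=200, burnin=100, thin=2, seed=5)
        b = run_joint_mcmc(panel, truth.G_true, iterations=200, burnin=100, thin=2, seed=5)
        np.testing.assert_array_equal(a.sigma2_G, b.sigma2_G)
        np.testing.assert_array_equal(a.lambda_G, b.lambda_G)

    def test_id_mismatch_errors(self, sim_small):
        panel, truth = sim_small
        bad = RelationshipMatrix(truth.G_true.values, list(truth.G_true.individual_ids[::-1]))
        with pytest.raises(ValueError, match="ID"):
            run_joint_mcmc(panel, bad, iterations=10, burnin=0, seed=1)

    def test_too_few_iterations_errors(self, sim_small):
        panel, truth = sim_small
        with pytest.raises(ValueError, match="iterations"):
            run_joint_mcmc(panel, truth.G_true, iterations=10, burnin=10, seed=1)

    def test_seed_required(self, sim_small):
        panel, truth = sim_small
        with pytest.raises(ValueError, match="seed"):
            run_joint_mcmc(panel, truth.G_true, iterations=10, burnin=0)

    def test_draw_count_and_shapes(self, sim_small):
        panel, truth = sim_small
        draws = run_joint_mcmc(panel, truth.G_true, iterations=300, burnin=100, thin=10, seed=3)
        assert draws.n_draws == 20
        assert draws.sigma2_G.shape == (20, panel.n_timepoints)
        assert np.all(draws.sigma2_G > 0) and np.all(draws.sigma2_E > 0)
        assert np.all((draws.h2 > 0) & (draws.h2 < 1))

    def test_cov_sqrt_cached_between_lambda_changes(self, sim_small):
        # one factorization per proposed lambda plus the initial one; the ESS
        # updates (which dominate likelihood evaluations) trigger none.
        panel, truth = sim_small
        iters = 150
        draws = run_joint_mcmc(panel, truth.G_true, iterations=iters, burnin=50, seed=4)
        for key in ("n_cov_sqrt_G", "n_cov_sqrt_E"):
            assert 1 <= draws.meta[key] <= iters + 1

    def test_scale_invariance_of_h2_bitwise(self, sim_small):
        panel, truth = sim_small
        scaled_panel = PhenotypePanel(
            panel.values * 4.0, panel.grid, list(panel.individual_ids)
        )
        a = run_joint_mcmc(panel, truth.G_true, iterations=300, burnin=100, seed=9)
        b = run_joint_mcmc(scaled_panel, truth.G_true, iterations=300, burnin=100, seed=9)
        np.testing.assert_array_equal(a.h2, b.h2)
        np.testing.assert_array_equal(a.sigma2_G, b.sigma2_G)  # analysis scale
        assert b.meta["scale_factor"] == a.meta["scale_factor"] / 16.0

    def test_recovers_constant_h2(self, sim_small):
        # moderate-size recovery check; the full-scale version is an
        # acceptance criterion.
        panel, truth = sim_small
        draws = run_joint_mcmc(panel, truth.G_true, iterations=4000, seed=17)
        h2_mean = draws.h2.mean(axis=0)
        assert np.mean(np.abs(h2_mean - 0.5) <= 0.2) >= 0.8

    def test_lambda_chains_pass_stationarity_check(self, sim_small):
        panel, truth = sim_small
        draws = run_joint_mcmc(panel, truth.G_true, iterations=6000, thin=2, seed=21)
        ok_g, z_g = split_chain_check(draws.lambda_G)
        ok_e, z_e = split_chain_check(draws.lambda_E)
        assert ok_g, f"lambda_G split-chain z-score {z_g:.2f}"
        assert ok_e, f"lambda_E split-chain z-score {z_e:.2f}"


class TestSummarize:
    def test_identical_draws_zero_width(self):
        arr = np.tile([[1.0, 2.0]], (5, 1))
        draws = PosteriorDraws(arr, arr, arr / (arr + arr), np.ones(5), np.ones(5), {})
        sg, se, h2 = summarize(draws)
        np.testing.assert_allclose(sg.lower95, sg.mean)
        np.testing.assert_allclose(sg.upper95, sg.mean)

    def test_two_draw_mean(self):
        sg = np.array([[0.2], [0.4]])
        draws = PosteriorDraws(sg, sg, sg, np.ones(2), np.ones(2), {})
        s, _, _ = summarize(draws)
        assert s.mean[0] == pytest.approx(0.3)

    def test_quantiles_match_sort_oracle(self, rng):
        s = 1001
        arr = rng.gamma(2.0, 1.0, size=(s, 3))
        draws = PosteriorDraws(arr, arr, arr / (arr + arr), np.ones(s), np.ones(s), {})
        sg, _, _ = summarize(draws)
        for t in range(3):
            srt = np.sort(arr[:, t])
            lo = np.quantile(srt, 0.025)
            hi = np.quantile(srt, 0.975)
            assert sg.lower95[t] == pytest.approx(lo, rel=1e-12)
            assert sg.upper95[t] == pytest.approx(hi, rel=1e-12)

    def test_band_ordering(self, rng):
        arr = rng.gamma(2.0, 1.0, size=(500, 4))
        arr2 = rng.gamma(2.0, 1.0, size=(500, 4))
        draws = PosteriorDraws(arr, arr2, arr / (arr + arr2), np.ones(500), np.ones(500), {})
        for s in summarize(draws):
            assert np.all(s.lower95 <= s.mean) and np.all(s.mean <= s.upper95)

    def test_empty_draws_error(self):
        arr = np.empty((0, 2))
        draws = PosteriorDraws(arr, arr, arr, np.empty(0), np.empty(0), {})
        with pytest.raises(ValueError):
            summarize(draws)

    def test_original_scale(self):
        arr = np.full((4, 2), 2.0)
        draws = PosteriorDraws(
            arr, arr, arr / (arr + arr), np.ones(4), np.ones(4), {"scale_factor": 2.0}
        )
        sg, _, _ = summarize(draws, scale="original")
        np.testing.assert_allclose(sg.mean, 1.0)


class TestBreedingValues:
    def test_identity_grm_scalar_shrinkage(self, rng):
        y = rng.standard_normal(6)
        mu, cov = breeding_values(RelationshipMatrix(np.eye(6)), 1.5, 0.5, y)
        np.testing.assert_allclose(mu, (1.5 / 2.0) * y, atol=1e-12)

    def test_matches_dense_solve(self, rng):
        g = random_psd(5, rng)
        y = rng.standard_normal(5)
        sg, se = 0.8, 1.3
        mu, cov = breeding_values(RelationshipMatrix(g), sg, se, y)
        k = sg * g + se * np.eye(5)
        mu_dense = sg * g @ np.linalg.solve(k, y)
        cov_dense = sg * g - sg * g @ np.linalg.solve(k, sg * g)
        np.testing.assert_allclose(mu, mu_dense, atol=1e-10)
        np.testing.assert_allclose(cov, cov_dense, atol=1e-10)

    def test_vanishing_genetic_variance_limit(self, rng):
        g = random_psd(4, rng)
        y = rng.standard_normal(4)
        mu, cov = breeding_values(RelationshipMatrix(g), 1e-12, 1.0, y)
        np.testing.assert_allclose(mu, 0.0, atol=1e-9)
        np.testing.assert_allclose(cov, 0.0, atol=1e-9)

    def test_nonpositive_variance_errors(self, rng):
        g = RelationshipMatrix(np.eye(3))
        with pytest.raises(ValueError):
            breeding_values(g, 0.0, 1.0, np.zeros(3))
        with pytest.raises(ValueError):
            breeding_values(g, 1.0, -1.0, np.zeros(3))
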