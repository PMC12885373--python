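"""Collapsed posterior, Laplace fit, and conjugate uncollapse."""

import numpy as np
import pytest
from scipy import linalg, stats
from scipy.special import logsumexp

from ampbias.compositions import make_contrast_matrix
from ampbias.inference import (
    _CollapsedModel,
    collapsed_log_posterior,
    collapsed_prior_logpdf,
    default_prior,
    extract_alpha_beta,
    fit_mln,
    summarize_posterior,
)
from ampbias.synthetic import (
    CountMatrix,
    SimulationTruth,
    make_design,
    mock_community_study,
    simulate_counts,
)


class TestCollapsedLogPosterior:
    def test_matches_monte_carlo_marginalization(self):
        """Matrix-t marginal equals brute-force MC integration over (Lambda, Sigma)."""
        design = make_design(["C1", "C1"], [0, 35])  # D=2, N=2, p=2
        prior = default_prior(2, 2, gamma_scale=1.0)  # tight prior keeps MC weights stable
        eta = np.array([[0.4, -0.3]])
        lp = collapsed_prior_logpdf(eta, design, prior)

        rng = np.random.default_rng(1)
        M = 200_000
        X = design.X
        sigmas = stats.invwishart.rvs(df=prior.upsilon0, scale=prior.xi0, size=M, random_state=rng)
        lams = rng.standard_normal((M, 2)) * np.sqrt(sigmas)[:, None]  # theta0=0, gamma0=I
        means = lams @ X  # (M, 2)
        resid = eta.ravel()[None, :] - means
        logs = (
            -0.5 * (resid**2).sum(axis=1) / sigmas
            - np.log(2 * np.pi * sigmas)
        )
        mc = logsumexp(logs) - np.log(M)
        se = np.std(np.exp(logs - mc)) / np.sqrt(M)  # relative MC error
        assert lp == pytest.approx(mc, abs=max(5 * se, 0.01))

    def test_likelihood_improves_toward_observed_log_ratio(self):
        # 1-sample, 2-taxon toy: the multinomial term peaks at the count log odds
        counts = CountMatrix(np.array([[30], [10]]), ["a", "b"], ["s"])
        design = make_design(["C"], [0])
        psi = make_contrast_matrix("alr", 2)
        prior = default_prior(2, 2)
        model = _CollapsedModel(counts.counts, design.X, prior, psi)
        target = np.log(30 / 10)
        grid = np.linspace(-2.0, target, 25)
        vals = [model.multinomial(np.array([[g]])) for g in grid]
        assert np.all(np.diff(vals) > 0)  # monotone improvement toward the MLE

    def test_sample_permutation_invariance(self):
        study = mock_community_study(seed=2, n_taxa=4, n_communities=2, depth=500)
        rng = np.random.default_rng(0)
        eta = rng.standard_normal((3, study.counts.N))
        lp = collapsed_log_posterior(eta, study.counts, study.design, psi=study.psi)
        perm = rng.permutation(study.counts.N)
        counts_p = CountMatrix(
            study.counts.counts[:, perm],
            study.counts.taxon_ids,
            [study.counts.sample_ids[i] for i in perm],
        )
        from ampbias.synthetic import DesignMatrix

        design_p = DesignMatrix(
            study.design.X[:, perm], study.design.covariate_names, study.design.cycle_row
        )
        lp_p = collapsed_log_posterior(eta[:, perm], counts_p, design_p, psi=study.psi)
        assert lp == pytest.approx(lp_p, abs=1e-8)

    def test_gradient_and_hessian_match_finite_differences(self):
        study = mock_community_study(seed=3, n_taxa=4, n_communities=2, cycles=(20, 35), depth=500)
        model = _CollapsedModel(
            study.counts.counts, study.design.X, default_prior(4, 3), study.psi
        )
        rng = np.random.default_rng(0)
        eta = rng.standard_normal((3, study.counts.N))
        eps = 1e-6
        g = model.grad(eta)
        H = model.hessian(eta)
        gfd = np.zeros_like(eta)
        for i in range(eta.shape[0]):
            for n in range(eta.shape[1]):
                e1, e2 = eta.copy(), eta.copy()
                e1[i, n] += eps
                e2[i, n] -= eps
                gfd[i, n] = (model.value(e1) - model.value(e2)) / (2 * eps)
        assert np.max(np.abs(g - gfd)) < 1e-4
        k = eta.size
        Hfd = np.zeros((k, k))
        for j in range(k):
            i, n = j % 3, j // 3
            e1, e2 = eta.copy(), eta.copy()
            e1[i, n] += eps
            e2[i, n] -= eps
            Hfd[:, j] = ((model.grad(e1) - model.grad(e2)) / (2 * eps)).flatten(order="F")
        assert np.max(np.abs(H - Hfd)) < 1e-4


class TestMetropolisOracle:
    def test_posterior_means_match_long_mcmc(self):
        """Laplace+uncollapse Lambda means vs Metropolis on the same collapsed posterior."""
        study = mock_community_study(
            seed=5, n_taxa=3, n_communities=1, cycles=(0, 17, 35), depth=800,
            noise_free=False,
        )
        counts, design, psi = study.counts, study.design, study.psi
        assert counts.N == 3 and design.p == 2
        prior = default_prior(3, 2)
        model = _CollapsedModel(counts.counts, design.X, prior, psi)
        draws = fit_mln(counts, design, prior=prior, psi=psi, n_draws=4000, seed=5)
        lam_mean = draws.lambda_draws.mean(axis=0)

        # random-walk Metropolis over eta, proposal scaled by the Laplace sd
        H = model.hessian(draws.eta_mode)
        prop_sd = np.sqrt(np.diag(linalg.inv(-(H + H.T) / 2))).reshape(
            draws.eta_mode.shape, order="F"
        )
        rng = np.random.default_rng(99)
        eta = draws.eta_mode.copy()
        cur = model.value(eta)
        n_iter, burn, thin = 60_000, 10_000, 10
        kept = []
        for it in range(n_iter):
            prop = eta + 1.2 * prop_sd * rng.standard_normal(eta.shape)
            val = model.value(prop)
            if np.log(rng.random()) < val - cur:
                eta, cur = prop, val
            if it >= burn and it % thin == 0:
                kept.append(eta.copy())
        kept = np.array(kept)
        # conjugate posterior mean of Lambda given eta: Theta_N(eta)
        X = design.X
        gamma_N = linalg.inv(linalg.inv(prior.gamma0) + X @ X.T)
        theta_mc = np.array([e @ X.T @ gamma_N for e in kept])
        mc_mean = theta_mc.mean(axis=0)
        # batch-means MC standard error
        nb = 20
        batches = np.array_split(theta_mc, nb)
        bm = np.array([b.mean(axis=0) for b in batches])
        mc_se = bm.std(axis=0, ddof=1) / np.sqrt(nb)
        laplace_se = draws.lambda_draws.std(axis=0, ddof=1) / np.sqrt(draws.S)
        tol = 3 * np.sqrt(mc_se**2 + laplace_se**2) + 0.02
        assert np.all(np.abs(lam_mean - mc_mean) < tol)


class TestFitMln:
    def test_parameter_recovery(self, small_study, small_fit):
        _, beta_d = extract_alpha_beta(small_fit, small_study.design.communities[0])
        r = np.corrcoef(beta_d.mean(axis=0), small_study.beta_true)[0, 1]
        assert r > 0.9

    def test_alpha_recovery_noise_free_high_depth(self):
        study = mock_community_study(
            seed=21, n_taxa=5, n_communities=3, depth=1_000_000,
            cycles=(0, 7, 14, 21, 28, 35), noise_free=True,
        )
        draws = fit_mln(study.counts, study.design, psi=study.psi, n_draws=200, seed=21)
        for name in study.design.communities:
            a_d, _ = extract_alpha_beta(draws, name)
            assert np.max(np.abs(a_d.mean(axis=0) - study.alpha_true[name])) < 0.05

    def test_mode_independent_of_draw_count(self, small_study):
        s = small_study
        d1 = fit_mln(s.counts, s.design, psi=s.psi, n_draws=1, seed=0)
        d2 = fit_mln(s.counts, s.design, psi=s.psi, n_draws=50, seed=123)
        assert np.allclose(d1.eta_mode, d2.eta_mode, atol=1e-10)

    def test_seed_determinism(self, small_study):
        s = small_study
        d1 = fit_mln(s.counts, s.design, psi=s.psi, n_draws=20, seed=4)
        d2 = fit_mln(s.counts, s.design, psi=s.psi, n_draws=20, seed=4)
        assert np.array_equal(d1.lambda_draws, d2.lambda_draws)

    def test_posterior_contraction_with_more_data(self):
        base = mock_community_study(seed=8, n_taxa=4, n_communities=3, depth=1000)
        more = mock_community_study(
            seed=8, n_taxa=4, n_communities=3, depth=2000,
            cycles=(20, 24, 28, 31, 35, 18),
        )
        db = fit_mln(base.counts, base.design, psi=base.psi, n_draws=400, seed=8)
        dm = fit_mln(more.counts, more.design, psi=more.psi, n_draws=400, seed=8)
        sd_base = db.lambda_draws[:, :, db.cycle_row].std(axis=0).mean()
        sd_more = dm.lambda_draws[:, :, dm.cycle_row].std(axis=0).mean()
        assert sd_more < sd_base

    def test_rank_deficient_design_rejected(self, small_study):
        from ampbias.synthetic import DesignMatrix

        s = small_study
        X = s.design.X.copy()
        X[s.design.cycle_row] = 0.0  # cycle row now in the span of the indicators
        bad = DesignMatrix(X, s.design.covariate_names, s.design.cycle_row)
        with pytest.raises(ValueError, match="rank"):
            fit_mln(s.counts, bad, psi=s.psi, n_draws=10, seed=0)

    def test_sigma_draws_positive_definite(self, small_fit):
        for s in range(0, small_fit.S, 37):
            np.linalg.cholesky(small_fit.sigma_draws[s])


class TestExtractAlphaBeta:
    def test_layout_contract(self, small_fit):
        comms = small_fit.communities
        a1, b1 = extract_alpha_beta(small_fit, comms[0])
        a2, b2 = extract_alpha_beta(small_fit, comms[1])
        assert np.array_equal(b1, b2)  # shared bias column
        assert not np.allclose(a1, a2)  # per-community baselines differ

    def test_round_trip_reassembly(self, small_fit):
        cols = []
        for i, name in enumerate(small_fit.covariate_names):
            if i == small_fit.cycle_row:
                cols.append(small_fit.lambda_draws[:, :, small_fit.cycle_row])
            else:
                cols.append(extract_alpha_beta(small_fit, name)[0])
        rebuilt = np.stack(cols, axis=2)
        assert np.array_equal(rebuilt, small_fit.lambda_draws)

    def test_unknown_community_rejected(self, small_fit):
        with pytest.raises(ValueError, match="unknown"):
            extract_alpha_beta(small_fit, "no_such_community")


def test_summary_frame_shape(small_fit):
    df = summarize_posterior(small_fit)
    assert set(df.columns) == {"covariate", "contrast", "mean", "sd", "p2.5", "p50", "p97.5"}
    assert len(df) == len(small_fit.covariate_names) * small_fit.lambda_draws.shape[1]
    assert np.all(df["p2.5"] <= df["p50"]) and np.all(df["p50"] <= df["p97.5"])
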