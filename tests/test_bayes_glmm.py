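"""Model assembly, log-posterior correctness, sampler behaviour and
convergence diagnostics for the phylogenetic binomial mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import binom, chisquare, kstest, multivariate_normal
from scipy.stats import t as tdist

from aposcore import bayes_glmm as bg
from aposcore import detectability as det
from aposcore import game_ingest as gi
from aposcore import phylo_cov as pc
from aposcore import synthetic_data as sd


def _identity_corr(n):
    return pc.PhyloCorrelation([f"s{i:02d}" for i in range(n)], np.eye(n))


def _make_data(rng, n_species=8, n_assays=5, beta=(-1.0, 0.3), sigma=0.7):
    data, _ = sd.simulate_model_dataset(
        n_species, n_assays, beta=np.asarray(beta), sigma_phylo=sigma,
        seed=int(rng.integers(2**31)),
    )
    return data


def _ref_log_posterior(beta, sigma, u, data):
    """Independent density oracle built from scipy distributions."""
    eta = data.X @ beta + u[data.species_idx]
    ll = binom.logpmf(data.y.astype(int), data.n.astype(int), expit(eta)).sum()
    lu = multivariate_normal.logpdf(
        u, mean=np.zeros(len(u)), cov=sigma**2 * data.C.matrix,
        allow_singular=True,
    )
    ls = np.log(2) + tdist.logpdf(sigma / 2.5, 3) - np.log(2.5)
    return ll + lu + ls


class TestLogPosterior:
    def test_single_assay_closed_form(self):
        data = bg.ModelData(
            y=[5], n=[10], species_idx=[0], X=np.ones((1, 1)),
            predictor_names=["Intercept"], species=["s00"], C=_identity_corr(1),
        )
        got = bg.log_posterior(np.zeros(1), 1.0, np.zeros(1), data)
        binom_term = np.log(252) + 10 * np.log(0.5)
        mvn_term = -0.5 * np.log(2 * np.pi)
        sigma_term = np.log(2) + tdist.logpdf(1 / 2.5, 3) - np.log(2.5)
        assert got == pytest.approx(binom_term + mvn_term + sigma_term, abs=1e-10)

    def test_matches_reference_at_random_points(self, rng):
        data = _make_data(rng)
        for _ in range(5):
            beta = rng.normal(0, 1, size=data.p)
            sigma = float(rng.uniform(0.2, 2.0))
            u = rng.normal(0, 1, size=data.n_species)
            assert bg.log_posterior(beta, sigma, u, data) == pytest.approx(
                _ref_log_posterior(beta, sigma, u, data), abs=1e-8
            )

    def test_row_permutation_invariance(self, rng):
        data = _make_data(rng)
        perm = rng.permutation(data.n_assays)
        shuffled = bg.ModelData(
            y=data.y[perm], n=data.n[perm], species_idx=data.species_idx[perm],
            X=data.X[perm], predictor_names=data.predictor_names,
            species=data.species, C=data.C,
        )
        beta = rng.normal(size=data.p)
        u = rng.normal(size=data.n_species)
        assert bg.log_posterior(beta, 0.9, u, data) == pytest.approx(
            bg.log_posterior(beta, 0.9, u, shuffled), abs=1e-10
        )

    def test_sigma_prior_finite_at_origin(self):
        assert np.isfinite(bg.half_t_logpdf(0.0))
        assert bg.half_t_logpdf(-0.1) == -np.inf

    def test_nonpositive_sigma_rejected(self, rng):
        data = _make_data(rng)
        with pytest.raises(ValueError):
            bg.log_posterior(np.zeros(data.p), 0.0, np.zeros(data.n_species), data)


class TestBuildModelData:
    def test_shapes_from_pipeline_tables(self, small_dataset):
        table = det.mean_times(gi.apply_censoring(small_dataset.rounds))
        preds = det.species_predictors(table, small_dataset.truth.images)
        for model, p in ((1, 3), (2, 2)):
            data = bg.build_model_data(
                preds, small_dataset.assays_model1,
                small_dataset.truth.correlation, model=model,
            )
            b = small_dataset.assays_model1.query("category == 'butterfly'")
            assert data.X.shape == (len(b), p)
            assert data.n_species == small_dataset.config.n_species

    def test_species_missing_from_tree_named(self, small_dataset):
        table = det.mean_times(gi.apply_censoring(small_dataset.rounds))
        preds = det.species_predictors(table, small_dataset.truth.images)
        corr = small_dataset.truth.correlation
        trimmed = corr.reorder(corr.species[:-1])
        with pytest.raises(KeyError, match=corr.species[-1]):
            bg.build_model_data(preds, small_dataset.assays_model1, trimmed, model=1)

    def test_collinear_predictors_warned(self, rng):
        n = 10
        z = det.zscore(rng.normal(size=n))
        scores = pd.DataFrame(
            {"z_dorsal": z, "z_ventral": z, "z_diff": z},
            index=[f"s{i:02d}" for i in range(n)],
        )
        assays = pd.DataFrame({
            "subject_id": scores.index, "category": "butterfly",
            "n_daphnia": 10, "deaths": 1,
        })
        with pytest.warns(UserWarning, match="collinear"):
            bg.build_model_data(scores, assays, _identity_corr(n), model=1)


class TestSampler:
    def test_same_seed_identical_draws(self, rng):
        data = _make_data(rng)
        a = bg.sample_posterior(data, chains=2, iter=400, warmup=200, seed=9)
        b = bg.sample_posterior(data, chains=2, iter=400, warmup=200, seed=9)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma, b.sigma)
        assert np.array_equal(a.u, b.u)

    def test_sigma_positive_in_every_draw(self, rng):
        data = _make_data(rng)
        draws = bg.sample_posterior(data, chains=2, iter=400, warmup=200, seed=3)
        assert (draws.sigma > 0).all()

    def test_prior_only_recovers_half_t_marginal(self):
        draws = bg.sample_posterior(
            None, prior_only=True, chains=4, iter=30000, warmup=2000, seed=12,
        )
        # thin hard: the KS test assumes (near-)independent samples
        sigma = draws.sigma.reshape(-1)[::28][:4000]

        def half_t_cdf(x):
            return 2 * (tdist.cdf(np.asarray(x) / 2.5, 3) - 0.5)

        assert kstest(sigma, half_t_cdf).pvalue > 0.01

    def test_laplace_oracle_agreement_without_phylogeny(self):
        """With C = I the fit must match an independently coded Laplace
        approximation of the same binomial GLMM."""
        rng = np.random.default_rng(77)
        S, n_per, beta_true, sigma_true = 30, 20, np.array([-1.0, 0.5]), 0.8
        corr = _identity_corr(S)
        x = det.zscore(rng.normal(size=S))
        u = sigma_true * rng.normal(size=S)
        sp = np.repeat(np.arange(S), n_per)
        Xs = np.column_stack([np.ones(S), x])
        y = rng.binomial(10, expit(Xs @ beta_true + u)[sp])
        data = bg.ModelData(
            y=y, n=np.full(len(y), 10), species_idx=sp, X=Xs[sp],
            predictor_names=["Intercept", "x"], species=corr.species, C=corr,
        )
        draws = bg.sample_posterior(data, chains=4, iter=3000, warmup=1000, seed=5)
        post_mean = draws.stacked()["beta"].mean(axis=0)
        lap = _laplace_beta_mean(data, np.linspace(0.3, 1.8, 25))
        np.testing.assert_allclose(post_mean, lap, atol=0.05)

    def test_simulation_based_calibration(self):
        """Rank statistics of true parameters within posterior draws are
        uniform on a scaled-down design (20 species, 4 assays)."""
        n_rep, S, n_per, n_bins = 80, 20, 4, 8
        counts = {k: np.zeros(n_bins) for k in ("beta0", "beta1", "sigma")}
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            corr = pc.correlation_matrix(
                pc.read_newick(sd.simulate_tree(S, seed=int(rng.integers(2**31))))
            )
            beta = rng.normal(0, 1, size=2)
            sigma = float(np.abs(tdist.rvs(3, random_state=rng)))  # scale 1 prior
            x = det.zscore(rng.normal(size=S))
            u = sd.draw_species_effects(corr, sigma, rng)
            Xs = np.column_stack([np.ones(S), x])
            sp = np.repeat(np.arange(S), n_per)
            y = rng.binomial(10, expit(Xs @ beta + u)[sp])
            data = bg.ModelData(
                y=y, n=np.full(len(y), 10), species_idx=sp, X=Xs[sp],
                predictor_names=["Intercept", "x"], species=corr.species, C=corr,
            )
            draws = bg.sample_posterior(
                data, chains=1, iter=980, warmup=350, seed=rep,
                beta_prior_sd=1.0, sigma_scale=1.0,
            )
            kept = {
                "beta0": draws.beta[0, ::10, 0][:63],
                "beta1": draws.beta[0, ::10, 1][:63],
                "sigma": draws.sigma[0, ::10][:63],
            }
            truths = {"beta0": beta[0], "beta1": beta[1], "sigma": sigma}
            for k in counts:
                rank = int(np.sum(kept[k] < truths[k]))
                counts[k][rank * n_bins // (len(kept[k]) + 1)] += 1
        for k, c in counts.items():
            assert chisquare(c).pvalue > 0.01, f"{k} ranks non-uniform: {c}"


def _laplace_beta_mean(data, sigmas):
    """Posterior mean of beta via per-sigma Laplace approximation and grid
    integration over sigma (independent of the MCMC code path)."""
    n, S, p = data.n_assays, data.n_species, data.p
    Z = np.zeros((n, S))
    Z[np.arange(n), data.species_idx] = 1.0
    Xf = np.hstack([data.X, Z])

    def mode(sigma):
        def f(theta):
            eta = Xf @ theta
            pen = 0.5 * theta[p:] @ theta[p:] / sigma**2
            return -(data.y @ eta - data.n @ np.logaddexp(0, eta)) + pen

        def grad(theta):
            mu = data.n * expit(Xf @ theta)
            g = Xf.T @ (mu - data.y)
            g[p:] += theta[p:] / sigma**2
            return g

        res = minimize(f, np.zeros(p + S), jac=grad, method="L-BFGS-B",
                       options={"maxiter": 500})
        mu = expit(Xf @ res.x)
        W = data.n * mu * (1 - mu)
        H = (Xf.T * W) @ Xf
        H[p:, p:] += np.eye(S) / sigma**2
        return res.x, -res.fun, H

    log_w, betas = [], []
    for s in sigmas:
        theta, lp, H = mode(s)
        _, logdet = np.linalg.slogdet(H)
        log_w.append(
            lp - S * np.log(s) - 0.5 * logdet + float(bg.half_t_logpdf(s))
        )
        betas.append(theta[:p])
    w = np.exp(np.array(log_w) - max(log_w))
    w /= w.sum()
    return (w[:, None] * np.array(betas)).sum(axis=0)


class TestDiagnosticsAndSummary:
    def _draws(self, beta_chains):
        arr = np.asarray(beta_chains, dtype=float)[:, :, None]
        c, d, _ = arr.shape
        return bg.PosteriorDraws(
            beta=arr, sigma=np.ones((c, d)), u=np.zeros((c, d, 1)),
            predictor_names=["Intercept"], species=["s00"], sigma_sampled=False,
        )

    def test_diagnose_requires_chains_and_draws(self, rng):
        with pytest.raises(ValueError, match="chains"):
            bg.diagnose(self._draws(rng.normal(size=(1, 500))))
        with pytest.raises(ValueError, match="draws"):
            bg.diagnose(self._draws(rng.normal(size=(4, 50))))

    def test_summary_mean_of_enumerated_draws(self):
        draws = self._draws(np.arange(1.0, 101.0).reshape(2, 50))
        s = bg.summarize(draws)
        assert s.loc[0, "Estimate"] == pytest.approx(50.5)

    def test_significance_follows_interval(self, rng):
        sym = self._draws(rng.normal(0, 1, size=(2, 400)))
        assert not bg.summarize(sym)["significant"].iloc[0]
        pos = self._draws(rng.uniform(0.5, 1.5, size=(2, 400)))
        assert bg.summarize(pos)["significant"].iloc[0]

    def test_rhat_warning_on_disjoint_chains(self, rng):
        chains = rng.normal(0, 1, size=(4, 200))
        chains[0] += 5.0
        with pytest.warns(UserWarning, match="R-hat"):
            bg.diagnose(self._draws(chains))
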