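"""Censored likelihood, posterior sampler, and summaries.

The likelihood is checked against direct numerical integration; the
Gibbs sampler (data augmentation) is cross-checked against an emcee fit
of the very same posterior written with the closed-form tail-probability
likelihood — two independent routes to one distribution.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from empabayes import censored_model as cm
from empabayes import synthetic_data as sd


def _tiny_dataset(rng, n_subjects=4, n_per=8, censor=True):
    rows = []
    for i in range(n_subjects):
        mu = 50 + 10 * rng.standard_normal()
        for j in range(n_per):
            intensity = 1 if j % 2 else -1
            session = 1 if j < n_per // 2 else -1
            y = mu + 20 * intensity + 12 * rng.standard_normal()
            y = min(max(y, 0.0), 100.0) if censor else y
            rows.append(
                dict(
                    subject_id=f"s{i:02d}",
                    group=-1 if i < n_subjects // 2 else 1,
                    session=session,
                    intensity=intensity,
                    rating=y,
                    censored="none",
                )
            )
    df = pd.DataFrame(rows)
    df.loc[df["rating"] <= 0, "censored"] = "low"
    df.loc[df["rating"] >= 100, "censored"] = "high"
    return df


SMALL_SPEC = cm.ModelSpec(
    fixed_terms=("intercept", "intensity"),
    random_terms=("intercept",),
)


class TestCensoredLoglik:
    def _params(self, df, beta=(50.0, 20.0), sigma_val=12.0):
        n_sub = df["subject_id"].nunique()
        return {
            "beta": np.array(beta),
            "b": np.zeros((n_sub, 1)),
            "sigma": np.full(n_sub, sigma_val),
        }

    def test_interior_data_match_gaussian_loglik(self):
        rng = np.random.default_rng(0)
        df = _tiny_dataset(rng, censor=False)
        df["rating"] = df["rating"].clip(1, 99)  # keep strictly interior
        params = self._params(df)
        ours = cm.censored_loglik(params, df, SMALL_SPEC)
        mu = params["beta"][0] + params["beta"][1] * df["intensity"]
        direct = stats.norm.logpdf(df["rating"], mu, 12.0).sum()
        assert ours == pytest.approx(direct, rel=1e-12)

    def test_boundary_observation_contributes_log_half(self):
        df = pd.DataFrame(
            [dict(subject_id="s0", group=1, session=1, intensity=1,
                  rating=100.0, censored="high"),
             dict(subject_id="s0", group=1, session=-1, intensity=-1,
                  rating=50.0, censored="none")]
        )
        # mu at the censored row must be exactly 100: beta0 + beta1 = 100
        params = {"beta": np.array([75.0, 25.0]),
                  "b": np.zeros((1, 1)), "sigma": np.array([1.0])}
        ll = cm.censored_loglik(params, df, SMALL_SPEC)
        interior = stats.norm.logpdf(50.0, 50.0, 1.0)
        assert ll - interior == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_quadrature_oracle(self):
        # Integrate the latent-normal density numerically: interior points
        # over a vanishing window and censored points over the tail.
        rng = np.random.default_rng(1)
        df = _tiny_dataset(rng, n_subjects=3, n_per=6)
        params = self._params(df, beta=(85.0, 20.0))  # pushes data to bound
        n_sub = 3
        params["b"] = rng.standard_normal((n_sub, 1)) * 5
        subjects = np.unique(df["subject_id"])
        ours = cm.censored_loglik(params, df, SMALL_SPEC)
        total = 0.0
        for _, row in df.iterrows():
            i = list(subjects).index(row["subject_id"])
            mu = (
                params["beta"][0]
                + params["beta"][1] * row["intensity"]
                + params["b"][i, 0]
            )
            sdv = params["sigma"][i]
            f = lambda x: stats.norm.pdf(x, mu, sdv)
            if row["censored"] == "high":
                val, _ = integrate.quad(f, 100.0, np.inf)
            elif row["censored"] == "low":
                val, _ = integrate.quad(f, -np.inf, 0.0)
            else:
                val = f(row["rating"])
            total += math.log(val)
        assert ours == pytest.approx(total, abs=1e-8)

    def test_censoring_never_increases_loglik_density_bound(self):
        # Tail probabilities are <= 1, so the censored log-likelihood of
        # boundary points is <= 0 while interior contributions match the
        # plain Gaussian term.
        rng = np.random.default_rng(2)
        df = _tiny_dataset(rng)
        params = self._params(df)
        interior = df[df["censored"] == "none"]
        ll_full = cm.censored_loglik(params, df, SMALL_SPEC)
        ll_interior = cm.censored_loglik(params, interior, SMALL_SPEC)
        assert ll_full <= ll_interior + 1e-12

    def test_rejects_out_of_bounds_rating(self):
        df = _tiny_dataset(np.random.default_rng(3))
        df.loc[0, "rating"] = 101.0
        with pytest.raises(ValueError):
            cm.censored_loglik(self._params(df), df, SMALL_SPEC)


class TestModelSpecValidation:
    def test_between_subject_random_term_rejected(self):
        with pytest.raises(ValueError):
            cm.ModelSpec(
                fixed_terms=("intercept", "group"), random_terms=("group",)
            )

    def test_intercept_required(self):
        with pytest.raises(ValueError):
            cm.ModelSpec(fixed_terms=("group",), random_terms=())

    def test_priors_validated(self):
        with pytest.raises(ValueError):
            cm.PriorSpec(beta_scale=-1.0)


class TestSummaries:
    def test_constant_draws_give_degenerate_interval(self):
        draws = _const_draws(3.5)
        (s,) = cm.summarize_fixed(draws)
        assert (s.posterior_mean, s.ci_low, s.ci_high) == (3.5, 3.5, 3.5)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(4)
        arr = rng.standard_normal((1, 1_000_000, 1))
        draws = _wrap_beta(arr)
        (s,) = cm.summarize_fixed(draws)
        assert s.ci_low == pytest.approx(-1.96, abs=0.01)
        assert s.ci_high == pytest.approx(1.96, abs=0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        arr = rng.standard_normal((1, 5000, 1))
        s1 = cm.summarize_fixed(_wrap_beta(arr))[0]
        perm = arr[:, rng.permutation(5000), :]
        s2 = cm.summarize_fixed(_wrap_beta(perm))[0]
        assert (s1.posterior_mean, s1.ci_low, s1.ci_high) == (
            s2.posterior_mean, s2.ci_low, s2.ci_high
        )


def _wrap_beta(arr):
    return cm.PosteriorDraws(
        fixed_terms=["intercept"],
        random_terms=["intercept"],
        subjects=["s0"],
        beta=arr,
        b=np.zeros((1, arr.shape[1], 1, 1)),
        re_sd=np.ones((1, arr.shape[1], 1)),
        re_corr=np.ones((1, arr.shape[1], 1, 1)),
        sigma=np.ones((1, arr.shape[1], 1)),
        priors=cm.PriorSpec(),
    )


def _const_draws(c):
    return _wrap_beta(np.full((1, 100, 1), c))


class TestConditionDifference:
    @pytest.mark.parametrize(
        "beta,expected", [(27.86, 55.72), (17.48, 34.96), (0.0, 0.0)]
    )
    def test_two_level_reading(self, beta, expected):
        assert cm.condition_difference(beta) == pytest.approx(expected)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            cm.condition_difference(float("nan"))

    def test_general_contrast_matches_simple_difference(self, empathy_fit):
        simple = 2.0 * np.mean(empathy_fit.term_draws("intensity"))
        general = cm.contrast(empathy_fit, {"intensity": 2.0})
        assert general.posterior_mean == pytest.approx(simple, rel=1e-12)


class TestFitPosterior:
    def test_recovers_generative_effects(self, empathy_fit):
        summ = {s.term: s for s in cm.summarize_fixed(empathy_fit)}
        s = summ["intensity"]
        assert s.ci_low < 27.86 < s.ci_high
        assert abs(summ["group:session:intensity"].posterior_mean) < 3.0

    def test_diagnostics_reported(self, empathy_fit):
        d = empathy_fit.diagnostics
        assert set(d) >= {"rhat", "ess_bulk", "acceptance", "divergences"}
        assert all(v > 50 for v in d["ess_bulk"].values())

    def test_ci_ordering_invariant(self, empathy_fit):
        for s in cm.summarize_fixed(empathy_fit):
            assert s.ci_low <= s.posterior_mean <= s.ci_high

    def test_bounds_enter_only_through_censoring(self):
        # With no observation at a bound the censored model is an
        # ordinary mixed model: widening the bounds must not change a
        # seeded fit at all.
        rng = np.random.default_rng(6)
        df = _tiny_dataset(rng, n_subjects=4, censor=False)
        df["rating"] = df["rating"].clip(5, 95)
        kw = dict(n_chains=1, n_warmup=150, n_draws=150, seed=3, check_rhat=False)
        fit_narrow = cm.fit_posterior(df, SMALL_SPEC, **kw)
        wide = cm.ModelSpec(
            fixed_terms=SMALL_SPEC.fixed_terms,
            random_terms=SMALL_SPEC.random_terms,
            bounds=(-1e6, 1e6),
        )
        fit_wide = cm.fit_posterior(df, wide, **kw)
        np.testing.assert_array_equal(fit_narrow.beta, fit_wide.beta)

    def test_rejects_nonfinite_and_underidentified_data(self):
        rng = np.random.default_rng(7)
        df = _tiny_dataset(rng)
        bad = df.copy()
        bad.loc[0, "rating"] = np.nan
        with pytest.raises(ValueError):
            cm.fit_posterior(bad, SMALL_SPEC, n_chains=1, n_warmup=10, n_draws=10)
        single_cell = df[(df["intensity"] == 1) & (df["session"] == 1)]
        with pytest.raises(ValueError):
            cm.fit_posterior(
                single_cell, SMALL_SPEC, n_chains=1, n_warmup=10, n_draws=10
            )

    def test_prior_recovery(self):
        spec = cm.empathy_model_spec()
        prior = cm.sample_prior(spec, n_draws=40_000, seed=8)
        beta = prior.term_draws("session")
        assert np.std(beta) == pytest.approx(spec.priors.beta_scale, rel=0.02)
        tau = prior.re_sd_draws("intensity")
        # half-normal(0, s): mean s*sqrt(2/pi)
        assert np.mean(tau) == pytest.approx(
            spec.priors.re_sd_scale * math.sqrt(2 / math.pi), rel=0.02
        )
        corr = prior.re_corr_draws("session", "intensity")
        assert abs(np.mean(corr)) < 0.02


class TestEmceeCrossCheck:
    def test_gibbs_matches_emcee_on_direct_likelihood(self):
        """Same posterior, two samplers: augmentation Gibbs vs. an
        ensemble sampler driven by the closed-form censored likelihood."""
        emcee = pytest.importorskip("emcee")
        rng = np.random.default_rng(9)
        df = _tiny_dataset(rng, n_subjects=4, n_per=10)
        assert (df["censored"] != "none").any()
        spec = SMALL_SPEC
        priors = spec.priors

        subjects = np.unique(df["subject_id"])
        S = subjects.size
        X = cm.build_design(df, spec.fixed_terms)
        sidx = pd.Categorical(df["subject_id"], categories=subjects).codes
        y = df["rating"].to_numpy(float)
        at_low = y <= 0.0
        at_high = y >= 100.0
        interior = ~(at_low | at_high)

        def log_post(theta):
            # theta: beta(2), b(S), log_tau, log_sigma(S) — vectorized
            # over walkers (theta is (w, dim)).
            th = np.atleast_2d(theta)
            beta = th[:, :2]
            b = th[:, 2: 2 + S]
            log_tau = th[:, 2 + S]
            log_sig = th[:, 3 + S:]
            tau = np.exp(log_tau)
            sig = np.exp(log_sig)
            mu = beta @ X.T + b[:, sidx]
            sdv = sig[:, sidx]
            ll = np.zeros(th.shape[0])
            z = (y[None, interior] - mu[:, interior]) / sdv[:, interior]
            ll += np.sum(
                -np.log(sdv[:, interior]) - 0.5 * (np.log(2 * np.pi) + z**2),
                axis=1,
            )
            if at_low.any():
                ll += np.sum(
                    stats.norm.logcdf(0.0, mu[:, at_low], sdv[:, at_low]), axis=1
                )
            if at_high.any():
                ll += np.sum(
                    stats.norm.logsf(100.0, mu[:, at_high], sdv[:, at_high]), axis=1
                )
            lp = (
                stats.norm.logpdf(beta[:, 0], 0, priors.intercept_scale)
                + stats.norm.logpdf(beta[:, 1], 0, priors.beta_scale)
                + np.sum(
                    stats.norm.logpdf(b, 0, tau[:, None]), axis=1
                )
                - 0.5 * (tau / priors.re_sd_scale) ** 2 + log_tau
                + np.sum(-0.5 * (sig / priors.sigma_scale) ** 2 + log_sig, axis=1)
            )
            return ll + lp

        ndim = 2 + S + 1 + S
        nwalk = 4 * ndim
        rng2 = np.random.default_rng(10)
        p0 = np.concatenate(
            [
                50 + 5 * rng2.standard_normal((nwalk, 1)),
                20 + 2 * rng2.standard_normal((nwalk, 1)),
                5 * rng2.standard_normal((nwalk, S)),
                np.log(8) + 0.3 * rng2.standard_normal((nwalk, 1)),
                np.log(12) + 0.3 * rng2.standard_normal((nwalk, S)),
            ],
            axis=1,
        )
        sampler = emcee.EnsembleSampler(nwalk, ndim, log_post, vectorize=True)
        sampler.run_mcmc(p0, 3000, progress=False)
        chain = sampler.get_chain(discard=1500, thin=5, flat=True)

        gibbs = cm.fit_posterior(
            df, spec, n_chains=2, n_warmup=600, n_draws=1500, seed=11,
            check_rhat=False,
        )
        for k, term in enumerate(spec.fixed_terms):
            em_mean, em_sd = chain[:, k].mean(), chain[:, k].std()
            gi = gibbs.term_draws(term)
            assert gi.mean() == pytest.approx(em_mean, abs=0.25 * em_sd)
            assert gi.std() == pytest.approx(em_sd, rel=0.25)
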