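import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from slsbayes import (
    DesignConfig,
    MCMCSettings,
    PosteriorDraws,
    PriorConfig,
    TruthConfig,
    dic,
    enumerate_candidates,
    error_level_to_sigma2_u,
    gelman_rubin,
    generate_dataset,
    posterior_predictive_check,
    posterior_summary,
    prior_treatment,
    run_mcmc,
    select_model,
    simulation_priors,
)

FAST = MCMCSettings(chains=2, iterations=3000, burn_in=1000, thin=2, seed=5)


def _draws_from_arrays(a2_chains, deviance=None):
    """Assemble a PosteriorDraws by hand for summary/diagnostic tests."""
    a2 = np.asarray(a2_chains, dtype=float)[..., None]  # (C, T, 1)
    dev = np.zeros(a2.shape[:2]) if deviance is None else np.asarray(deviance)
    st = MCMCSettings(chains=a2.shape[0], iterations=2 * a2.shape[1],
                      burn_in=a2.shape[1], thin=1)
    return PosteriorDraws(params={"A2": a2}, deviance=dev, settings=st)


class TestSampler:
    def test_same_seed_bitwise_identical(self, small_dataset, informative_priors):
        ds, _ = small_dataset
        a = run_mcmc(ds, informative_priors, FAST)
        b = run_mcmc(ds, informative_priors, FAST)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_stored_shapes_and_support(self, small_dataset, informative_priors):
        ds, _ = small_dataset
        d = run_mcmc(ds, informative_priors, FAST)
        assert d.params["A2"].shape == (2, 1000, 1)
        assert np.all(d.params["sigma2_R"] > 0)
        assert np.all(d.params["sigma2_dn"] > 0)
        assert np.all(d.params["sigma2_u"] > 0)
        assert np.all(np.isfinite(d.deviance))

    def test_conjugate_sigma2_r_posterior(self):
        """With A2 and dn/dc pinned by near-degenerate priors, no Berkson
        adjustment and no RI channel, sigma2_R draws follow the closed-form
        inverse-gamma posterior."""
        truth = TruthConfig(A2=(0.0,), sigma2_u=0.0, sigma2_dn=0.0)
        ds = generate_dataset(truth, DesignConfig(), seed=21)
        ds = dataclasses.replace(ds) if False else ds
        ds.ri_valid[:] = False  # LS-only
        pri = PriorConfig(
            mu_dn_dc=truth.dn_dc, sigma_dn_dc=1e-9, truncate_dn_dc=False,
            mu_A2=0.0, sigma_A2=1e-11, adjust_concentration=False,
            a_R=1.0, b_R=1e-10,
        )
        st = MCMCSettings(chains=2, iterations=9000, burn_in=5000, thin=2, seed=3)
        d = run_mcmc(ds, pri, st)
        # closed form at the pinned parameter values
        from slsbayes import material_constant, true_rayleigh

        k = material_constant(truth.dn_dc, truth.constants)
        resid = ds.rayleigh - true_rayleigh(ds.c_measured, truth.mw(), 0.0, k)
        shape = pri.a_R + ds.n_obs / 2.0
        scale = pri.b_R + 0.5 * float(resid @ resid)
        draws = d.pooled("sigma2_R")
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_interval_calibration_on_generated_data(self):
        """95% intervals for A2 cover the generating value in >= 90% of
        seeded single-run fits (5% error, informative prior)."""
        from slsbayes.simstudy import SimulationCell, run_cell

        res = run_cell(SimulationCell(1e-4, 5.0, "informative", 1,
                                      n_datasets=20, base_seed=77))
        assert res.coverage >= 0.9

    def test_initialization_failure_reports(self, small_dataset):
        ds, truth = small_dataset
        bad = dataclasses.replace(ds)
        bad.rayleigh = ds.rayleigh * np.inf
        pri = prior_treatment("informative", truth.sigma2_u)
        with pytest.raises(RuntimeError, match="log-likelihood"):
            run_mcmc(bad, pri, FAST)


class TestGelmanRubin:
    def test_identical_chains_floor(self):
        a = np.tile(np.random.default_rng(0).standard_normal(200), (3, 1))
        r = gelman_rubin({"x": a}.items() and {"x": a})
        n = a.shape[1]
        assert r["x"] == pytest.approx(math.sqrt((n - 1) / n))
        assert r["x"] <= 1.0

    def test_same_gaussian_chains_near_one(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2, 10_000))
        assert gelman_rubin({"x": a})["x"] < 1.05

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((2, 500))
        a[1] += 10.0
        assert gelman_rubin({"x": a})["x"] > 2.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin({"x": np.zeros((1, 100))})


class TestDIC:
    def test_constant_trace(self):
        d0 = 123.4
        val, pd_, dbar = dic(np.full(50, d0))
        assert (val, pd_, dbar) == (pytest.approx(d0), pytest.approx(0.0), pytest.approx(d0))

    def test_two_point_trace(self):
        val, pd_, dbar = dic(np.array([0.0, 2.0]))
        assert dbar == pytest.approx(1.0)
        assert pd_ == pytest.approx(np.var([0.0, 2.0], ddof=1) / 2.0)
        assert val == pytest.approx(dbar + pd_)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            dic(np.array([1.0]))

    def test_gaussian_toy_matches_exact_posterior(self):
        """Known-variance Gaussian mean model with flat prior: the exact
        posterior gives DIC = D(ybar) + 2 (pD = 1 from the chi-square
        deviance excess). Check against 1e5 exact posterior draws."""
        rng = np.random.default_rng(9)
        n, sigma = 40, 1.3
        y = rng.normal(0.7, sigma, size=n)
        ybar = y.mean()
        theta = rng.normal(ybar, sigma / math.sqrt(n), size=100_000)
        dev = (((y[None, :] - theta[:, None]) ** 2).sum(axis=1) / sigma**2
               + n * math.log(2 * math.pi * sigma**2))
        d_at_mean = ((y - ybar) ** 2).sum() / sigma**2 + n * math.log(2 * math.pi * sigma**2)
        val, pd_, dbar = dic(dev)
        assert pd_ == pytest.approx(1.0, abs=0.05)
        assert val == pytest.approx(d_at_mean + 2.0, abs=0.1)

    def test_mean_variant_close_to_var_variant_when_regular(
        self, small_dataset, informative_priors
    ):
        ds, _ = small_dataset
        d = run_mcmc(ds, informative_priors, FAST)
        v_var, pd_var, _ = dic(d)
        v_mean, pd_mean, _ = dic(d, variant="mean", dataset=ds, priors=informative_priors)
        assert pd_var > 0 and pd_mean > 0
        assert abs(pd_var - pd_mean) < 0.8 * max(pd_var, pd_mean)


class TestPosteriorSummary:
    def test_three_point_example(self):
        d = _draws_from_arrays([[1e-5, 2e-5, 3e-5] * 5, [2e-5] * 15])
        s = posterior_summary(d, compute_dic=False)
        assert s.table.loc["A2[0]", "mean"] == pytest.approx(2e-5)
        assert s.p_a2_positive[0] == 1.0

    def test_sign_split(self):
        d = _draws_from_arrays([[-1.0, 1.0] * 10, [-1.0, 1.0] * 10])
        s = posterior_summary(d, compute_dic=False)
        assert s.p_a2_positive[0] == pytest.approx(0.5)

    def test_gaussian_quantiles(self):
        rng = np.random.default_rng(4)
        d = _draws_from_arrays(rng.standard_normal((2, 5000)))
        s = posterior_summary(d, compute_dic=False)
        assert s.table.loc["A2[0]", "q2.5"] == pytest.approx(-1.96, abs=0.1)
        assert s.table.loc["A2[0]", "q97.5"] == pytest.approx(1.96, abs=0.1)


class TestModelSelection:
    SETTINGS = MCMCSettings(chains=2, iterations=2500, burn_in=1000, thin=3, seed=1)

    def _score(self, mw_multiple, winners):
        pri = dataclasses.replace(
            prior_treatment("informative", error_level_to_sigma2_u(5.0),
                            base=PriorConfig()),
        )
        cands = enumerate_candidates("lysozyme", 14307.0)
        hits = 0
        for rep in range(10):
            truth = TruthConfig(A2=(1e-4,), Mw_multiple=mw_multiple,
                                sigma2_u=error_level_to_sigma2_u(5.0))
            ds = generate_dataset(truth, DesignConfig(), seed=100 + rep)
            ranked = select_model(ds, cands, pri, self.SETTINGS)
            if ranked[0][0] in winners:
                hits += 1
        return hits

    def test_monomer_data_selects_monomer_capable_model(self):
        assert self._score(1.0, {"M1", "M3"}) >= 8

    def test_dimer_data_selects_dimer_model(self):
        assert self._score(2.0, {"M2", "M3"}) >= 8

    def test_single_candidate_returned(self, small_dataset, informative_priors):
        ds, _ = small_dataset
        out = select_model(ds, enumerate_candidates("lysozyme", 14307.0)[:1],
                           informative_priors, FAST)
        assert len(out) == 1 and out[0][0] == "M1" and np.isfinite(out[0][1])


class TestNoAdjustmentLimit:
    def test_tight_berkson_prior_approaches_no_adjustment(self, small_dataset):
        """As the sigma2_u prior collapses to zero, the A2 posterior of the
        full model converges to the no-adjustment posterior."""
        ds, truth = small_dataset
        base = simulation_priors()
        tight = dataclasses.replace(base, a_u=200.0, b_u=200.0 * 1e-12)
        none = dataclasses.replace(base, adjust_concentration=False)
        st = MCMCSettings(chains=2, iterations=6000, burn_in=2000, thin=4, seed=13)
        a2_tight = run_mcmc(ds, tight, st).pooled("A2")[:, 0]
        a2_none = run_mcmc(ds, none, st).pooled("A2")[:, 0]
        ks = stats.ks_2samp(a2_tight, a2_none).statistic
        assert ks < 0.1


class TestPosteriorPredictive:
    def test_coverage_and_determinism(self, small_dataset, informative_priors):
        ds, _ = small_dataset
        d = run_mcmc(ds, informative_priors, FAST)
        rep1 = posterior_predictive_check(d, ds, seed=2)
        rep2 = posterior_predictive_check(d, ds, seed=2)
        assert rep1.equals(rep2)
        cov = rep1["inside"].mean()
        assert 0.85 <= cov <= 1.0

    def test_shifted_observation_flagged(self, small_dataset, informative_priors):
        ds, _ = small_dataset
        d = run_mcmc(ds, informative_priors, FAST)
        shifted = dataclasses.replace(ds)
        pred_sd = math.sqrt(float(d.pooled("sigma2_R").mean()))
        shifted.rayleigh = ds.rayleigh.copy()
        shifted.rayleigh[5] += 10 * pred_sd + 10 * d.pooled("A2").std()
        rep = posterior_predictive_check(d, shifted, seed=2)
        row = rep[(rep.obs == 5) & (rep.signal == "LS")].iloc[0]
        assert not row["inside"]
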