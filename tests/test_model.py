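import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, stats

from slsbayes import (
    ExperimentDataset,
    ModelParameters,
    OligomerSpec,
    PhysicalConstants,
    PriorConfig,
    enumerate_candidates,
    log_likelihood,
    log_prior,
    no_adjustment_variant,
)
from slsbayes.model import _truncnorm0_logpdf, condition_kstar


def toy_dataset(n_levels=3, L=1, seed=0):
    rng = np.random.default_rng(seed)
    c = np.tile(np.array([0.0025, 0.01, 0.02][:n_levels]), L)
    cond = np.repeat(np.arange(L), n_levels)
    n0 = np.full(L, 1.33)
    r = 2.4e-7 * 14307 * c * (1 + 0.02 * rng.standard_normal(c.size))
    dn = 0.2 * c * (1 + 0.01 * rng.standard_normal(c.size))
    valid = np.ones(c.size, dtype=bool)
    return ExperimentDataset(c, r, dn, valid, cond, n0)


def toy_params(ds, u=None, sigma2_u=2e-4):
    L = ds.n_conditions
    return ModelParameters(
        A2=np.full(L, 3e-4),
        dn_dc=0.197,
        Mw=np.full(L, 14307.0),
        sigma2_R=1e-11,
        sigma2_dn=2e-9,
        u=np.full(ds.n_obs, 1.01) if u is None else u,
        sigma2_u=sigma2_u,
    )


def brute_force_loglik(ds, p):
    """Term-by-term scipy.stats oracle, independent of the implementation."""
    total = 0.0
    kstar = condition_kstar(ds, p.dn_dc)
    for i in range(ds.n_obs):
        l = ds.cond_idx[i]
        c = ds.c_measured[i] * (p.u[i] if p.u is not None else 1.0)
        mean_r = kstar[l] * p.Mw[l] * c * (1 - 2 * p.A2[l] * p.Mw[l] * c)
        total += stats.norm.logpdf(ds.rayleigh[i], mean_r, math.sqrt(p.sigma2_R))
        if ds.ri_valid[i]:
            mu, sd = c * p.dn_dc, math.sqrt(p.sigma2_dn)
            total += stats.truncnorm.logpdf(ds.delta_n[i], -mu / sd, np.inf, mu, sd)
    return total


def brute_force_logprior(p, pri, constants):
    total = 0.0
    sd = pri.sigma_dn_dc
    if pri.truncate_dn_dc:
        total += stats.truncnorm.logpdf(p.dn_dc, -pri.mu_dn_dc / sd, np.inf, pri.mu_dn_dc, sd)
    else:
        total += stats.norm.logpdf(p.dn_dc, pri.mu_dn_dc, sd)
    total += stats.invgamma.logpdf(p.sigma2_R, pri.a_R, scale=pri.b_R)
    total += stats.invgamma.logpdf(p.sigma2_dn, pri.a_dn, scale=pri.b_dn)
    total += stats.norm.logpdf(p.A2, pri.mu_A2, pri.sigma_A2).sum()
    if pri.adjust_concentration:
        total += stats.invgamma.logpdf(p.sigma2_u, pri.a_u, scale=pri.b_u)
        total += stats.lognorm.logpdf(p.u, math.sqrt(p.sigma2_u), scale=1.0).sum()
    spec = pri.oligomer
    m = constants.monomer_mass
    if spec.kind == "uniform_range":
        total += stats.uniform.logpdf(p.Mw, spec.low * m, (spec.high - spec.low) * m).sum()
    elif spec.kind == "bernoulli_dimer":
        total += len(p.Mw) * math.log(0.5)
    return total


class TestLogLikelihood:
    def test_matches_brute_force_oracle(self):
        ds = toy_dataset(L=2, seed=1)
        p = toy_params(ds, u=1.0 + 0.02 * np.random.default_rng(2).standard_normal(ds.n_obs))
        assert log_likelihood(ds, p) == pytest.approx(brute_force_loglik(ds, p), abs=1e-10)

    def test_gaussian_mode_attained_at_mean(self):
        """With R_m exactly at the model mean and no RI term, the log-density
        is the Gaussian normalising constant."""
        kstar = 2.4154232456053897e-07
        c = np.array([0.01])
        r = np.array([kstar * 14307 * 0.01])
        ds = ExperimentDataset(c, r, np.array([np.nan]), np.array([False]),
                               np.array([0]), np.array([1.33]))
        p = ModelParameters(A2=[0.0], dn_dc=0.1970, Mw=[14307.0],
                            sigma2_R=1e-12, sigma2_dn=1e-9,
                            u=np.ones(1), sigma2_u=1e-4)
        expect = math.log(1.0 / (math.sqrt(1e-12) * math.sqrt(2 * math.pi)))
        assert log_likelihood(ds, p) == pytest.approx(expect, rel=1e-12)

    def test_truncation_negligible_far_from_zero(self):
        """At dn = 0.002 and sd = 1e-4 the truncated and plain Gaussian
        densities agree to < 1e-8."""
        x, mu, s2 = 0.00198, 0.002, (1e-4) ** 2
        tn = _truncnorm0_logpdf(x, mu, s2)
        gauss = stats.norm.logpdf(x, mu, math.sqrt(s2))
        assert abs(tn - gauss) < 1e-8

    def test_factorises_over_observations(self):
        ds = toy_dataset(seed=3)
        p = toy_params(ds)
        full = log_likelihood(ds, p)
        for i in range(ds.n_obs):
            reduced = ds.drop_observation(i)
            p_red = dataclasses.replace(p, u=np.delete(p.u, i))
            single = ExperimentDataset(
                ds.c_measured[[i]], ds.rayleigh[[i]], ds.delta_n[[i]],
                ds.ri_valid[[i]], np.array([ds.cond_idx[i]]), ds.n0,
            )
            p_one = dataclasses.replace(p, u=p.u[[i]])
            assert full == pytest.approx(
                log_likelihood(reduced, p_red) + log_likelihood(single, p_one), abs=1e-9
            )

    def test_nonpositive_variance_rejected(self):
        ds = toy_dataset()
        p = toy_params(ds)
        with pytest.raises(ValueError):
            log_likelihood(ds, dataclasses.replace(p, sigma2_R=0.0))

    def test_noiseless_identifiability_ridge(self):
        """With A2 = 0 and exact data, the likelihood is maximal on the
        ridge K*·Mw = R/c."""
        kstar = condition_kstar(toy_dataset(), 0.1970)[0]
        c = np.array([0.005, 0.01, 0.02])
        r = kstar * 14307 * c
        ds = ExperimentDataset(c, r, np.full(3, np.nan), np.zeros(3, bool),
                               np.zeros(3, int), np.array([1.33]))

        def ll(mw):
            p = ModelParameters(A2=[0.0], dn_dc=0.1970, Mw=[mw],
                                sigma2_R=1e-12, sigma2_dn=1e-9,
                                u=np.ones(3), sigma2_u=1e-4)
            return log_likelihood(ds, p)

        on_ridge = ll(14307.0)
        assert on_ridge > ll(14307.0 * 1.01)
        assert on_ridge > ll(14307.0 * 0.99)


class TestLogPrior:
    def test_matches_brute_force_oracle(self):
        ds = toy_dataset(L=2, seed=4)
        pri = PriorConfig()
        p = toy_params(ds)
        got = log_prior(p, pri, ds.constants)
        want = brute_force_logprior(p, pri, ds.constants)
        assert got == pytest.approx(want, abs=1e-10)

    def test_unit_multipliers_at_lognormal_log_median(self):
        ds = toy_dataset()
        pri = PriorConfig()
        p = toy_params(ds, u=np.ones(ds.n_obs), sigma2_u=4e-4)
        got = log_prior(p, pri, ds.constants)
        # each u-term at u = 1: log(1/sqrt(2*pi*sigma2_u))
        per_term = math.log(1.0 / math.sqrt(2 * math.pi * 4e-4))
        base = brute_force_logprior(
            dataclasses.replace(p, u=None),
            dataclasses.replace(pri, adjust_concentration=False),
            ds.constants,
        ) + stats.invgamma.logpdf(4e-4, pri.a_u, scale=pri.b_u)
        assert got == pytest.approx(base + ds.n_obs * per_term, abs=1e-10)

    def test_negative_dndc_outside_truncated_support(self):
        ds = toy_dataset()
        p = dataclasses.replace(toy_params(ds), dn_dc=-0.1)
        assert log_prior(p, PriorConfig(truncate_dn_dc=True), ds.constants) == -np.inf

    def test_uniform_range_support(self):
        ds = toy_dataset()
        pri = PriorConfig(oligomer=OligomerSpec("uniform_range", low=1.0, high=2.0))
        inside = dataclasses.replace(toy_params(ds), Mw=np.array([1.5 * 14307]))
        outside = dataclasses.replace(toy_params(ds), Mw=np.array([2.5 * 14307]))
        assert np.isfinite(log_prior(inside, pri, ds.constants))
        assert log_prior(outside, pri, ds.constants) == -np.inf
        assert log_prior(inside, pri, ds.constants) == pytest.approx(
            brute_force_logprior(inside, pri, ds.constants), abs=1e-10
        )

    def test_truncated_density_integrates_to_one(self):
        for mu, s2 in [(0.002, 1e-8), (1e-4, 1e-8), (-1e-4, 1e-8), (0.0005, 4e-8)]:
            val, _ = integrate.quad(
                lambda x: math.exp(_truncnorm0_logpdf(x, mu, s2)),
                0.0, mu + 20 * math.sqrt(s2),
            )
            assert val == pytest.approx(1.0, abs=1e-7)

    def test_continuity_near_interior_point(self):
        ds = toy_dataset()
        pri = PriorConfig()
        p = toy_params(ds)
        base = log_prior(p, pri, ds.constants) + log_likelihood(ds, p)
        for eps in (1e-6, 1e-8):
            p2 = dataclasses.replace(p, dn_dc=p.dn_dc + eps,
                                     A2=p.A2 + eps * 1e-3)
            moved = log_prior(p2, pri, ds.constants) + log_likelihood(ds, p2)
            assert abs(moved - base) < 1e-2


class TestNoAdjustment:
    def test_flag_cleared(self):
        pri = no_adjustment_variant(PriorConfig())
        assert pri.adjust_concentration is False

    def test_likelihood_equals_full_model_at_unit_u(self):
        ds = toy_dataset(seed=5)
        p_full = toy_params(ds, u=np.ones(ds.n_obs))
        p_none = dataclasses.replace(p_full, u=None, sigma2_u=None)
        assert log_likelihood(ds, p_full) == pytest.approx(
            log_likelihood(ds, p_none), abs=1e-12
        )

    def test_prior_has_no_u_terms(self):
        ds = toy_dataset()
        pri = no_adjustment_variant(PriorConfig())
        p = dataclasses.replace(toy_params(ds), u=None, sigma2_u=None)
        got = log_prior(p, pri, ds.constants)
        assert got == pytest.approx(brute_force_logprior(p, pri, ds.constants), abs=1e-10)


class TestCandidates:
    def test_lysozyme_family(self):
        cands = enumerate_candidates("lysozyme", 14307.0)
        assert [n for n, _ in cands] == ["M1", "M2", "M3", "M4"]
        m2 = dict(cands)["M2"]
        assert m2.kind == "fixed_multiple" and m2.x * 14307.0 == 28614.0

    def test_hgs_family_count_and_dodecamer(self):
        cands = enumerate_candidates("hgs", 20959.80)
        assert len(cands) == 22
        m12 = dict(cands)["M12"]
        assert m12.x * 20959.80 == pytest.approx(251517.6)

    def test_bad_mode_and_mass(self):
        with pytest.raises(ValueError):
            enumerate_candidates("elastin", 10000.0)
        with pytest.raises(ValueError):
            enumerate_candidates("lysozyme", -1.0)
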