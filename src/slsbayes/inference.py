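"""MCMC engine, diagnostics, DIC model comparison and posterior summaries.

The sampler is a Metropolis-within-Gibbs scheme over the full latent
state, vectorised over independent rows (chains, and — for the simulation
study — whole batches of datasets sharing one measurement design):

* ``log u[il]`` — per-observation random-walk MH, all coordinates updated
  in parallel (valid because the likelihood factorises over observations
  given the global parameters);
* ``A2[l]`` — per-condition random-walk MH;
* oligomer state — exact 2-state Gibbs for the Bernoulli monomer/dimer
  switch, random-walk MH for continuous Mw, conjugate/truncated-Gaussian
  Gibbs for the hierarchical hyperparameters;
* ``dn/dc`` — global random-walk MH (it enters both K* and the RI mean);
* ``sigma2_R`` and ``sigma2_u`` — exact conjugate inverse-gamma Gibbs;
* ``sigma2_dn`` — independence MH proposing from the untruncated
  conjugate posterior, corrected for the truncated-Gaussian
  normalisation (the correction is numerically negligible except near
  the detection limit, but is included exactly).

Proposal scales adapt toward a 44% acceptance rate during burn-in and are
frozen afterwards, so the post-burn-in chain is a valid Markov chain.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from . import model as mdl
from .model import ExperimentDataset, ModelParameters, OligomerSpec, PriorConfig

__all__ = [
    "MCMCSettings",
    "PosteriorDraws",
    "FitSummary",
    "run_mcmc",
    "gelman_rubin",
    "dic",
    "select_model",
    "posterior_summary",
    "posterior_predictive_check",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler run-length controls.

    The defaults are working-scale settings adequate for the single-run
    designs used throughout the test-suite (gated by R-hat); use
    :meth:`reference_scale` for the conservative 5×300k/200k/250 protocol
    used for the case-study-sized fits.
    """

    chains: int = 4
    iterations: int = 6000  # total per chain, including burn-in
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    adapt_target: float = 0.44
    adapt_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains and thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def reference_scale(cls, seed: int = 0) -> "MCMCSettings":
        return cls(chains=5, iterations=300000, burn_in=200000, thin=250, seed=seed)


@dataclass
class PosteriorDraws:
    """Stored post-burn-in draws, shaped (chains, stored, ...) per name.

    ``params`` maps parameter names to arrays: scalars (C, T), vectors
    (C, T, dim). ``deviance`` is −2×log-likelihood at each stored state.
    """

    params: dict[str, np.ndarray]
    deviance: np.ndarray  # (C, T)
    settings: MCMCSettings
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_stored(self) -> int:
        return self.deviance.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated: (C*T,) or (C*T, dim)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_items(self):
        """Yield (label, (C, T) array) for every scalar component."""
        for name, a in self.params.items():
            if a.ndim == 2:
                yield name, a
            else:
                for j in range(a.shape[2]):
                    yield f"{name}[{j}]", a[:, :, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) export."""
        rows = []
        for label, a in self.scalar_items():
            c, t = np.meshgrid(np.arange(a.shape[0]), np.arange(a.shape[1]), indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "iteration": t.ravel(),
                        "parameter": label,
                        "value": a.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# batched sampler core
# ---------------------------------------------------------------------------


@dataclass
class _Batch:
    """D independent datasets sharing one design, tiled over C chains."""

    c_m: np.ndarray  # (D, N)
    r_m: np.ndarray  # (D, N)
    dn_m: np.ndarray  # (D, N), NaN where invalid
    valid: np.ndarray  # (N,) bool
    cond_idx: np.ndarray  # (N,)
    n0: np.ndarray  # (L,)
    constants: mdl.PhysicalConstants


def _batch_from_dataset(ds: ExperimentDataset) -> _Batch:
    return _Batch(
        c_m=ds.c_measured[None, :],
        r_m=ds.rayleigh[None, :],
        dn_m=ds.delta_n[None, :],
        valid=ds.ri_valid,
        cond_idx=ds.cond_idx,
        n0=ds.n0,
        constants=ds.constants,
    )


class _Engine:
    """Vectorised Metropolis-within-Gibbs over B = D×C independent rows."""

    def __init__(self, batch: _Batch, priors: PriorConfig, settings: MCMCSettings,
                 store_u: bool = False):
        self.b = batch
        self.priors = priors
        self.st = settings
        self.store_u = store_u
        self.D, self.N = batch.c_m.shape
        self.C = settings.chains
        self.B = self.D * self.C
        self.L = batch.n0.shape[0]
        self.adjust = priors.adjust_concentration
        self.spec = priors.oligomer
        self.M = batch.constants.monomer_mass

        # data tiled over chains: row b = dataset b//C, chain b%C
        self.c = np.repeat(batch.c_m, self.C, axis=0)  # (B, N)
        self.r = np.repeat(batch.r_m, self.C, axis=0)
        self.v = np.where(batch.valid)[0]
        self.dn = np.repeat(batch.dn_m[:, batch.valid], self.C, axis=0)  # (B, Nv)
        self.cond = batch.cond_idx
        self.cond_onehot = np.eye(self.L)[self.cond]  # (N, L)
        lam = batch.constants.wavelength
        self.k0_obs = (
            4.0 * math.pi**2 * batch.n0[self.cond] ** 2
            / (batch.constants.avogadro * lam**4)
        )  # (N,) K* per observation divided by (dn/dc)²

        self.rng = np.random.default_rng(settings.seed)

    # -- model pieces ------------------------------------------------------

    def _r_mean(self, dndc, a2, mw, logu):
        ct = self.c * np.exp(logu) if logu is not None else self.c
        kst = self.k0_obs[None, :] * dndc[:, None] ** 2
        a2o = a2[:, self.cond]
        mwo = mw[:, self.cond]
        return kst * mwo * ct * (1.0 - 2.0 * a2o * mwo * ct), ct

    def _ll_r_obs(self, r_mean, s2r):
        return -0.5 * (_LOG_2PI + np.log(s2r)[:, None] + (self.r - r_mean) ** 2 / s2r[:, None])

    def _ll_dn_obs(self, ct, dndc, s2dn):
        mu = ct[:, self.v] * dndc[:, None]
        sd = np.sqrt(s2dn)[:, None]
        return (
            -0.5 * (_LOG_2PI + np.log(s2dn)[:, None] + (self.dn - mu) ** 2 / s2dn[:, None])
            - log_ndtr(mu / sd)
        )

    # -- initialisation ----------------------------------------------------

    def _init_state(self):
        pri = self.priors
        rng = self.rng
        B, L, N = self.B, self.L, self.N

        dndc = np.full(B, pri.mu_dn_dc) + 0.1 * pri.sigma_dn_dc * rng.standard_normal(B)
        if pri.truncate_dn_dc:
            dndc = np.abs(dndc)
        mw = self._init_mw(rng)

        # rough per-row least-squares A2 from y = R/(K0·Mw·c) ≈ 1 − 2·A2·Mw·c
        k0 = self.k0_obs[None, :] * pri.mu_dn_dc**2
        mwo = mw[:, self.cond]
        with np.errstate(invalid="ignore", divide="ignore"):
            y = self.r / (k0 * mwo * self.c)
            x = self.c
            xm = x.mean(axis=1, keepdims=True)
            ym = y.mean(axis=1, keepdims=True)
            slope = ((x - xm) * (y - ym)).sum(axis=1) / ((x - xm) ** 2).sum(axis=1)
            a2_hat = -slope / (2.0 * mw.mean(axis=1))
        a2 = np.repeat(a2_hat[:, None], L, axis=1)

        r_mean, ct = self._r_mean(dndc, a2, mw, None)
        ssr = ((self.r - r_mean) ** 2).mean(axis=1)
        s2r = np.maximum(ssr, 1e-14)
        mu_dn = ct[:, self.v] * dndc[:, None]
        ssd = ((self.dn - mu_dn) ** 2).mean(axis=1) if self.v.size else np.full(B, pri.b_dn)
        s2dn = np.maximum(ssd, 1e-16)
        s2u = np.full(B, pri.ig_scale(pri.b_u) / (pri.a_u + 1.0))
        logu = np.zeros((B, N))
        # overdispersed chain starts for the MH-updated blocks
        a2 = a2 * (1.0 + 0.05 * rng.standard_normal((B, L))) + 1e-7 * rng.standard_normal((B, L))

        state = {
            "a2": a2, "dndc": dndc, "mw": mw, "s2r": s2r, "s2dn": s2dn,
            "s2u": s2u, "logu": logu,
        }
        if self.spec.kind == "bernoulli_dimer":
            state["k"] = np.zeros((B, L), dtype=int)
            state["mw"] = np.full((B, L), self.M)
        if self.spec.kind == "hierarchical_gaussian":
            state["mu_mw"] = state["mw"].mean(axis=1).clip(self.M, 20 * self.M)
            state["s2mw"] = np.full(B, (self.M / 3.0) ** 2)
        return state

    def _init_mw(self, rng):
        B, L = self.B, self.L
        sp = self.spec
        if sp.kind == "fixed_multiple":
            return np.full((B, L), sp.x * self.M)
        if sp.kind == "bernoulli_dimer":
            return np.full((B, L), self.M)
        lo, hi = sp.low * self.M, sp.high * self.M
        if sp.kind == "uniform_range":
            return rng.uniform(lo, hi, size=(B, L))
        # hierarchical_gaussian: start spread over the plausible range
        return rng.uniform(self.M, 20 * self.M, size=(B, L))

    # -- full log-likelihood (deviance) ------------------------------------

    def _loglik(self, state):
        logu = state["logu"] if self.adjust else None
        r_mean, ct = self._r_mean(state["dndc"], state["a2"], state["mw"], logu)
        ll = self._ll_r_obs(r_mean, state["s2r"]).sum(axis=1)
        if self.v.size:
            ll = ll + self._ll_dn_obs(ct, state["dndc"], state["s2dn"]).sum(axis=1)
        return ll

    # -- sampling ----------------------------------------------------------

    def run(self):
        st, pri, rng = self.st, self.priors, self.rng
        state = self._init_state()
        ll0 = self._loglik(state)
        if not np.all(np.isfinite(ll0)):
            raise RuntimeError(
                "non-finite log-likelihood at initialisation "
                f"(first bad row {int(np.argmax(~np.isfinite(ll0)))}); "
                "check data scales and prior support"
            )

        scales = {
            "logu": np.full((self.B, self.N), 0.3 * math.sqrt(max(state["s2u"].mean(), 1e-8))),
            "a2": np.maximum(np.abs(state["a2"]) * 0.3, 1e-6),
            "dndc": np.full(self.B, 0.3 * pri.sigma_dn_dc),
            "mw": np.full((self.B, self.L), 0.05 * self.M),
        }
        acc = {k: np.zeros_like(v) for k, v in scales.items()}
        n_att = {k: 0 for k in scales}

        T = st.n_stored
        out = {
            "a2": np.empty((self.B, T, self.L)),
            "dndc": np.empty((self.B, T)),
            "s2r": np.empty((self.B, T)),
            "s2dn": np.empty((self.B, T)),
        }
        if self.adjust:
            out["s2u"] = np.empty((self.B, T))
            if self.store_u:
                out["logu"] = np.empty((self.B, T, self.N))
        if self.spec.kind in ("uniform_range", "hierarchical_gaussian", "bernoulli_dimer"):
            out["mw"] = np.empty((self.B, T, self.L))
        if self.spec.kind == "hierarchical_gaussian":
            out["mu_mw"] = np.empty((self.B, T))
            out["s2mw"] = np.empty((self.B, T))
        dev = np.empty((self.B, T))

        t_out = 0
        for it in range(st.iterations):
            adapting = it < st.burn_in
            if self.adjust:
                self._update_logu(state, scales, acc)
            self._update_a2(state, scales, acc)
            self._update_mw(state, scales, acc)
            self._update_dndc(state, scales, acc)
            self._gibbs_s2r(state)
            self._mh_s2dn(state)
            if self.adjust:
                self._gibbs_s2u(state)
            for k in n_att:
                n_att[k] += 1

            if adapting and (it + 1) % 25 == 0:
                for k in scales:
                    rate = acc[k] / n_att[k]
                    scales[k] *= np.exp(2.0 * st.adapt_rate * (rate - st.adapt_target))
                    acc[k][...] = 0.0
                    n_att[k] = 0
            if it == st.burn_in - 1:
                for k in acc:
                    acc[k][...] = 0.0
                    n_att[k] = 0

            if it >= st.burn_in and (it - st.burn_in) % st.thin == st.thin - 1:
                out["a2"][:, t_out] = state["a2"]
                out["dndc"][:, t_out] = state["dndc"]
                out["s2r"][:, t_out] = state["s2r"]
                out["s2dn"][:, t_out] = state["s2dn"]
                if self.adjust:
                    out["s2u"][:, t_out] = state["s2u"]
                    if self.store_u:
                        out["logu"][:, t_out] = state["logu"]
                if "mw" in out:
                    out["mw"][:, t_out] = state["mw"]
                if "mu_mw" in out:
                    out["mu_mw"][:, t_out] = state["mu_mw"]
                    out["s2mw"][:, t_out] = state["s2mw"]
                dev[:, t_out] = -2.0 * self._loglik(state)
                t_out += 1

        rates = {
            k: float(np.mean(a / max(n_att[k], 1))) for k, a in acc.items()
        }
        return out, dev, rates

    # individual updates ----------------------------------------------------

    def _update_logu(self, state, scales, acc):
        rng = self.rng
        logu = state["logu"]
        prop = logu + scales["logu"] * rng.standard_normal(logu.shape)
        cur = self._obs_terms(state, logu)
        new = self._obs_terms(state, prop)
        s2u = state["s2u"][:, None]
        d = (new - prop**2 / (2 * s2u)) - (cur - logu**2 / (2 * s2u))
        accept = np.log(rng.random(logu.shape)) < d
        state["logu"] = np.where(accept, prop, logu)
        acc["logu"] += accept

    def _obs_terms(self, state, logu):
        """Per-observation log-likelihood (R term + RI term where valid)."""
        r_mean, ct = self._r_mean(state["dndc"], state["a2"], state["mw"], logu)
        t = self._ll_r_obs(r_mean, state["s2r"])
        if self.v.size:
            dn_t = self._ll_dn_obs(ct, state["dndc"], state["s2dn"])
            t[:, self.v] += dn_t
        return t

    def _cond_ll_r(self, state, a2, logu=None):
        lu = logu if logu is not None else (state["logu"] if self.adjust else None)
        r_mean, _ = self._r_mean(state["dndc"], a2, state["mw"], lu)
        return self._ll_r_obs(r_mean, state["s2r"]) @ self.cond_onehot  # (B, L)

    def _update_a2(self, state, scales, acc):
        rng = self.rng
        pri = self.priors
        a2 = state["a2"]
        prop = a2 + scales["a2"] * rng.standard_normal(a2.shape)
        ll_cur = self._cond_ll_r(state, a2)
        ll_new = self._cond_ll_r(state, prop)
        lp = lambda x: -((x - pri.mu_A2) ** 2) / (2.0 * pri.sigma_A2**2)
        d = (ll_new + lp(prop)) - (ll_cur + lp(a2))
        accept = np.log(rng.random(a2.shape)) < d
        state["a2"] = np.where(accept, prop, a2)
        acc["a2"] += accept

    def _update_mw(self, state, scales, acc):
        sp = self.spec
        if sp.kind == "fixed_multiple":
            acc["mw"] += 1.0  # keep adaptation bookkeeping neutral
            return
        rng = self.rng
        if sp.kind == "bernoulli_dimer":
            mw0 = np.full((self.B, self.L), self.M)
            mw1 = np.full((self.B, self.L), 2.0 * self.M)
            lu = state["logu"] if self.adjust else None
            r0, _ = self._r_mean(state["dndc"], state["a2"], mw0, lu)
            r1, _ = self._r_mean(state["dndc"], state["a2"], mw1, lu)
            ll0 = self._ll_r_obs(r0, state["s2r"]) @ self.cond_onehot
            ll1 = self._ll_r_obs(r1, state["s2r"]) @ self.cond_onehot
            p1 = 1.0 / (1.0 + np.exp(np.clip(ll0 - ll1, -700, 700)))
            k = (rng.random((self.B, self.L)) < p1).astype(int)
            state["k"] = k
            state["mw"] = (k + 1.0) * self.M
            acc["mw"] += 1.0
            return
        # continuous Mw: per-condition RW-MH
        mw = state["mw"]
        prop = mw + scales["mw"] * rng.standard_normal(mw.shape)
        lp_cur = self._mw_log_prior(mw, state)
        lp_new = self._mw_log_prior(prop, state)
        lu = state["logu"] if self.adjust else None
        r_cur, _ = self._r_mean(state["dndc"], state["a2"], mw, lu)
        r_new, _ = self._r_mean(state["dndc"], state["a2"], prop, lu)
        ll_cur = self._ll_r_obs(r_cur, state["s2r"]) @ self.cond_onehot
        ll_new = self._ll_r_obs(r_new, state["s2r"]) @ self.cond_onehot
        d = (ll_new + lp_new) - (ll_cur + lp_cur)
        accept = np.log(rng.random(mw.shape)) < d
        state["mw"] = np.where(accept, prop, mw)
        acc["mw"] += accept
        if sp.kind == "hierarchical_gaussian":
            self._gibbs_mw_hyper(state)

    def _mw_log_prior(self, mw, state):
        sp = self.spec
        if sp.kind == "uniform_range":
            lo, hi = sp.low * self.M, sp.high * self.M
            return np.where((mw >= lo) & (mw <= hi), 0.0, -np.inf)
        # hierarchical_gaussian
        mu = state["mu_mw"][:, None]
        s2 = state["s2mw"][:, None]
        return -0.5 * (mw - mu) ** 2 / s2

    def _gibbs_mw_hyper(self, state):
        rng = self.rng
        mw = state["mw"]
        s2 = state["s2mw"]
        L = self.L
        # mu_Mw | . : Normal(mean(mw), s2/L) truncated to [M, 20M]
        mean = mw.mean(axis=1)
        sd = np.sqrt(s2 / L)
        lo = ndtr((self.M - mean) / sd)
        hi = ndtr((20.0 * self.M - mean) / sd)
        p = lo + (hi - lo) * rng.random(self.B)
        state["mu_mw"] = mean + sd * ndtri(np.clip(p, 1e-12, 1 - 1e-12))
        # sigma2_Mw | . : conjugate inverse-gamma
        ss = ((mw - state["mu_mw"][:, None]) ** 2).sum(axis=1)
        shape = 1.0 + L / 2.0
        scale = (self.M / 3.0) ** 2 + ss / 2.0
        state["s2mw"] = scale / rng.standard_gamma(shape, self.B)

    def _update_dndc(self, state, scales, acc):
        rng = self.rng
        pri = self.priors
        dndc = state["dndc"]
        prop = dndc + scales["dndc"] * rng.standard_normal(self.B)
        lu = state["logu"] if self.adjust else None

        def total_ll(d):
            r_mean, ct = self._r_mean(d, state["a2"], state["mw"], lu)
            ll = self._ll_r_obs(r_mean, state["s2r"]).sum(axis=1)
            if self.v.size:
                ll = ll + self._ll_dn_obs(ct, d, state["s2dn"]).sum(axis=1)
            return ll

        def lp(d):
            out = -((d - pri.mu_dn_dc) ** 2) / (2.0 * pri.sigma_dn_dc**2)
            if pri.truncate_dn_dc:
                out = np.where(d > 0, out, -np.inf)
            return out

        d = (total_ll(prop) + lp(prop)) - (total_ll(dndc) + lp(dndc))
        accept = np.log(rng.random(self.B)) < d
        state["dndc"] = np.where(accept, prop, dndc)
        acc["dndc"] += accept

    def _gibbs_s2r(self, state):
        pri = self.priors
        lu = state["logu"] if self.adjust else None
        r_mean, _ = self._r_mean(state["dndc"], state["a2"], state["mw"], lu)
        ss = ((self.r - r_mean) ** 2).sum(axis=1)
        shape = pri.a_R + self.N / 2.0
        scale = pri.ig_scale(pri.b_R) + ss / 2.0
        state["s2r"] = scale / self.rng.standard_gamma(shape, self.B)

    def _mh_s2dn(self, state):
        pri = self.priors
        rng = self.rng
        if not self.v.size:  # no RI data: sample from the prior
            state["s2dn"] = pri.ig_scale(pri.b_dn) / rng.standard_gamma(pri.a_dn, self.B)
            return
        lu = state["logu"] if self.adjust else None
        _, ct = self._r_mean(state["dndc"], state["a2"], state["mw"], lu)
        mu = ct[:, self.v] * state["dndc"][:, None]
        ss = ((self.dn - mu) ** 2).sum(axis=1)
        shape = pri.a_dn + self.v.size / 2.0
        scale = pri.ig_scale(pri.b_dn) + ss / 2.0
        prop = scale / rng.standard_gamma(shape, self.B)
        cur = state["s2dn"]
        # correction for the truncated-Gaussian normalisation Φ(μ/σ)
        corr = (
            log_ndtr(mu / np.sqrt(cur)[:, None]).sum(axis=1)
            - log_ndtr(mu / np.sqrt(prop)[:, None]).sum(axis=1)
        )
        accept = np.log(rng.random(self.B)) < corr
        state["s2dn"] = np.where(accept, prop, cur)

    def _gibbs_s2u(self, state):
        pri = self.priors
        ss = (state["logu"] ** 2).sum(axis=1)
        shape = pri.a_u + self.N / 2.0
        scale = pri.ig_scale(pri.b_u) + ss / 2.0
        state["s2u"] = scale / self.rng.standard_gamma(shape, self.B)


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

_NAME_MAP = {
    "a2": "A2", "dndc": "dn_dc", "s2r": "sigma2_R", "s2dn": "sigma2_dn",
    "s2u": "sigma2_u", "mw": "Mw", "mu_mw": "mu_Mw", "s2mw": "sigma2_Mw",
    "logu": "log_u",
}


def run_mcmc(
    dataset: ExperimentDataset,
    priors: PriorConfig,
    settings: MCMCSettings = MCMCSettings(),
    store_u: bool = True,
) -> PosteriorDraws:
    """Sample the posterior for one dataset; reproducible for a fixed seed."""
    eng = _Engine(_batch_from_dataset(dataset), priors, settings, store_u=store_u)
    out, dev, rates = eng.run()
    params = {_NAME_MAP[k]: v for k, v in out.items()}  # (C, T, ...) since D = 1
    diags = {"acceptance": rates}
    if priors.oligomer.kind == "fixed_multiple":
        diags["fixed_mw"] = priors.oligomer.x * dataset.constants.monomer_mass
    return PosteriorDraws(params=params, deviance=dev, settings=settings,
                          diagnostics=diags)


def fit_batch(
    batch_c_m: np.ndarray,
    batch_r_m: np.ndarray,
    batch_dn_m: np.ndarray,
    valid: np.ndarray,
    cond_idx: np.ndarray,
    n0: np.ndarray,
    constants,
    priors: PriorConfig,
    settings: MCMCSettings,
):
    """Fit D independent same-design datasets in one vectorised pass.

    Returns (params, deviance) with leading axes (D, C, T, ...). Used by
    the simulation study, where hundreds of structurally identical fits
    would otherwise dominate runtime.
    """
    batch = _Batch(batch_c_m, batch_r_m, batch_dn_m, np.asarray(valid, bool),
                   np.asarray(cond_idx, int), np.atleast_1d(n0), constants)
    eng = _Engine(batch, priors, settings, store_u=False)
    out, dev, _ = eng.run()
    D, C, T = batch_c_m.shape[0], settings.chains, settings.n_stored
    params = {
        _NAME_MAP[k]: v.reshape(D, C, T, *v.shape[2:]) for k, v in out.items()
    }
    return params, dev.reshape(D, C, T)


# ---------------------------------------------------------------------------
# diagnostics, DIC, summaries
# ---------------------------------------------------------------------------


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential scale reduction factor R̂ per scalar parameter.

    Classic (Brooks–)Gelman–Rubin: with C chains of length n, W the mean
    within-chain variance and B_n the variance of the chain means,
    R̂ = sqrt(var⁺/W) where var⁺ = (n−1)/n·W + B_n. Identical chains give
    R̂ = sqrt((n−1)/n) ≤ 1.
    """
    items = draws.scalar_items() if isinstance(draws, PosteriorDraws) else draws.items()
    out = {}
    for label, a in items:
        a = np.asarray(a, float)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 10:
            raise ValueError("need >= 2 chains with >= 10 stored iterations")
        out[label] = _rhat(a)
    return out


def _rhat(a: np.ndarray) -> float:
    c, n = a.shape
    means = a.mean(axis=1)
    w = a.var(axis=1, ddof=1).mean()
    b_n = means.var(ddof=1)  # = B/n in the classic notation
    var_plus = (n - 1) / n * w + b_n
    if w == 0:
        return 1.0 if b_n == 0 else np.inf
    return float(np.sqrt(var_plus / w))


def dic(
    draws: PosteriorDraws | np.ndarray,
    variant: str = "var",
    dataset: ExperimentDataset | None = None,
    priors: PriorConfig | None = None,
) -> tuple[float, float, float]:
    """Deviance Information Criterion from the stored deviance trace.

    Returns (DIC, pD, mean deviance). The default effective-parameter
    count is pD = var(deviance)/2; ``variant='mean'`` uses the classic
    pD = D̄ − D(θ̄) with the deviance evaluated at posterior means of the
    continuous parameters (requires ``dataset`` and ``priors``).
    """
    dev = draws.deviance if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    dev = dev.ravel()
    dbar = float(dev.mean())
    if variant == "var":
        if dev.size < 2:
            raise ValueError("variance-based pD needs >= 2 deviance samples")
        pd_ = float(dev.var(ddof=1) / 2.0)
    elif variant == "mean":
        if not isinstance(draws, PosteriorDraws) or dataset is None or priors is None:
            raise ValueError("variant='mean' requires draws, dataset and priors")
        pd_ = dbar - _deviance_at_mean(draws, dataset, priors)
    else:
        raise ValueError("variant must be 'var' or 'mean'")
    return dbar + pd_, pd_, dbar


def _deviance_at_mean(draws: PosteriorDraws, dataset, priors) -> float:
    p = draws.params
    u = None
    s2u = None
    if "log_u" in p:
        u = np.exp(p["log_u"].reshape(-1, p["log_u"].shape[-1]).mean(axis=0))
    if "sigma2_u" in p:
        s2u = float(draws.pooled("sigma2_u").mean())
    mw = draws.pooled("Mw").mean(axis=0) if "Mw" in p else None
    if mw is None:
        mw = np.full(dataset.n_conditions, priors.oligomer.x * dataset.constants.monomer_mass)
    params = ModelParameters(
        A2=draws.pooled("A2").mean(axis=0),
        dn_dc=float(draws.pooled("dn_dc").mean()),
        Mw=mw,
        sigma2_R=float(draws.pooled("sigma2_R").mean()),
        sigma2_dn=float(draws.pooled("sigma2_dn").mean()),
        u=u,
        sigma2_u=s2u,
    )
    return -2.0 * mdl.log_likelihood(dataset, params)


@dataclass
class FitSummary:
    """Posterior summary table plus model-level diagnostics."""

    table: pd.DataFrame  # index: parameter label; mean, sd, q2.5, q97.5
    p_a2_positive: np.ndarray  # per condition
    rhat: dict[str, float]
    dic: float | None = None
    model_name: str | None = None

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="index"),
            "p_a2_positive": list(map(float, self.p_a2_positive)),
            "rhat": self.rhat,
            "dic": self.dic,
            "model_name": self.model_name,
        }


def posterior_summary(draws: PosteriorDraws, compute_dic: bool = True) -> FitSummary:
    """Moments, type-7 empirical 95% quantiles and P(A2>0) per condition,
    pooled over chains."""
    rows = {}
    rhat = {}
    for label, a in draws.scalar_items():
        pooled = a.ravel()
        if pooled.size < 2:
            raise ValueError("need >= 2 stored draws")
        rows[label] = {
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)),
            "q2.5": float(np.quantile(pooled, 0.025)),
            "q97.5": float(np.quantile(pooled, 0.975)),
        }
        if a.shape[0] >= 2 and a.shape[1] >= 10:
            rhat[label] = _rhat(a)
    a2 = draws.pooled("A2")
    p_pos = (a2 > 0).mean(axis=0)
    d = dic(draws)[0] if (compute_dic and draws.deviance.size >= 2) else None
    return FitSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        p_a2_positive=np.atleast_1d(p_pos),
        rhat=rhat,
        dic=d,
    )


def select_model(
    dataset: ExperimentDataset,
    candidates: list[tuple[str, OligomerSpec]],
    priors: PriorConfig,
    settings: MCMCSettings = MCMCSettings(),
) -> list[tuple[str, float]]:
    """Fit every candidate oligomer spec and rank by ascending DIC.

    Ties are preserved in the returned ordering, not broken.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    results = []
    for name, spec in candidates:
        pri = dataclasses.replace(priors, oligomer=spec)
        draws = run_mcmc(dataset, pri, settings, store_u=False)
        results.append((name, dic(draws)[0]))
    return sorted(results, key=lambda t: t[1])


def posterior_predictive_check(
    draws: PosteriorDraws,
    dataset: ExperimentDataset,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicated detector readings at each stored state.

    For every observation, replicated R^m (and Δn^m where RI-valid) are
    drawn from the observation model at each posterior draw; the report
    gives the central 95% predictive interval and whether the measured
    value falls inside. The ``inside`` column's mean is the overall
    predictive coverage.
    """
    rng = np.random.default_rng(seed)
    p = draws.params
    a2 = draws.pooled("A2")  # (S, L)
    dndc = draws.pooled("dn_dc")  # (S,)
    s2r = draws.pooled("sigma2_R")
    s2dn = draws.pooled("sigma2_dn")
    S = dndc.shape[0]
    if "Mw" in p:
        mw = draws.pooled("Mw")
    else:
        fixed = draws.diagnostics.get("fixed_mw", dataset.constants.monomer_mass)
        mw = np.full((S, dataset.n_conditions), fixed)
    if "log_u" in p:
        u = np.exp(draws.pooled("log_u"))  # (S, N)
    else:
        u = np.ones((S, dataset.n_obs))

    kstar0 = (4.0 * math.pi**2 * dataset.n0[dataset.cond_idx] ** 2
              / (dataset.constants.avogadro * dataset.constants.wavelength**4))
    ct = dataset.c_measured[None, :] * u
    kst = kstar0[None, :] * dndc[:, None] ** 2
    a2o = a2[:, dataset.cond_idx]
    mwo = mw[:, dataset.cond_idx]
    r_mean = kst * mwo * ct * (1 - 2 * a2o * mwo * ct)
    r_rep = rng.normal(r_mean, np.sqrt(s2r)[:, None])
    rows = []
    dn_mean = ct * dndc[:, None]
    for i in range(dataset.n_obs):
        lo, hi = np.quantile(r_rep[:, i], [0.025, 0.975])
        obs = dataset.rayleigh[i]
        rows.append({"obs": i, "signal": "LS", "lo": lo, "hi": hi,
                     "observed": obs, "inside": bool(lo <= obs <= hi)})
        if dataset.ri_valid[i]:
            dn_rep = rng.normal(dn_mean[:, i], np.sqrt(s2dn))
            dn_rep = np.abs(dn_rep)  # negligible-mass reflection at 0
            lo, hi = np.quantile(dn_rep, [0.025, 0.975])
            obs = dataset.delta_n[i]
            rows.append({"obs": i, "signal": "RI", "lo": lo, "hi": hi,
                         "observed": obs, "inside": bool(lo <= obs <= hi)})
    return pd.DataFrame(rows)
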