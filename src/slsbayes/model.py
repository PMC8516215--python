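"""Probabilistic model for multi-condition static light scattering data.

The data are L solution conditions (pH/ionic strength), each observed at I
concentration levels. Per (condition l, level i) the instruments report a
measured concentration ``c_m`` (UV absorbance), an excess Rayleigh ratio
``R_m`` (light-scattering detector at 90°) and, where the refractometer is
within its working range, a refractive-index difference ``dn_m``.

Observation model
-----------------
    R_m[il]  ~ Normal( R(c[il]; Mw[l], A2[l], K*[l]),  sigma2_R )
    dn_m[il] ~ TruncNormal_[0,∞)( c[il]·dn/dc,         sigma2_dn )

with the true concentration related to the measured one through a
multiplicative Berkson error

    c[il] = c_m[il] · u[il],      u[il] ~ iid LogNormal(0, sigma2_u).

Priors: Gaussian (optionally zero-truncated) on dn/dc, inverse-gamma on
the three variances, iid Gaussian on the per-condition A2, and one of
several oligomer-state specifications on Mw (fixed x-mer, Bernoulli
monomer/dimer switch, uniform range, or hierarchical Gaussian).

Everything here is an evaluable log-density over an explicit latent state;
sampling lives in :mod:`slsbayes.inference`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

from .physics import PhysicalConstants, material_constant, true_delta_n, true_rayleigh

__all__ = [
    "ExperimentDataset",
    "ModelParameters",
    "OligomerSpec",
    "PriorConfig",
    "log_likelihood",
    "log_prior",
    "no_adjustment_variant",
    "enumerate_candidates",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDataset:
    """Processed per-level measurements for L conditions x I levels.

    Arrays are flat over observations; ``cond_idx`` maps each observation to
    its condition. ``delta_n`` is NaN wherever ``ri_valid`` is False (the
    refractometer out of range); those cells contribute no likelihood term.
    """

    c_measured: np.ndarray  # (N,) g/mL, > 0
    rayleigh: np.ndarray  # (N,) 1/cm
    delta_n: np.ndarray  # (N,) dimensionless, NaN where not ri_valid
    ri_valid: np.ndarray  # (N,) bool
    cond_idx: np.ndarray  # (N,) int in [0, L)
    n0: np.ndarray  # (L,) solvent refractive index per condition
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    condition_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.c_measured = np.asarray(self.c_measured, dtype=float)
        self.rayleigh = np.asarray(self.rayleigh, dtype=float)
        self.delta_n = np.asarray(self.delta_n, dtype=float)
        self.ri_valid = np.asarray(self.ri_valid, dtype=bool)
        self.cond_idx = np.asarray(self.cond_idx, dtype=int)
        self.n0 = np.atleast_1d(np.asarray(self.n0, dtype=float))
        n = self.c_measured.shape[0]
        for name in ("rayleigh", "delta_n", "ri_valid", "cond_idx"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch with c_measured")
        if np.any(self.c_measured <= 0):
            raise ValueError("measured concentrations must be positive")
        if np.any(~np.isfinite(self.rayleigh)):
            raise ValueError("Rayleigh ratios must all be present and finite")
        if self.cond_idx.min() < 0 or self.cond_idx.max() >= self.n_conditions:
            raise ValueError("cond_idx out of range for n0")
        valid = self.ri_valid
        if np.any(~np.isfinite(self.delta_n[valid])):
            raise ValueError("delta_n missing on an ri_valid observation")
        if self.condition_ids is None:
            self.condition_ids = [f"cond{j}" for j in range(self.n_conditions)]

    @property
    def n_obs(self) -> int:
        return self.c_measured.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.n0.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-observation table (the CSV interchange schema)."""
        return pd.DataFrame(
            {
                "condition_id": [self.condition_ids[j] for j in self.cond_idx],
                "c_measured_g_per_mL": self.c_measured,
                "rayleigh_1_per_cm": self.rayleigh,
                "delta_n": np.where(self.ri_valid, self.delta_n, np.nan),
                "ri_valid": self.ri_valid,
            }
        )

    def drop_observation(self, i: int) -> "ExperimentDataset":
        keep = np.ones(self.n_obs, dtype=bool)
        keep[i] = False
        return ExperimentDataset(
            self.c_measured[keep],
            self.rayleigh[keep],
            self.delta_n[keep],
            self.ri_valid[keep],
            self.cond_idx[keep],
            self.n0,
            self.constants,
            self.condition_ids,
        )


# ---------------------------------------------------------------------------
# latent state and priors
# ---------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """One complete latent state of the model."""

    A2: np.ndarray  # (L,) mL·mol/g²
    dn_dc: float  # mL/g
    Mw: np.ndarray  # (L,) g/mol
    sigma2_R: float
    sigma2_dn: float
    u: np.ndarray | None = None  # (N,) positive multipliers; None = no adjustment
    sigma2_u: float | None = None
    k: np.ndarray | None = None  # (L,) in {0,1} for the Bernoulli dimer spec
    mu_Mw: float | None = None  # hierarchical-spec hyperparameters
    sigma2_Mw: float | None = None

    def __post_init__(self) -> None:
        self.A2 = np.atleast_1d(np.asarray(self.A2, dtype=float))
        self.Mw = np.atleast_1d(np.asarray(self.Mw, dtype=float))
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)


@dataclass(frozen=True)
class OligomerSpec:
    """Specification of the oligomer (aggregation) state of the scatterer.

    kind:
      * ``fixed_multiple`` — monodisperse x-mer, Mw = x·M exactly.
      * ``bernoulli_dimer`` — per-condition latent k in {0,1},
        Mw = (k+1)·M, k ~ Bernoulli(1/2).
      * ``uniform_range``   — per-condition Mw ~ Uniform(low·M, high·M).
      * ``hierarchical_gaussian`` — Mw ~ Normal(mu_Mw, sigma2_Mw) with
        mu_Mw ~ Uniform(M, 20M) and sigma2_Mw ~ InvGamma(1, (M/3)²).
    """

    kind: str = "fixed_multiple"
    x: int = 1
    low: float = 1.0
    high: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in (
            "fixed_multiple",
            "bernoulli_dimer",
            "uniform_range",
            "hierarchical_gaussian",
        ):
            raise ValueError(f"unknown oligomer kind {self.kind!r}")
        if self.kind == "fixed_multiple" and (self.x < 1 or self.x != int(self.x)):
            raise ValueError("fixed_multiple requires integer x >= 1")
        if self.kind == "uniform_range" and not self.low < self.high:
            raise ValueError("uniform_range requires low < high")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of all priors plus the concentration-adjustment flag.

    Inverse-gamma pairs (a, b) use the shape/scale convention by default
    (density ∝ x^{-(a+1)} e^{-b/x}, so b sets the typical magnitude of the
    variance); set ``ig_parameterization='rate'`` to read b as 1/scale.
    """

    mu_dn_dc: float = 0.1970
    sigma_dn_dc: float = 0.005
    truncate_dn_dc: bool = True
    a_R: float = 1.0
    b_R: float = 1e-10  # (10⁻⁵)²
    a_dn: float = 1.0
    b_dn: float = 1e-8  # (10⁻⁴)²
    a_u: float = 1.0
    b_u: float = (math.log(1.05) / 1.96) ** 2
    mu_A2: float = 0.0
    sigma_A2: float = 1.0
    adjust_concentration: bool = True
    oligomer: OligomerSpec = field(default_factory=OligomerSpec)
    ig_parameterization: str = "scale"

    def __post_init__(self) -> None:
        for name in ("sigma_dn_dc", "a_R", "b_R", "a_dn", "b_dn", "a_u", "b_u", "sigma_A2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.ig_parameterization not in ("scale", "rate"):
            raise ValueError("ig_parameterization must be 'scale' or 'rate'")

    def ig_scale(self, b: float) -> float:
        return b if self.ig_parameterization == "scale" else 1.0 / b


# ---------------------------------------------------------------------------
# density helpers
# ---------------------------------------------------------------------------


def _normal_logpdf(x, mu, sigma2):
    return -0.5 * (_LOG_2PI + np.log(sigma2) + (x - mu) ** 2 / sigma2)


def _truncnorm0_logpdf(x, mu, sigma2):
    """log density of Normal(mu, sigma2) truncated to [0, ∞)."""
    sigma = np.sqrt(sigma2)
    out = _normal_logpdf(x, mu, sigma2) - log_ndtr(mu / sigma)
    return np.where(np.asarray(x) >= 0, out, -np.inf)


def _invgamma_logpdf(x, a, scale):
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, -np.inf, dtype=float)
    pos = x > 0
    out = np.where(
        pos,
        a * np.log(scale) - gammaln(a) - (a + 1.0) * np.log(np.where(pos, x, 1.0))
        - scale / np.where(pos, x, 1.0),
        out,
    )
    return out


def condition_kstar(dataset: ExperimentDataset, dn_dc: float) -> np.ndarray:
    """Per-condition optical constant K*(n0[l], dn/dc)."""
    consts = dataset.constants
    return np.array(
        [
            material_constant(dn_dc, dataclasses.replace(consts, solvent_index=float(n)))
            for n in dataset.n0
        ]
    )


def predicted_means(dataset: ExperimentDataset, params: ModelParameters):
    """Model means (R, Δn) per observation at the given latent state."""
    u = params.u if params.u is not None else np.ones(dataset.n_obs)
    c_true = dataset.c_measured * u
    kstar = condition_kstar(dataset, params.dn_dc)[dataset.cond_idx]
    mw = params.Mw[dataset.cond_idx]
    a2 = params.A2[dataset.cond_idx]
    r_mean = true_rayleigh(c_true, mw, a2, kstar)
    dn_mean = true_delta_n(c_true, params.dn_dc)
    return r_mean, dn_mean


# ---------------------------------------------------------------------------
# log-likelihood and log-prior
# ---------------------------------------------------------------------------


def log_likelihood(dataset: ExperimentDataset, params: ModelParameters) -> float:
    """Joint log-density of all LS and (valid) RI observations.

    The Rayleigh terms are Gaussian; the RI terms are zero-truncated
    Gaussian including the parameter-dependent normalisation Φ(Δn/σ_Δn).
    Observations with ``ri_valid`` False contribute no RI term
    (missing-at-random by instrument range).
    """
    if not (params.sigma2_R > 0 and params.sigma2_dn > 0):
        raise ValueError("observation variances must be positive")
    r_mean, dn_mean = predicted_means(dataset, params)
    ll = float(np.sum(_normal_logpdf(dataset.rayleigh, r_mean, params.sigma2_R)))
    v = dataset.ri_valid
    if v.any():
        ll += float(
            np.sum(
                _truncnorm0_logpdf(dataset.delta_n[v], dn_mean[v], params.sigma2_dn)
            )
        )
    return ll


def log_prior(
    params: ModelParameters, priors: PriorConfig, constants: PhysicalConstants
) -> float:
    """Joint log prior density of the latent state; −∞ outside support."""
    lp = 0.0
    # dn/dc
    if priors.truncate_dn_dc:
        lp += float(
            _truncnorm0_logpdf(params.dn_dc, priors.mu_dn_dc, priors.sigma_dn_dc**2)
        )
    else:
        lp += float(_normal_logpdf(params.dn_dc, priors.mu_dn_dc, priors.sigma_dn_dc**2))
    # observation variances
    lp += float(
        _invgamma_logpdf(params.sigma2_R, priors.a_R, priors.ig_scale(priors.b_R))
    )
    lp += float(
        _invgamma_logpdf(params.sigma2_dn, priors.a_dn, priors.ig_scale(priors.b_dn))
    )
    # A2
    lp += float(np.sum(_normal_logpdf(params.A2, priors.mu_A2, priors.sigma_A2**2)))
    # Berkson multipliers
    if priors.adjust_concentration:
        if params.u is None or params.sigma2_u is None:
            raise ValueError("adjust_concentration=True requires u and sigma2_u")
        if params.sigma2_u <= 0 or np.any(params.u <= 0):
            return -np.inf
        lp += float(
            _invgamma_logpdf(params.sigma2_u, priors.a_u, priors.ig_scale(priors.b_u))
        )
        logu = np.log(params.u)
        # LogNormal(0, sigma2_u) density of u (includes the 1/u Jacobian)
        lp += float(
            np.sum(_normal_logpdf(logu, 0.0, params.sigma2_u) - logu)
        )
    # oligomer state
    lp += _oligomer_log_prior(params, priors.oligomer, constants)
    return lp


def _oligomer_log_prior(
    params: ModelParameters, spec: OligomerSpec, constants: PhysicalConstants
) -> float:
    m = constants.monomer_mass
    mw = params.Mw
    if spec.kind == "fixed_multiple":
        target = spec.x * m
        return 0.0 if np.allclose(mw, target, rtol=1e-12) else -np.inf
    if spec.kind == "bernoulli_dimer":
        if params.k is None:
            raise ValueError("bernoulli_dimer requires the discrete state k")
        k = np.asarray(params.k)
        if np.any((k != 0) & (k != 1)):
            return -np.inf
        if not np.allclose(mw, (k + 1) * m, rtol=1e-12):
            return -np.inf
        return float(len(k)) * math.log(0.5)
    if spec.kind == "uniform_range":
        lo, hi = spec.low * m, spec.high * m
        if np.any(mw < lo) or np.any(mw > hi):
            return -np.inf
        return -float(len(mw)) * math.log(hi - lo)
    # hierarchical_gaussian
    if params.mu_Mw is None or params.sigma2_Mw is None:
        raise ValueError("hierarchical_gaussian requires mu_Mw and sigma2_Mw")
    if not (m <= params.mu_Mw <= 20.0 * m) or params.sigma2_Mw <= 0:
        return -np.inf
    lp = -math.log(19.0 * m)  # Uniform(M, 20M) on mu_Mw
    lp += float(_invgamma_logpdf(params.sigma2_Mw, 1.0, (m / 3.0) ** 2))
    lp += float(np.sum(_normal_logpdf(mw, params.mu_Mw, params.sigma2_Mw)))
    return lp


def no_adjustment_variant(priors: PriorConfig) -> PriorConfig:
    """The comparison model that treats measured concentration as true.

    Under it u ≡ 1 and sigma2_u leaves the latent state; the likelihood is
    that of the full model evaluated at u = 1.
    """
    return dataclasses.replace(priors, adjust_concentration=False)


def enumerate_candidates(mode: str, monomer_mass: float) -> list[tuple[str, OligomerSpec]]:
    """Candidate oligomer-state models for model selection.

    ``mode='lysozyme'`` yields the monomer/dimer family M1–M4;
    ``mode='hgs'`` yields the 1–20-mer ladder Mx plus a uniform-range and a
    hierarchical polydisperse alternative (22 candidates).
    """
    if not monomer_mass > 0:
        raise ValueError("monomer_mass must be positive")
    if mode == "lysozyme":
        return [
            ("M1", OligomerSpec("fixed_multiple", x=1)),
            ("M2", OligomerSpec("fixed_multiple", x=2)),
            ("M3", OligomerSpec("bernoulli_dimer")),
            ("M4", OligomerSpec("uniform_range", low=1.0, high=2.0)),
        ]
    if mode == "hgs":
        cands = [(f"M{x}", OligomerSpec("fixed_multiple", x=x)) for x in range(1, 21)]
        cands.append(("M21", OligomerSpec("uniform_range", low=1.0, high=20.0)))
        cands.append(("M22", OligomerSpec("hierarchical_gaussian")))
        return cands
    raise ValueError(f"unknown mode {mode!r}; expected 'lysozyme' or 'hgs'")
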