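"""Generate SLS datasets from the generative model itself.

The in-house lysozyme and γS-crystallin measurements behind the case
studies are not public, so synthetic data drawn from the model are the
test bed for everything downstream: a design of I nominal concentration
levels (with the refractometer valid only below a cutoff), Gaussian noise
on the Rayleigh ratio, zero-truncated Gaussian noise on the RI difference,
and a multiplicative lognormal Berkson error linking nominal to true
concentration.

Defaults reproduce the simulation-study conditions: the 14-level
2.5–50 mg/mL lysozyme dilution series with the 8 lowest levels RI-valid,
monomeric lysozyme (M = 14307 g/mol), dn/dc = 0.20 mL/g, n0 = 1.33,
sigma2_R = 1e-11, sigma2_dn = 2e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ExperimentDataset, OligomerSpec, PriorConfig
from .physics import PhysicalConstants, material_constant, true_delta_n, true_rayleigh

__all__ = [
    "LYSOZYME_LEVELS_MG_PER_ML",
    "TruthConfig",
    "DesignConfig",
    "error_level_to_sigma2_u",
    "generate_dataset",
    "prior_treatment",
    "simulation_priors",
]

#: Nominal lysozyme dilution series (mg/mL); the first 8 are RI-valid.
LYSOZYME_LEVELS_MG_PER_ML = (
    2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0
)
_RI_CUTOFF_MG_PER_ML = 20.0


def error_level_to_sigma2_u(percent: float) -> float:
    """Log-scale Berkson variance for a given percent concentration error.

    sigma2_u = (log(1 + p/100) / 1.96)², calibrated so that the true
    concentration lies within ±p% of the measured one with ≈95%
    probability under the lognormal multiplier.
    """
    if not percent > 0:
        raise ValueError("percent must be positive")
    return (math.log(1.0 + percent / 100.0) / 1.96) ** 2


@dataclass(frozen=True)
class TruthConfig:
    """Generating ('true') parameter values for one synthetic experiment."""

    A2: tuple[float, ...] = (1e-4,)  # one entry per condition
    dn_dc: float = 0.20
    Mw_multiple: float = 1.0  # Mw = multiple × monomer mass, per condition
    sigma2_R: float = 1e-11
    sigma2_dn: float = 2e-9
    sigma2_u: float = error_level_to_sigma2_u(5.0)
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def mw(self) -> float:
        return self.Mw_multiple * self.constants.monomer_mass


@dataclass(frozen=True)
class DesignConfig:
    """Measurement design: nominal levels, RI validity, replication."""

    levels_mg_per_ml: tuple[float, ...] = LYSOZYME_LEVELS_MG_PER_ML
    ri_cutoff_mg_per_ml: float = _RI_CUTOFF_MG_PER_ML
    n_conditions: int = 1
    replicates: int = 1

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels_mg_per_ml, dtype=float)
        if np.any(lv <= 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be positive and strictly increasing")
        if self.n_conditions < 1 or self.replicates < 1:
            raise ValueError("n_conditions and replicates must be >= 1")

    @property
    def levels_g_per_ml(self) -> np.ndarray:
        return np.asarray(self.levels_mg_per_ml, dtype=float) / 1000.0

    @property
    def ri_valid_mask(self) -> np.ndarray:
        lv = np.asarray(self.levels_mg_per_ml, dtype=float)
        return lv <= self.ri_cutoff_mg_per_ml


def _draw_truncnorm0(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Rejection sampler for Normal(mean, sd²) truncated to [0, ∞).

    The RI means sit many sd above zero in every realistic design, so the
    expected number of redraws is negligible.
    """
    out = rng.normal(mean, sd)
    bad = out < 0
    while np.any(bad):
        out[bad] = rng.normal(mean[bad], sd)
        bad = out < 0
    return out


def generate_dataset(
    truth: TruthConfig,
    design: DesignConfig = DesignConfig(),
    seed: int | np.random.Generator = 0,
) -> ExperimentDataset:
    """Draw one complete dataset from the generative model.

    For every condition, replicate and level: u ~ LogNormal(0, sigma2_u),
    the true concentration is nominal×u, the Rayleigh ratio is Gaussian
    about the forward-model value and the RI difference (where valid) is
    zero-truncated Gaussian. Setting all variances to zero recovers the
    noiseless forward model exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(truth.A2) != design.n_conditions:
        raise ValueError("need one true A2 per condition")
    consts = truth.constants
    levels = design.levels_g_per_ml
    mask = design.ri_valid_mask
    n_per_run = levels.size

    kstar = material_constant(truth.dn_dc, consts)
    mw = truth.mw()
    sd_r = math.sqrt(truth.sigma2_R)
    sd_dn = math.sqrt(truth.sigma2_dn)
    sd_u = math.sqrt(truth.sigma2_u)

    c_m, r_m, dn_m, valid, cond = [], [], [], [], []
    for l in range(design.n_conditions):
        for _ in range(design.replicates):
            u = np.exp(rng.normal(0.0, sd_u, size=n_per_run)) if sd_u > 0 else np.ones(n_per_run)
            c_true = levels * u
            r_mean = true_rayleigh(c_true, mw, truth.A2[l], kstar)
            dn_mean = true_delta_n(c_true, truth.dn_dc)
            r_obs = rng.normal(r_mean, sd_r) if sd_r > 0 else r_mean
            dn_obs = np.full(n_per_run, np.nan)
            if sd_dn > 0:
                dn_obs[mask] = _draw_truncnorm0(rng, dn_mean[mask], sd_dn)
            else:
                dn_obs[mask] = dn_mean[mask]
            c_m.append(levels)
            r_m.append(r_obs)
            dn_m.append(dn_obs)
            valid.append(mask)
            cond.append(np.full(n_per_run, l))

    return ExperimentDataset(
        c_measured=np.concatenate(c_m),
        rayleigh=np.concatenate(r_m),
        delta_n=np.concatenate(dn_m),
        ri_valid=np.concatenate(valid),
        cond_idx=np.concatenate(cond),
        n0=np.full(design.n_conditions, consts.solvent_index),
        constants=consts,
    )


def simulation_priors() -> PriorConfig:
    """Priors held fixed across the simulation study.

    dn/dc ~ Normal(0.195, 0.005²) — deliberately centred 1 sd off the
    generating value 0.20; sigma2_R ~ IG(1, 1e-10); sigma2_dn ~ IG(1, 1e-8);
    A2 ~ Normal(0, 1); monomer model.
    """
    return PriorConfig(
        mu_dn_dc=0.195,
        sigma_dn_dc=0.005,
        truncate_dn_dc=False,
        a_R=1.0,
        b_R=1e-10,
        a_dn=1.0,
        b_dn=1e-8,
        oligomer=OligomerSpec("fixed_multiple", x=1),
    )


def prior_treatment(
    name: str,
    true_sigma2_u: float | None = None,
    base: PriorConfig | None = None,
    informative_variant: str = "inverse_chi2",
) -> PriorConfig:
    """Concentration-error prior treatments of the simulation study.

    * ``informative`` — inverse-χ² centred on the truth:
      IG(shape = 1 + 1/(2·sigma2_u), scale = 1/2), whose mean is exactly
      the true sigma2_u and which tightens as sigma2_u shrinks. A looser
      mean-matched alternative IG(2, sigma2_u) is available via
      ``informative_variant='mean_matched'``.
    * ``intermediate`` — IG(1, sigma2_u): mass concentrated near the truth
      but heavy-tailed.
    * ``weak`` — IG(1, (log 1.40 / 1.96)²): anchored at a 40% relative
      error upper bound, regardless of the truth.
    * ``none`` — no adjustment: measured concentration treated as true.
    """
    import dataclasses

    if base is None:
        base = simulation_priors()
    if name == "none":
        return dataclasses.replace(base, adjust_concentration=False)
    if name == "weak":
        return dataclasses.replace(
            base, a_u=1.0, b_u=(math.log(1.40) / 1.96) ** 2, adjust_concentration=True
        )
    if true_sigma2_u is None or not true_sigma2_u > 0:
        raise ValueError(f"treatment {name!r} requires the true sigma2_u")
    if name == "intermediate":
        return dataclasses.replace(
            base, a_u=1.0, b_u=float(true_sigma2_u), adjust_concentration=True
        )
    if name == "informative":
        if informative_variant == "inverse_chi2":
            a = 1.0 + 1.0 / (2.0 * true_sigma2_u)
            b = 0.5
        elif informative_variant == "mean_matched":
            a, b = 2.0, float(true_sigma2_u)
        else:
            raise ValueError(f"unknown informative_variant {informative_variant!r}")
        return dataclasses.replace(base, a_u=a, b_u=b, adjust_concentration=True)
    raise ValueError(
        f"unknown treatment {name!r}; expected informative/intermediate/weak/none"
    )
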