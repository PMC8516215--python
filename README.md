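# slsbayes

Bayesian analysis of static light scattering (SLS) experiments on
globular proteins: joint posterior inference for the second virial
coefficient **A₂**, the refractive-index increment **dn/dc**, the
oligomer state of the scatterer (**M_w**) and the instrument noise
levels, with explicit modelling of concentration measurement error.

## Who this is for

SLS is a bench-top technique for measuring protein–protein interaction
propensity: the sign of A₂ separates net-repulsive (aggregation-
resistant) from net-attractive (aggregation-prone) solution conditions.
The classical analysis — the Zimm plot, a graphical double
extrapolation — gives no usable uncertainty estimates and is fragile to
errors in the measured concentrations, which enter every other
estimate. `slsbayes` replaces it with a full generative model fitted by
MCMC, for anyone running dilution-series SLS + refractometry
experiments on small (P(r_g, θ) ≈ 1) proteins.

## The model

For condition *l* and concentration level *i*, with
K\* = 4π²n₀²(dn/dc)²/(N_A λ⁴):

    R_m[il]  ~ Normal( K*·Mw[l]·c[il]·(1 − 2·A2[l]·Mw[l]·c[il]),  σ²_R )
    Δn_m[il] ~ TruncNormal_[0,∞)( c[il]·dn/dc,  σ²_Δn )      (where RI-valid)
    c[il]    = c_m[il] · u[il],   u[il] ~ iid LogNormal(0, σ²_u)

The last line is a multiplicative **Berkson** error: the true
concentration scatters around the measured one, reflecting losses that
occur *after* the UV-absorbance measurement (filters, adhesion, liquid
handling). Priors: Gaussian (optionally zero-truncated) on dn/dc,
inverse-gamma on the three variances, N(0, 1) on each A₂ (flat over the
physical range |A₂| ≲ 10⁻²), and one of several oligomer-state
specifications on M_w (fixed x-mer, Bernoulli monomer/dimer switch,
uniform range, hierarchical Gaussian), compared by DIC. A "no
adjustment" variant (u ≡ 1) is included as the Bayesian analogue of
fitting nominal concentrations directly. See `docs/methods.md` for the
full account, including the sampler.

## Worked example

Generate a dilution-series dataset from the model (14 levels,
2.5–50 mg/mL, RI valid up to 20 mg/mL, 5% concentration error,
A₂ = 10⁻⁴ mL·mol/g²) and fit it back:

```python
import slsbayes as s

truth = s.TruthConfig(A2=(1e-4,), sigma2_u=s.error_level_to_sigma2_u(5.0))
data = s.generate_dataset(truth, s.DesignConfig(replicates=1), seed=42)

priors = s.prior_treatment("informative", truth.sigma2_u)
settings = s.MCMCSettings(chains=4, iterations=6000, burn_in=2000, thin=2, seed=7)
draws = s.run_mcmc(data, priors, settings)

summary = s.posterior_summary(draws)
row = summary.table.loc["A2[0]"]
print(f"A2 posterior mean {row['mean']:.3e}  sd {row['sd']:.1e}  "
      f"95% CI [{row['q2.5']:.3e}, {row['q97.5']:.3e}]")
print(f"P(A2 > 0 | data) = {summary.p_a2_positive[0]:.3f}")
print(f"dn/dc posterior mean {summary.table.loc['dn_dc', 'mean']:.4f}")
print(f"max R-hat = {max(summary.rhat.values()):.3f}   DIC = {summary.dic:.1f}")
```

Output:

```
A2 posterior mean 7.411e-05  sd 2.3e-05  95% CI [2.756e-05, 1.175e-04]
P(A2 > 0 | data) = 0.999
dn/dc posterior mean 0.1979
max R-hat = 1.004   DIC = -425.0
```

The 95% credible interval covers the generating A₂ = 10⁻⁴; the posterior
probability of repulsive interactions is ≈ 1; dn/dc is recovered near
the generating 0.20 despite a prior centred at 0.197; and R̂ ≈ 1
indicates the four chains agree.

The same workflow is available from the shell:

```sh
slsbayes simulate --a2 1e-4 --error-percent 5 --seed 42 --out data.csv
slsbayes fit --data data.csv --out fit.json --seed 7
slsbayes compare --data data.csv --mode lysozyme --out dic.csv   # M1–M4 by DIC
slsbayes clean --trace trace.csv --n-levels 14 --out levels.csv  # raw traces
slsbayes simstudy --a2 1e-5 --error-percent 20 --prior informative \
    --replicates 1 --n-datasets 100 --seed 1 --out cells.csv
```

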