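# Methods

## The measurement problem

A static light scattering (SLS) experiment on a dilute solution of a
globular protein reports, per solution condition *l* (pH, ionic strength)
and concentration level *i*:

* a measured concentration `c_m[il]` (UV absorbance, g/mL),
* an excess Rayleigh ratio `R_m[il]` (90° light-scattering detector, 1/cm),
* a refractive-index difference `Δn_m[il]` (batch refractometer),
  available only while the refractometer is in range (here: nominal
  concentrations ≤ 20 mg/mL).

For small particles (radius ≪ wavelength) in dilute solution the
noise-free signals are

    R(c)  = K* · Mw · c · (1 − 2·A2·Mw·c),      K* = 4π² n0² (dn/dc)² / (N_A λ⁴)
    Δn(c) = c · (dn/dc)

with `Mw` the weight-average molar mass of the scattering particle, `A2`
the second (osmotic) virial coefficient (mL·mol/g²; positive = net
repulsion), `dn/dc` the refractive-index increment (mL/g), `n0` the
solvent index and `λ` the vacuum wavelength (657 nm here). The angular
form factor `P(r_g, θ)` is implemented but fixed to 1 downstream: for
r_g ≈ 1 nm–10 nm proteins it differs from unity by far less than the
detector noise (the package asserts < 1e-3 at r_g = 1e-7 cm).

All computations use one unit system — cm, g/mL, g/mol — and conversions
happen only at I/O boundaries, because the instrument constants are
naturally stated in those units.

## The probabilistic model

Observation model (independent across il given the latent state):

    R_m[il]  ~ Normal( R(c[il]),  σ²_R )
    Δn_m[il] ~ TruncNormal_[0,∞)( Δn(c[il]), σ²_Δn )     where RI-valid

The truncation reflects the physical non-negativity of the RI difference;
its normalisation Φ(Δn/σ_Δn) depends on the parameters and is kept
exactly, although it is numerically negligible except near the detection
limit. Missing RI observations (refractometer out of range) contribute no
likelihood term; the missingness is by instrument design, not by outcome.

The true concentration is tied to the measured one through a
multiplicative Berkson error

    c[il] = c_m[il] · u[il],     u[il] ~ iid LogNormal(0, σ²_u),

modelling post-measurement losses (filters, adhesion, transfer) that
perturb the *true* quantity around the *measured* one — the defining
feature of Berkson error, opposite in direction to classical error.

Priors: `dn/dc ~ N(μ, σ²)` (optionally truncated at 0; the case-study
default is TN(0,∞)(0.1970, 0.005²)); inverse-gamma `IG(shape, scale)` on
σ²_R, σ²_Δn, σ²_u with shapes 1 and scales set to the squared
manufacturer precision ((1e-5)², (1e-4)², (log 1.05/1.96)²); and
`A2[l] ~ iid N(0, 1)`, which is effectively flat over the physically
plausible range |A2| ≲ 1e-2. The inverse-gamma parameterization is
shape/scale (density ∝ x^−(a+1) e^(−b/x)) so that b sets the magnitude of
typical variances; a shape/rate reading is available behind a config
switch since conventions differ between toolchains.

Oligomer state: `Mw` is expressed as a multiple of the monomer mass M.
The candidate families are a fixed x-mer (x = 1, 2, … ), a per-condition
Bernoulli(½) monomer/dimer switch, a continuous Uniform(low·M, high·M),
and a hierarchical Gaussian `Mw ~ N(μ_Mw, σ²_Mw)` with
μ_Mw ~ U(M, 20M), σ²_Mw ~ IG(1, (M/3)²) for polydisperse scatterers.
`dn/dc` is a single global parameter across conditions; `n0` (and hence
K*) is per-condition.

The "no adjustment" comparison model sets u ≡ 1 and removes σ²_u from the
state — the Bayesian analogue of fitting nominal concentrations directly.

## Sampler

No probabilistic-programming backend is used; the sampler is a
vectorised Metropolis-within-Gibbs engine written directly against the
model:

* per-observation `log u[il]`: parallel random-walk MH (valid because the
  likelihood factorises over observations given the globals);
* per-condition `A2[l]` and continuous `Mw[l]`: random-walk MH;
* Bernoulli monomer/dimer state: exact 2-state Gibbs;
* hierarchical (μ_Mw, σ²_Mw): truncated-Gaussian and conjugate
  inverse-gamma Gibbs;
* `dn/dc`: global random-walk MH (enters K* quadratically and the RI mean
  linearly);
* `σ²_R`, `σ²_u`: exact conjugate inverse-gamma Gibbs;
* `σ²_Δn`: independence MH proposing from the untruncated conjugate
  posterior with an exact correction for the Φ(Δn/σ_Δn) terms (the
  proposal is accepted with probability ≈ 1 away from the detection
  limit).

Proposal scales adapt multiplicatively toward 44% acceptance every 25
iterations during burn-in and are frozen afterwards, so post-burn-in
draws come from a fixed-kernel Markov chain. Initialisation: `dn/dc` at
the prior mean, u = 1, `A2` at a per-dataset least-squares estimate of
the quadratic signal (jittered per chain), observation variances at the
initial residual mean square. Chains are run independently and pooled
after burn-in; quantiles are empirical (type-7).

Run lengths: the conservative reference protocol is 5 chains × 300 000
iterations (200 000 burn-in, thinning 250). The package default —
adequate for single-run datasets of this design and used throughout the
tests — is 3–4 chains × 6 000–9 000 iterations with thinning 2–6, gated
by the classic Gelman–Rubin R̂: simulation-study fits whose pooled-A2 R̂
exceeds 1.1 are refitted once with 3× the chain length and flagged.
Reported diagnostics include per-block acceptance rates and R̂ per scalar.

Determinism: one master seed drives a single generator for the whole
vectorised batch; simulation-study dataset seeds are derived from
(base seed, cell key, dataset index), so results are independent of cell
ordering and worker count, and scaled-down runs are prefixes of larger
ones.

## Model selection and checking

DIC = mean deviance + pD with the deviance −2·log-likelihood recorded at
every stored state. The default effective-parameter count is
pD = var(deviance)/2, matching common Gibbs-sampler wrappers; the classic
pD = D̄ − D(θ̄) is available by flag. Absolute DIC values depend on this
choice; DIC *differences* between candidates on the same data are the
quantity used for selection, and ties are reported rather than broken.
Posterior predictive checks simulate replicated detector readings from
the observation model at every stored state and report central 95%
predictive intervals and their empirical coverage of the measured values.

## Synthetic data and the simulation study

The generator draws from exactly the model above. Its defaults are the
reference experimental conditions: the 14-level dilution series 2.5, 5,
7.5, 10, 12.5, 15, 17.5, 20, 25, 30, 35, 40, 45, 50 mg/mL with the 8
lowest levels RI-valid; monomeric lysozyme M = 14307 g/mol; dn/dc = 0.20;
n0 = 1.33; σ²_R = 1e-11; σ²_Δn = 2e-9. Concentration-error levels are
parameterized as percentages p via σ²_u = (log(1+p/100)/1.96)², which
puts u within ±p% with ≈95% probability. In simulation the nominal
concentrations play the role of measured ones, consistent with the
Berkson structure (truth = measured × u).

The factorial crosses A2 ∈ {±1e-2, ±1e-3, ±1e-4, ±1e-5}, error ∈
{1, 5, 10, 20}%, four σ²_u prior treatments, and 1/2/5/10 experiment
replicates (each replicate an independent run of the full dilution
series sharing one truth) — 512 cells, 100 datasets per cell in the
reference design. The fit prior on dn/dc is N(0.195, 0.005²), centred
one prior sd below the generating 0.20, and A2 ~ N(0, 1).

Prior treatments for σ²_u:

* informative — IG(1 + 1/(2σ²_u), 1/2), a scaled inverse-χ² whose mean
  is exactly the generating σ²_u and which tightens as σ²_u shrinks. A
  mean-matched but much looser IG(2, σ²_u) variant is kept available for
  sensitivity analysis.
* intermediate — IG(1, σ²_u): mode near the truth, heavy-tailed.
* weak — IG(1, (log 1.40/1.96)²): anchored at a 40% error upper bound.
* none — no adjustment (u ≡ 1).

Cell metrics: relative bias of the posterior mean, frequentist coverage
of the central 95% credible interval, and mean interval width. The
relative-bias sign convention deserves a note: the printed definition in
the reference tables is E(A2 − Â2)/A2, but empirically the table signs
(downward bias for positive A2 when error is adjusted) correspond to
(Â2 − A2)/A2. Both conventions are implemented; magnitudes agree, and
reported values use the sign convention that matches the tables.

## What the synthetic tests do and do not show

Because the generator and the likelihood share one model, the simulation
study measures *self-consistency* (calibration, estimator behaviour
under concentration error) — it cannot detect misspecification that real
traces might exhibit: drift within a plateau, non-Gaussian detector
noise, concentration-dependent σ²_R, angular effects for larger
particles, or RI missingness correlated with the signal. The
pre-processing stage is likewise exercised on synthetic staircase traces
with Gaussian noise plus heavy-tailed spikes, which emulates injection
artifacts but not slow fouling.

## Numerical and design choices

* Truncated-Gaussian log-densities use `scipy.special.log_ndtr` for the
  normalisation; generation uses rejection sampling (the acceptance
  probability is ≈ 1 in every realistic design).
* Near-degenerate inputs: a constant deviance trace of length 1 is an
  error for DIC; identical chains give R̂ = √((n−1)/n); artifact
  screening refuses to flag an entire segment; segmentation fails loudly
  with diagnostics when the requested number of plateaus is not found.
* Pre-processing defaults (change-point window 15, jump threshold 6
  robust sd, artifact threshold 3.5 robust z, guard band 2% of segment
  length, 10% trimmed median, mean-of-buffers baseline with optional
  linear drift) are exposed as configuration keys; they are working
  values, not calibrated constants.
* Scaled-down problem sizes used by the test-suite and the acceptance
  script (short adaptive chains gated by R̂, 50–100 datasets per
  simulation cell) were chosen as the smallest sizes at which the
  Monte-Carlo standard errors of the cell metrics are small compared to
  the effects being checked; tolerances in the tests are stated as
  printed value ± max(0.06, 2 standard errors).

## Known limitations

* The sampler mixes more slowly in the |A2| = 1e-2 regime with the full
  Berkson adjustment (strong coupling between A2 and the u ensemble);
  the R̂ gate with refit handles it, at some cost in runtime.
* Higher-order virial coefficients, multi-angle likelihoods and Bayesian
  model averaging over oligomer specs are out of scope.
* Marginal likelihoods / Bayes factors are not computed; model choice is
  by DIC only.
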