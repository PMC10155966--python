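# Methods

`itcbayes` infers microscopic binding thermodynamics from isothermal
titration calorimetry (ITC) isotherms by Bayesian posterior sampling, for
1:1 binding and for a symmetric two-site (2:2) system — a homodimeric
titrand M with two equivalent ligand grooves titrated by a ligand X.  This
note records the model, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Binding models

**1:1.**  Total heat after any titration point, from the standard quadratic
(identical-sites, n = 1) expression with microscopic dissociation constant
`Kd = exp(dG/RT)` and molar enthalpy `dH`:

    Q = V0 [M_t] dH/2 { 1 + [X_t]/[M_t] + Kd/[M_t]
                        - sqrt( (1 + [X_t]/[M_t] + Kd/[M_t])^2 - 4[X_t]/[M_t] ) }

**Two-site.**  The scheme M + X ⇌ MX + X ⇌ MX2 is parameterised by
microscopic, site-resolved energies: step one has `Kd1 = exp(dG/RT)` and
enthalpy `dH`; step two has `Kd2 = exp((dG+ddG)/RT)` and enthalpy
`dH + ddH`.  Negative `ddG` is positive cooperativity.  Statistical factors
for the two indistinguishable sites enter the equilibrium relations
(`Kd1/2` and `2 Kd2` are the macroscopic stepwise constants), giving the
mass-balance system

    [M_t] = [M] (1 + 2[X]/Kd1 + [X]^2/(Kd1 Kd2))
    [X_t] = [X] + [M] (2[X]/Kd1 + 2[X]^2/(Kd1 Kd2))

and the heat  `Q = V0 ( dH [MX] + (2 dH + ddH) [MX2] )`.

Throughout, `R = 1.9872e-3 kcal/(mol K)`; energies are kcal/mol,
concentrations molar internally (μM at the user surface), volumes litres
internally (μL/mL at the surface), `Q` in calories and per-injection heats
in μcal.

**Free-concentration solver.**  [M] is eliminated analytically (first
equation above), leaving a single residual in [X] that is strictly
increasing and bracketed by [0, [X_t]].  We solve it by vectorised bisection
(62 iterations, i.e. to machine precision), simultaneously for all
injections of all isotherms and all walker positions.  This is
deterministic, cannot fail inside the bracket, and is what makes the MCMC
likelihood fast (a posterior evaluation for 50 walkers costs ~2 ms).  A
scalar Levenberg–Marquardt solve in log concentrations
(`solve_free_two_site_lm`) is retained as an independent route and is
cross-checked against the bisection solver in the test suite, along with a
nested 2-D bracketing oracle.

**Dilution bookkeeping.**  The calorimeter cell is perfused: injections
displace mixed cell content.  The default convention is the
continuous-displacement (Origin-style) limit, `[M_t] = M0 exp(-ΔV/V0)` and
`[X_t] = X0 (1 - exp(-ΔV/V0))` after cumulative injected volume ΔV.  A
stepwise per-injection variant (midpoint convention: the displaced volume
carries the average of pre- and post-injection concentrations) is provided
as a pluggable alternative (`dilution="stepwise"`); the two agree to better
than 0.1% over a standard 35-injection protocol.

**Per-injection heats.**  With Q_i the total heat at the post-injection-i
composition (Q_0 = 0),

    dQ_i = Q_i + (V_i/V0) (Q_i + Q_{i-1})/2 - Q_{i-1} + dH0

where the middle term restores the heat carried out by the displaced
volume, and `dH0` (μcal) is a flat per-injection offset absorbing dilution
heat and buffer mismatch.  The typeset source for this correction is
ambiguous; we adopt the standard displaced-volume average shown above,
which is the published Origin form.  The first injection (small priming
volume) is simulated but by default excluded from fitting
(`discard_first`), matching standard practice.

**Concentration degeneracy.**  For any α > 0, scaling both analyte
concentrations and every Kd by α while dividing every enthalpy by α leaves
every model heat exactly unchanged (`dG → dG + RT ln α`, `ddG` unchanged,
`dH → dH/α`, `ddH → ddH/α`).  Consequently only the syringe/cell
concentration *ratio* is identifiable from the data; individual
concentration posteriors take the shape of their priors, and enthalpies
inherit concentration uncertainty linearly while free energies inherit it
only logarithmically.  `degeneracy_transform` implements the map, and the
test suite asserts heat invariance to 1e-10 and likelihood constancy along
in-support degenerate sets to 1e-8.

## Bayesian model

Parameters: the shared thermodynamic block (`dG, ddG, dH, ddH`; two for
1:1) plus, per isotherm, `cell_uM, syringe_uM, dH0_ucal, sigma_ucal` —
4 + 4k parameters for k isotherms (12 for a two-isotherm global model).
The likelihood is independent Gaussian across retained injections with one
noise sd σ per isotherm.

Default priors (all overridable):

| parameter | prior | rationale |
|---|---|---|
| dG | uniform [-15, -2] kcal/mol | spans sub-nM to mM affinities |
| ddG | uniform [-7.5, +7.5] kcal/mol | strong cooperativity both signs |
| dH | uniform [-60, +20] kcal/mol | generous around observed range |
| ddH | uniform [-45, +45] kcal/mol | ditto |
| cell, syringe | uniform ±10% of stated | typical concentration accuracy; fractional window configurable per analyte, normal option for sensitivity studies |
| dH0 | uniform [-10, 10] μcal | flat offset scale |
| σ | uniform [0.001, 1] μcal | instrument noise scale |

The exact thermodynamic prior ranges used in the original analyses are not
recoverable from the accessible text; the wide uniforms above are our
declared defaults and cover every value the package is validated against.
Uniform priors are used for concentrations by default because, along the
degenerate direction, the posterior *is* the prior — a normal prior would
silently impose a normal posterior (this behaviour is itself tested).

Forward-model failures inside the prior support are mapped to log
likelihood −∞ (zero likelihood) rather than an exception, and counted, so
sampling continues.

## Sampling

emcee's affine-invariant ensemble sampler with a 20%:80% mix of
differential-evolution and stretch moves and 50 walkers (25–50 supported;
at least 2× the parameter count enforced).  Seeding is explicit and
deterministic: replica i uses `seed + 7919 i`.

**Initialisation.**  Walkers are drawn i.i.d. from the priors (redrawn up
to 100 times where the posterior is −∞).  Pure prior initialisation has a
known pathology here: stretch moves contract the ensemble by at most a
factor ~2 per accepted move, so walkers that start in far corners of the
wide prior box can take tens of thousands of steps to join the posterior
bulk, inflating the apparent marginals.  The default `init="collapse"`
therefore runs a 2 000-step exploration phase from the prior draws, then
restarts all walkers in a tight Gaussian ball (1e-3 of each prior scale)
around the best point found before the production run.  This affects only
the transient, which is discarded as burn-in; `init="prior"` disables it.

**Burn-in, thinning, convergence.**  The integrated autocorrelation time τ
per parameter is estimated with the standard windowed estimator on
walker-averaged chains.  Burn-in is 5× max τ (capped at half the chain) and
summaries thin by τ/2; raw chains are retained.  A run is declared
converged when the chain exceeds 50× τ for every parameter, and, when
replicas are run, when each replica's 95% credible-interval endpoints lie
within 10% of the pooled interval width.  Typical τ for the 8-parameter
single-isotherm model is 200–350 steps, so the default 20 000–40 000 step
runs give 60–200 τ.

## Synthetic isotherms

The generator reproduces the standard validation conditions: 1.42 mL cell,
25 °C, one 2 μL priming injection then 34 × 6 μL (or 10 μL) injections,
`dH0 = 0`, i.i.d. Gaussian noise of 0.2 μcal per integrated heat.
Registered scenarios: `validation2site` (dG = −7, ddG = −1, dH = −10,
ddH = −1.5; 17/500 μM), `one2one` (dG = −8, dH = −12; 34/500 μM),
`bsn_mimic_17` / `bsn_mimic_70` (dG = −5.1, ddG = −1.7, dH = −11, ddH = −2;
17/900 and 70/2000 μM; 10 μL injections), and the noiseless `coop_panel`
ΔΔG sweep.  `replicate_set` additionally draws "measured" concentrations
from the ±w uniform window around truth, emulating concentration-assay
error for coverage studies.

What the generator does *not* emulate: baseline drift, non-Gaussian or
heteroscedastic noise, injection-volume error, active-fraction differences
between analytes, or competing equilibria.  Passing the synthetic-recovery
tests therefore demonstrates correctness of the inference machinery under
the stated noise model, not robustness to every artefact of real
calorimetry.

## Validation campaigns

**Credible-region calibration.**  `coverage_validation` simulates replicate
isotherms (fresh noise, freshly drawn stated concentrations), fits each,
and records whether the generating value falls inside the credible region
at a ladder of levels {10, 30, 50, 70, 90, 95}%, with bootstrap (1000
resample) uncertainties.  A calibrated pipeline tracks the diagonal.  The
full-MCMC version at 20+ replicates is an hours-long batch job (exposed as
`itcbayes coverage`); the test suite exercises the machinery with an
analytically calibrated stand-in posterior at desk scale, plus MCMC
recovery checks on single isotherms.

**Identifiability map.**  `identifiability_heatmap` simulates one isotherm
per point of a (dG, ddG) grid at fixed (dH = −10, ddH = −1.5), fits it, and
stores 95% credible-width of each thermodynamic parameter together with the
per-step Wiseman parameters c_k = n[cell]/Kd_k (informative band 5 < c <
500).  The default grid is a coarse 5×5 over dG ∈ [−8.5, −5],
ddG ∈ [−2.5, +1] with reduced sampler settings; one noise realisation per
grid point with per-point seeds derived from the run seed.

## Problem sizes and tolerances

Free-concentration solves are exact to machine precision; solver tests
demand mass-balance residuals < 1e-9 relative and oracle agreement < 1e-6.
Degeneracy invariance is asserted at 1e-10 relative.  The in-suite
posterior-validation fit uses 50 walkers × 40 000 steps on one synthetic
isotherm (≈2 minutes with the vectorised likelihood); sensitivity and
design-comparison fits use 12 000 steps, which resolves credible widths to
the few-percent level — adequate for the factor-scale trends they assert.
The acceptance script uses 40 000 steps.  Credible regions are central
(2.5–97.5 percentile for 95%).

## Known limitations

- Stoichiometries beyond two sites, ternary/competition models and raw
  power-trace integration are out of scope; inputs are integrated heats.
- Convergence is judged by τ and replica agreement only; no R-hat across
  independent chains (walkers are coupled within a replica).
- The two-site model assumes a pre-formed, stable titrand dimer; dimer
  dissociation during the titration is not modelled.
- Single-replica fits at 12 000 steps can fail the strict 50τ rule for the
  slowest (concentration) directions while the reported thermodynamic
  widths are already stable; the convergence flag is reported, not hidden.
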