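# Methods

## The model

The package describes the extracellular-plus-lumped-intracellular
metabolism of HEK293 cells producing rAAV as a single well-mixed
compartment: 53 concentration state variables (mM), 32 reactions, and
three auxiliary cumulative outputs (Biomass, Rep protein, capsid protein)
that accumulate from zero and carry no mass balance of their own. No
intracellular sub-compartments (mitochondria, nucleus) are distinguished,
and there is no explicit cell-density state: biomass synthesis is a sink
flux, not a growth law, so the model has no dilution or fed-batch terms.

Every flux follows saturation (Michaelis–Menten) kinetics,

    v = vmax · Π_s  [S_s] / (Km_s + [S_s]),

with one saturation factor per substrate; the five reversible reactions
(TPI, PGK, SD, FH, LDH) subtract an analogous reverse product. Km
parameters are registered per metabolite and shared across laws (for
example `Km_ATP` appears in the HK, PFK, PGK, PC, Glu, Growth, Rep and Cep
laws), giving 52 distinct Km and 37 vmax values — 89 kinetic parameters —
plus 53 initial concentrations, 142 fittable quantities in total. The
species dynamics are the dense mass balance dC/dt = S·v(C) with S the
(53+3) × 32 signed stoichiometric matrix.

Two bookkeeping choices in the shipped definition deserve note. The
source network prints the pentose-phosphate reactions twice (once under
"pyruvate fates", once under PPP) while the kinetic table carries a single
G6PDH and TK law; the definition includes each once, which is what makes
the 32-law count consistent. Water and protons appear in three reactions
but have no tracked state and are omitted. The lactate dehydrogenase and
alanine transaminase laws have kinetic entries but no printed reaction
row; their stoichiometry follows standard biochemistry
(Pyr + NADH ↔ Lac + NAD⁺; Pyr + Glu → Ala + αKG). The pyruvate
carboxylase row is kept exactly as printed (ATP consumed, no ADP
released). Glutamic acid (GluAc) and glutamate (Glu) are distinct species;
GluAc is consumed only by the Rep/Cap synthesis fluxes. Cofactors
(ATP/ADP, NAD(H), NADP(H), FAD(H₂), CoA, Pi, CO₂) are dynamic states with
fitted initial values, not clamped pools.

**Units.** Concentrations are mM and time is hours (the emulated dataset
is sampled at 24 h intervals), so fluxes and vmax are mM·h⁻¹. The source
tables state concentrations only; this is the package's convention and is
applied consistently everywhere.

## Simulation

The mass balances are stiff — cofactor concentrations span roughly
1e-5–20 mM and several pools (serine, glutamate, oxaloacetate) switch
between depletion and turnover regimes — so the default integrator is
LSODA with rtol 1e-7 and atol 1e-9 mM, supplied with an analytic state
Jacobian (d(S·v)/dC assembled from the saturation-term derivatives
Km/(Km+c)²). The analytic Jacobian cuts roughly 80% of the right-hand-side
evaluations that finite-difference Jacobians would cost and brings one
120 h simulation of the full model to ~0.08 s.

Inside the right-hand side, concentrations are floored at zero before the
flux evaluation: a Michaelis–Menten term then vanishes smoothly for a
depleted substrate instead of turning negative under integrator
overshoot, and the corresponding Jacobian entries are zeroed
consistently. Reported trajectories are clipped at zero (the overshoot
this removes is below solver tolerance). The default output grid is
0–120 h every 24 h; the horizon is configurable since the true culture
duration is an experimental choice, not a model property.

## Parameter fitting (blockwise NGL/M)

The objective is the unweighted sum of squared residuals between measured
and simulated profiles of the five observed metabolites, reported both
raw (ssq, mM²) and as SMSE = ssq/n. Residual tables also report √ssq per
species, since residual magnitudes are often quoted on the concentration
scale.

One damped Gauss–Newton step solves

    (JᵀJ + λ·diag(JᵀJ)) δ = −Jᵀr,

accepts the shifted parameters if the ssq decreases (λ → λ/10), otherwise
raises λ tenfold and retries with the same Jacobian; λ exceeding 1e10
without an acceptable step is a stall, and a proposed step of negligible
norm declares the (local) optimum. A trial step whose simulation fails is
treated as non-improving rather than an error. Design choices:

* **Log-space parameters.** Km, vmax and C₀ are positive and span seven
  decades, so steps are taken on log p and exponentiated before each
  simulation. The Jacobian uses forward differences with step 1e-6 on
  log p.
* **Trust region.** A single accepted step may move a parameter by at most
  a factor e² ≈ 7.4. Without the cap, a nearly flat (weakly identified)
  direction can teleport a parameter many decades to a bound in one jump
  and strand the fit in a spurious basin (observed with a Km collapsing to
  zero, i.e. a zero-order-kinetics local optimum).
* **Bounds.** Default box bounds are wide (1e-12–1e6); for real fits,
  order-of-magnitude bounds around literature-derived initial estimates
  are recommended — the optimizer is local, and bounds are what keep
  correlated Km/vmax pairs in the physically meaningful basin.
* **Blocks.** With 142 fittable quantities and 30 data points, all-at-once
  fitting is hopeless; parameters are optimized 2–10 at a time (default
  block size 6, consecutive chunks, optionally shuffled by seed) with the
  rest held fixed, cycling until the largest relative parameter change
  over a full cycle falls below 1e-4 (max 20 cycles). Inner LM iterations
  stop at a relative ssq improvement below 1e-8 or 50 iterations per
  block. The best-ever parameters are returned, and the accepted-step ssq
  history is non-increasing by construction.
* The initial concentrations of the five measured species are known at
  t=0 and are never fittable; all other C₀ are legitimate fit targets.

**The recovery experiment.** The packaged experiment perturbs four
parameters by +30% and re-fits them (blocks of 2) against synthetic data.
The quartet — c0_ATP, c0_Pyr, c0_Gly, vmax_GLNS — was chosen by an
identifiability analysis, not by convenience: the residual Jacobian at the
generating values was propagated through the Gauss–Newton normal equations
against the measurement-noise covariance, and the quartet minimizes the
worst-case posterior standard error (~0.10 on log parameters). That
matters because most vmax values in this network are *supply-limited* —
the flux they scale is controlled by regeneration of a co-substrate, so
the parameter is nearly flat above a threshold (vmax_NS and vmax_PC are
textbook cases) — and a vmax paired with its own Km rides a classic
saturation ridge. On noiseless data the quartet is recovered essentially
exactly; with 5% measurement noise, worst-case errors of 6–15% were
observed across seeds, comfortably inside a 25% band.

## Sobol sensitivity analysis

First-order indices S_i = V[E[Y|X_i]]/V[Y] are estimated with a Saltelli
paired design: matrices A and B drawn from a scrambled Sobol' sequence
(seeded, reproducible) plus the k hybrids A_B^(i), (k+2)·n model runs for
k parameters at base sample size n (default 1024). V[E[Y|X_i]] uses the
Jansen form V − (1/2n)·Σ(f(B)−f(A_B^(i)))², which has lower estimator
variance than the naive product form. Percentile bootstrap confidence
intervals resample the base rows (seeded, 200 replicates). Only
first-order indices are computed — with 89 parameters, higher-order
interaction terms are computationally out of reach — and their sum is at
most 1 up to estimator noise. Failed integrations become NaN rows and are
excluded pairwise; more than 10% failures aborts with a suggestion to
narrow the ranges.

Choices the analysis cannot inherit from data:

* **Ranges.** Parameters vary uniformly over 0.5×–1.5× their fitted
  values by default, overridable per parameter. Published index magnitudes
  for this model are tied to unstated ranges and are therefore not
  reproducible; what the package validates is the estimator itself
  (closed-form linear and Ishigami benchmarks, within ±0.02 and within
  the bootstrap CI respectively at n = 4096) and the workflow.
* **Aggregate output.** Time-resolved indices are computed per metabolite
  and time point directly. The aggregate scalar collapses a run to the
  mean over outputs and times of |y(t) − y(0)| normalized by each
  output's typical magnitude — a "how much did the profiles move" summary
  that no single high-concentration metabolite can dominate. Normalizing
  by initial value was rejected because outputs starting near zero blow
  up the scale.
* **Outputs.** Glutamic acid is excluded from the default output set: it
  is consumed only by the Rep/Cap synthesis fluxes and carries almost no
  information about the rest of the network.

## Synthetic data

The generator stands in for the original bioreactor dataset (a
low-cell-density AAV6 production culture, not publicly deposited). It
simulates the five measured profiles on the 24 h grid over 0–120 h and
adds heteroscedastic Gaussian noise with sd = max(0.05·value, 0.02 mM),
truncated at zero — a relative component typical of enzymatic/biosensor
assays plus a floor near the detection limit. Both noise magnitudes are
placeholders for unknown assay characteristics and are explicit NoiseModel
fields. Glucose/lactate columns round-trip through g/L (molar masses
180.16 and 90.08 g/mol) to match common analyzer output.

What the generator does *not* emulate: replicate structure, sampling
volume effects, transfection timing, cell growth/death phases, or any
model-mismatch — its "truth" is the model itself. Passing recovery tests
therefore demonstrate that the optimizer works, not that the model is
identifiable from real cultures; with real data the glutamic-acid profile,
for instance, is known to be poorly captured.

## Numerical edge cases

* Zero substrate concentration gives exactly zero flux (and vmax/2 at
  [S] = Km), by construction of the saturation term.
* A constant batch output (collapsed parameter ranges) yields zero total
  variance; all indices are reported 0 with a degenerate-variance flag.
* Ranking ties are broken by parameter name, so reports are
  deterministic.
* All randomness (noise, perturbations, Saltelli sampling, bootstrap,
  block shuffling) flows from explicit integer seeds.

## Problem sizes used in the packaged checks

Structural checks are instantaneous. The round-trip and recovery
experiments run the full 53-species model on the 6-point grid (a fit is a
few hundred simulations, ~0.5–1.5 min each experiment). Estimator
benchmarks use n = 4096 base samples on closed-form functions (seconds).
The model-based sensitivity smoke runs use 5 parameters at n = 8–64; a
full 37-parameter analysis at n = 1024 is a ~40k-simulation production
run (about an hour on one CPU) and is left to the CLI.

## Known limitations

* The optimizer is local; different block schedules can reach different
  basins when parameters are strongly correlated and unbounded. Bounds
  and mild perturbations keep the packaged experiments in one basin.
* Fit quality against the original culture data (total ssq ≈ 7 mM²
  dominated by glucose) cannot be reproduced here because that dataset is
  not available; the packaged substitute is the exact round-trip on
  synthetic data.
* Thermodynamic consistency, flux-balance analysis, compartments, and
  second/total-order Sobol indices are out of scope.
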