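# Methods

This package re-implements, as a tested pipeline, a population
pharmacokinetic (popPK) analysis of ropeginterferon alfa-2b — a
mono-PEGylated interferon given subcutaneously every two weeks — built
around a quasi-equilibrium target-mediated drug disposition (QE-TMDD)
mixed-effects model. Because the underlying phase-I concentration data are
not publicly deposited, every stage runs against synthetic trials generated
from the published final-model values; what the pipeline demonstrates is
therefore *methodological*: that the model, estimator, selection procedure
and simulator recover the conditions they were given.

## Structural models

**QE-TMDD (primary).** One-compartment disposition with first-order
absorption from a subcutaneous depot (rate `ka`, lag `tlag`) and two
elimination routes: linear clearance `CL/F` and receptor-mediated uptake.
Drug binds its receptor at quasi-equilibrium with dissociation constant
`KD`; the complex is internalised at rate `kint`; free receptor turns over
with degradation rate `kdeg` and synthesis `ksyn = R0·kdeg`, pinning the
drug-free receptor level at `R0`. States are the depot amount, the *total*
central amount and the *total* receptor concentration; the free
concentration is the closed-form root of the binding mass balance

    Cfree = ½[(Ctot − Rtot − KD) + √((Ctot − Rtot − KD)² + 4·KD·Ctot)],

evaluated on the numerically stable branch (the naive sum cancels when
`Ctot − Rtot − KD` is large and negative); `KD → 0` is handled as the
infinite-affinity limit. Total clearance decomposes as
`CL_total = CL + Rtot·kint·V/(KD + Cfree)`: at free concentrations well
above `KD` the receptor route saturates and kinetics become linear, at low
concentrations it multiplies clearance several-fold — the mechanism behind
the more-than-dose-proportional exposure.

**Michaelis–Menten (comparator).** The empirical saturable-elimination
alternative. The clearance relation is implemented in two forms:
`printed` (`CL = Vm·C/(Km+C)`, the form as published, under which clearance
*rises* with concentration) and `conventional` (elimination rate
`Vm·C/(Km+C)`, i.e. `CL = Vm/(Km+C)`, the classical decreasing-clearance
behaviour that matches the observed CL/F-vs-dose trend). The printed form
is the default and the discrepancy is deliberately surfaced here rather
than silently corrected.

**Observation mapping.** The bioassay is taken to measure the *free*
concentration — the standard QE-TMDD convention — with a flag for total
concentration. Bioavailability is fixed at 1; all clearances and volumes
are apparent (CL/F, V/F), as only extravascular data exist.

**Numerics.** Internal units are hours, micrograms, litres and ng/ml
(1 µg/L = 1 ng/ml, so amount/volume needs no conversion); per-day
parameters are converted only at the reporting boundary. The ODE system is
integrated with LSODA using the analytic Jacobian (the receptor equation,
`kdeg = 0.544 h⁻¹`, is fast against absorption, `ka ≈ 0.0058 h⁻¹`);
tolerances default to rtol 1e-8 / atol 1e-10. The absorption lag is an
exact time-shift of each dose's depot entry, not a transit compartment.
Dose events reset integration segments with a depot-amount discontinuity
only.

## Mixed-effects estimation (FOCE-I)

Between-subject variability is lognormal (`p_i = p_pop·exp(η_i)`, diagonal
Ω); residual error is additive, proportional or combined, with variance
evaluated at the individual prediction (η–ε interaction). For each subject
the empirical Bayes mode minimises the penalised conditional deviance
`Σ[ln v_j(η) + (y_j − f_j(η))²/v_j(η)] + η'Ω⁻¹η` by damped Gauss–Newton
with a finite-difference prediction Jacobian; the subject's marginal
contribution is the classical FOCE linearisation about that mode,

    OFV_i = n ln 2π + ln|C_i| + r_i' C_i⁻¹ r_i,
    C_i = G Ω G' + V(η̂),  r_i = y − f(η̂) + G η̂.

A Laplace objective at the same mode is provided as a cross-check; both
reduce exactly to the Gaussian marginal likelihood for a linear model
(unit-tested against the closed form). The 2π constants are included, so
OFVs are internally comparable; model discrimination uses differences.

The outer search runs L-BFGS-B over log-transformed typical values and
variances — power-law covariate exponents stay on the natural scale as
they may take either sign. Gradients are forward differences computed
with the empirical-Bayes modes *frozen at the base point*: every
perturbed evaluation warm-starts from the same conditional modes (one
Gauss–Newton refinement, which is second-order accurate in the step), so
the differences are free of inner-optimisation path noise — without this
the gradient floor stalls the search tens of OFV points short.
Convergence is a relative OFV change below 1e-6 (default;
replicate-heavy procedures use 1e-4 to 1e-3), and the search restarts
with cleared curvature memory until a restart gains less than one OFV
point: the strongly correlated (clearance, weight-exponent) and
(volume, absorption) pairs form curved valleys where a single L-BFGS-B
run triggers the relative-reduction stop early. Powell's method is
available as an alternative but proved markedly less able to escape the
ω²–θ ridge that forms when an inflated variance absorbs a biased typical
value. Standard errors come from the
central-difference Hessian of the OFV on the natural scale (relative step
1e-4), the condition number from the eigenvalue ratio of the estimates'
correlation matrix; η-shrinkage is `(1 − SD(η̂)/ω)·100` and ε-shrinkage
`(1 − SD(IWRES))·100`.

**Below-quantification samples.** The published analysis does not state
its BLQ rule, and roughly 12-18% of the nominal samples fall below the
0.05 ng/ml assay limit at these doses. Two handlings are implemented:
discarding the flagged rows (M1, the file-level default used by NCA and
the diagnostics) and a censored-data likelihood (M3) in which a
below-limit row contributes `−2·ln Φ((LLOQ − f)/√v)` through the Laplace
objective — the classical pairing, since the FOCE linearisation assumes
Gaussian observation terms; the implementation is unit-tested against
direct numerical integration of a censored marginal. The headline
recovery experiments use M3: this censoring is *informative* — the
discarded tail samples are exactly the low ones — and M1 estimation
converges, reproducibly and with the exact likelihood concurring
(cross-checked by adaptive Gauss-Hermite quadrature), to an optimum with
the apparent volume and absorption rate ~25-30% below their generating
values, while M3 recovers them within sampling error. Pre-dose samples
(true zeros by design) are excluded from estimation either way.

Estimation practicalities worth knowing: (i) successive objective
evaluations agree only to roughly the inner (empirical-Bayes) tolerance,
so warm-started refits can differ in OFV by a few hundredths; (ii) with
n = 57 subjects the apparent volume and absorption rate carry sampling
variability of order 10-25% (their between-subject CVs are 91% and 64%),
so single-replicate recovery is judged at the ±20% level — and on an
unlucky synthetic draw the *maximum-likelihood estimate itself* can sit
just outside that band (verified on one generation seed by converging to
the same point from displacements in opposite directions, with the OFV
well below the generating values); (iii) from starting values displaced
~15-30% the optimiser needs on the order of a thousand objective
evaluations (including gradient perturbations), the budget the
reproduction workflow allots together with a wall-clock cap.

## Covariate analysis

Screening correlates empirical Bayes estimates with covariates (Spearman
for continuous, point-biserial for two-level categorical; default
threshold |ρ| > 0.2 — an explicit operationalisation of the published
visual inspection). Weight, BMI and BSA are near-collinear in these
trials; among candidates with pairwise |r| strictly above 0.8 on the same
parameter only the highest-priority covariate survives (weight first, the
usual pharmacological choice). Continuous covariates enter as power
functions referenced at 70 kg — the published reporting convention, kept
in preference to the dataset median — and categorical ones as proportional
factors with the modal level as reference. Stepwise selection is greedy
best-first forward inclusion at ΔOFV > 3.84 (χ², df 1, 5%) and backward
elimination retaining effects whose removal raises the OFV > 6.63 (1%);
both inequalities are strict, and the trace of every decision is returned.

## Diagnostics

*CWRES* uses the same FOCE linearisation as the estimator: residuals are
decorrelated by the subject-level covariance `G Ω G' + V`, so they are
approximately standard normal under a correct model (calibration is
unit-tested: mean within ±0.15, variance in [0.7, 1.3] on ~900 simulated
observations). *pc-VPC* bins observations by nominal sampling time
(merging bins below 5% of observations into their smaller neighbour),
scales each observed and simulated value by bin-median PRED / own PRED,
and compares observed 10/50/90th percentile curves with their 90% bands
across simulated replicates (1,000 by default); simulated values below the
assay limit are discarded exactly as real ones are. The *bootstrap*
resamples subjects with replacement within study strata — preserving the
30/27 two-trial composition — and refits each replicate from the final
estimates; success means optimiser convergence with finite OFV, and runs
abort below 50% success. *Sensitivity*: refits with KD and kint fixed at
0.5/0.75/1.5/2× and reports percent changes of CL/F, V/F and ka against
the reference fit.

## Synthetic trials

The generator reproduces the two printed designs exactly: 6 Caucasian
cohorts × 5 evaluable males at 24-270 µg with 20 post-dose samples to
672 h, and 3 Chinese cohorts (9/8/10 evaluable, male:female 5:4/5:3/5:5)
with 18 post-dose samples. Weights and heights are bivariate normal at the
published per-study moments (correlation 0.5 — unreported, chosen once for
realistic BMI spread) truncated to 45-120 kg / 145-205 cm; BMI and BSA are
derived (`WT/HT²`, `√(WT·HT/3600)`). Pre-dose samples are true zeros
flagged below-limit. An `enrolled` switch generates the enrolled counts
(36/30) and removes the trial's dropout count at random. The ~894
retained concentrations of the original analysis emerge from censoring
rather than being forced: the default generator yields ≈1,000 quantifiable
samples, within the plausible range given that the exact BLQ handling and
dropout timing are unreported.

What the generator does *not* emulate: real assay drift between the two
laboratories, dropout that correlates with exposure, deviations from
nominal sampling times, and any model misspecification — the data are
generated by the very model being fitted. Passing recovery tests therefore
demonstrates estimator correctness, not clinical validity of the model.

## Steady-state simulation

Virtual populations (default 1,000 subjects) draw weights from truncated
normals at the per-study moments (resampling a supplied weight vector is
supported) and η from the final-model Ω; residual error and
parameter-estimation uncertainty are excluded — exposure is a model
quantity, not an assay replicate. Each subject receives repeated SC doses
every 336 h; steady state is declared when successive interval AUCs agree
within 1% (cap 20 doses ≈ 40 weeks, beyond 7 half-lives of the slowest
process; capped subjects are flagged and contribute their last interval).
The AUC integrates the free concentration on a 337-point grid per
interval (the trough across the lag window is carried explicitly).

A structural observation that matters for interpreting the published
exposure intervals: in any model whose only elimination routes are linear
clearance plus a receptor route that removes drug, the steady-state AUC
over one interval cannot exceed `Dose/CL_linear` (3,085 ng·h/ml for a
70-kg subject at 100 µg). The faithful QE-TMDD integration gives 1,887
ng·h/ml for that subject — cross-checked against an independent
cumulative-AUC integration at rtol 1e-10 — because receptor-mediated
uptake dominates through each interval's low-concentration tail. The
published 80% intervals sit largely *above* that ceiling, implying less
total clearance than the linear pathway alone; no setting of this
implementation's flags (free vs total concentration, CV read with or
without the radical, added residual or estimation uncertainty) reproduces
them, and the simulated intervals here are reported from the faithful
default protocol (free concentration, BSV only, √(exp(ω²)−1) CVs). The
qualitative conclusions — slightly higher exposure in the lighter Chinese
population at equal dose, and more-than-proportional exposure with dose —
hold robustly for every seed.

## Problem sizes in the validation suite

The test suite exercises every stage at sizes chosen to make the checks
sharp but cheap. The headline recovery experiment uses one full synthetic
two-trial dataset (57 subjects, both printed designs) refitted from
displaced starting values. The fixed-parameter sensitivity analysis runs
on a reduced single-study design — three cohorts (24/90/270 µg) of three
subjects with nine sampling times, the absorption lag and weight exponent
held at their generating values — which preserves the dose range that
drives KD/kint identifiability while keeping the nine refits tractable;
on this design all refits converge and the largest shift in CL/F, V/F or
ka across the 0.5-2× grid is ~11%. Estimator calibration (CWRES, VPC
self-coverage, bootstrap behaviour, stepwise type-I error) runs on linear
one-compartment populations of 10-60 subjects, where predictions are
closed-form, with 150 VPC replicates and 5-6 bootstrap replicates per
check; the full-size defaults (1,000 VPC simulations, 1,000 bootstrap
iterations) remain the library defaults used by the analysis scripts.

## Default parameter values

| quantity | value | note |
| --- | --- | --- |
| CL/F | 0.778 L/day (70 kg) | typical apparent clearance |
| weight exponent on CL/F | 0.927 | power law, 70 kg reference |
| V/F | 2.32 L | apparent central volume |
| ka | 0.14 day⁻¹ | slower than elimination: flip-flop kinetics |
| tlag | 0.426 h | absorption lag |
| R0 | 0.111 ng/ml | baseline receptor |
| kdeg | 0.544 h⁻¹ | receptor turnover |
| kint | 0.0788 h⁻¹ | fixed (poorly identified otherwise) |
| KD | 0.142 ng/ml | fixed |
| BSV CV | 35.7 / 90.8 / 63.5 % | CL/F, V/F, ka; ω² = ln(1+CV²) |
| residual | 18.7% prop + 0.342 ng/ml add | combined model |
| LLOQ | 0.05 ng/ml | M1 discard before estimation |

The CV footnote of the source table omits the radical; this package uses
`CV% = √(exp(ω²)−1)·100`, the standard lognormal relation, which is also
the reading consistent with the printed CL/F variance.

## Known limitations

- FOCE-I here is not NONMEM-bit-compatible: OFV constants, optimiser path
  and Hessian conventions differ. Comparisons should always be within-package.
- Ω is diagonal; no η correlations, no inter-occasion variability
  (single-dose trials make both unidentifiable anyway).
- No likelihood-based (M3) BLQ handling; heavy censoring at the lowest
  dose biases that cohort's information downward.
- The λz point-selection rule (best adjusted R² over terminal suffixes,
  ties toward more points) is one of several defensible conventions.
- The steady-state exposure experiment inherits the structural ceiling
  discussed above; its published endpoints are not reproducible from the
  published parameters by any faithful mechanistic reading.
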