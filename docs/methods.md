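# Methods

`nanopk` compares the pharmacokinetics of drug formulations — here a
free methotrexate solution, polymeric ("hard") nanoparticles, and
lipid ("soft") nanoemulsions given to rats — with two complementary
toolchains: classical non-compartmental analysis (NCA) per subject,
and a population (nonlinear mixed-effects) model in which the
formulation enters as a binary covariate on the structural
parameters.

## Structural model

Plasma concentration follows a one-compartment disposition model with
first-order elimination. An IV bolus dose D (mg/kg) gives

    C(t) = 1000 · (D/V) · exp(−(CL/V)·t)            [ng/mL]

and an oral dose passes through a depot with first-order absorption
rate Ka (1/h), lag time Tlag (h) and bioavailability F:

    C(t) = 1000 · F·D·Ka / (V·(Ka−ke)) · (e^{−ke·τ} − e^{−Ka·τ}),
    τ = t − Tlag,  ke = CL/V,

with the limit form 1000·(F·D/V)·ke·τ·e^{−ke·τ} when |Ka−ke| <
10⁻⁸·ke, which is exact in the limit and avoids catastrophic
cancellation. Units are fixed package-wide — time h, concentration
ng/mL, dose mg/kg, V L/kg, CL L/h/kg — and the single mg/L → ng/mL
factor of 1000 lives in `structural.py` only. Multi-compartment
disposition, transit absorption and nonlinear elimination are out of
scope: the studies this emulates were single-dose designs adequately
described by one compartment.

## Population model

Subject-level parameters are log-normally distributed around typical
values, with the formulation covariate acting linear-fractionally:

    P_i = tvP · (1 + dP·code) · exp(η_P,i),   η ~ N(0, ω²_P)

for P ∈ {V, CL, Ka, F} (Tlag carries only the random effect by
default, but is a legal covariate candidate in the search). `code` is
0/1 under one of two contrasts: free solution (0) vs nanoformulation
(1), or nanoparticle (0) vs nanoemulsion (1). Residual error is
log-additive — observation = prediction × exp(ε), ε ~ N(0, σ²) — so
observations must be strictly positive. Additive, proportional, power
and mixed residual contracts exist as alternatives for the base-model
ladder, but only the log-additive model is tuned and tested for
fitting.

### Estimation

The marginal likelihood is approximated FOCE-style. For subject i
with log-residual vector r(η), Jacobian J = ∂log f/∂η, and residual
variances v:

1. the conditional mode η̂ minimizes
   S(η) = Σ r²/v + Σ log v + ηᵀΩ⁻¹η (damped Gauss–Newton, analytic
   J, vectorized across subjects);
2. the subject's contribution is the Laplace expression with
   Gauss–Newton curvature A = JᵀWJ + Ω⁻¹ (W = diag(1/v)) at η̂:

       −2LL_i = Σ[r²/v + log(2πv)] + η̂ᵀΩ⁻¹η̂ + log|Ω| + log|A|.

Variance weights are evaluated at the conditional prediction, which
is what retains the η–ε interaction for heteroscedastic error models;
under the log-additive model v ≡ σ² and the interaction is vacuous.
As Ω → 0 the expression collapses to the conditional −2LL at η = 0.
A 1-D quadrature oracle bounds the approximation error at ≤1% on
one-random-effect problems (tested).

The outer problem maximizes this over a transformed vector: log scale
for typical values (tvF deliberately unconstrained above 1, since
covariate scaling can push typical bioavailability past unity), the
map d = e^q − 1 for covariate coefficients (guaranteeing 1 + d > 0),
log ω² with a floor of 10⁻⁶ (variances printed as 0.000 are handled
as exact zeros in generation and floored in estimation to keep Ω
invertible), and log σ. tvTlag is bounded above by half the earliest
oral sampling time so predictions at observation times stay positive;
points a search step pushes to f ≤ 0 contribute a large finite
penalty instead of raising. The optimizer is L-BFGS-B with
finite-difference step 10⁻⁵ and a "polish" restart from the optimum
with fresh conditional modes, which removes warm-start hysteresis;
multi-start with seeded jitter is available and guards against the
absorption/elimination flip-flop optimum on oral-heavy designs.
Initial values come from per-covariate-level moment estimates (IV
intercept → V, IV log-slope → CL, oral AUC vs IV-derived CL → F,
1/Tmax → Ka).

OFV means the minimized −2LL throughout (the literature uses both
names for the same quantity); AIC = −2LL + 2·n_params. Standard
errors come from a central finite-difference Hessian of −2LL on the
transformed scale (covariance 2·H⁻¹) with a delta-method
back-transform; RSE% = 100·SE/|estimate| and is reported as undefined
for near-zero estimates. η-shrinkage is 100·(1 − SD(η̂)/ω) with the
n−1 SD; IIV% = 100·√ω². No claim of numerical agreement with any
proprietary estimator is made; correctness is established through
oracles, identities and recovery experiments.

## Non-compartmental analysis

Per subject: Cmax/Tmax read off the profile; terminal slope λz by
log-linear regression over all candidate tails of ≥3 points (strictly
after Tmax for oral data, from the first post-peak point for IV),
keeping the maximal adjusted R², ties toward more points — the usual
"best fit" rule; T1/2 = 0.693/λz with the conventional rounded
constant; AUC by linear trapezoid with a (0, 0) anchor for oral and a
back-extrapolated (0, C0) anchor for IV (C0 log-linear through the
first two samples, falling back to the first concentration if the
head is not decreasing); AUC0–∞ = AUC0–t + Clast/λz; AUMC by the
first-moment trapezoid plus its tail terms; CL = dose/AUC0–∞ and
V = dose/(λz·AUC0–∞) for IV data, in mL-based units; MRT =
AUMC/AUC; Vss = MRT·CL. Dose-normalized exposure divides by dose in
matching units, and absolute bioavailability is the oral/IV ratio of
dose-normalized AUC0–∞, in percent. Arm summaries are mean ± SD;
between-arm comparisons use Welch's unequal-variance t-test, chosen
because 5-animal arms routinely show order-of-magnitude variance
differences. Tissue delivering efficiency is the tissue/plasma
concentration ratio.

Note the trapezoidal rule overestimates the AUC of a convex decaying
curve, so CL from sparse late sampling is biased low by a few
percent; NCA recovery tests therefore use dense grids, and
comparisons against arm means computed from ratios of printed means
carry a documented ~1% ratio-of-means vs mean-of-ratios discrepancy.

## Covariate search

Forward addition then backward elimination over formulation-on-
parameter effects, judged by the drop in OFV against χ²(1) critical
values: entry needs a drop > 3.84 (p < 0.05), survival needs removal
to cost > 6.63 (p < 0.01). The search is greedy largest-drop-first;
ties break toward fewer parameters then alphabetical name; candidate
refits warm-start from the incumbent; every model tried is recorded
in a ledger. Tlag is a legal candidate and fails naturally — no
special-casing.

The χ²(1) calibration of the entry rule is asymptotic. On very small
problems the LRT is inflated by roughly n/(n−p): a 6-subject, 24-
observation, 8-parameter null design admits a spurious covariate at
~13%, exactly as that factor predicts. The calibration test therefore
uses a 12-subject, 60-observation null design where the predicted and
measured rates (~6–7%) agree with the nominal 5% within binomial
noise.

## Model evaluation

All diagnostics are deterministic functions of (fit, data, seed).

* **Goodness of fit** — PRED (η = 0), IPRED (η = η̂), and CWRES from
  the FOCE linearization on the log scale:
  cwres = Cov^{−1/2}(log y − (log f(η̂) − Jη̂)), Cov = JΩJᵀ + σ²I,
  symmetric matrix square root, 10⁻¹⁰ ridge on singular covariances.
* **VPC** — replicate datasets simulated at the estimates on the
  original design; per nominal time bin (all subjects share the
  schedule, so no adaptive binning) the observed 5/50/95 percentiles
  against the across-replicate median and 95% CI of each simulated
  percentile; linear interpolation between order statistics;
  optional stratification by formulation.
* **Bootstrap** — subjects resampled with replacement within each
  (formulation, route) arm so every covariate level stays estimable;
  warm-started refits; percentile medians and 95% intervals; failed
  replicates dropped and counted.
* **NPDE** — per subject, simulated log-observation vectors are
  decorrelated with the simulated mean and Cholesky factor;
  pd = fraction of decorrelated simulations below the decorrelated
  observation, clamped to [1/(2n_sim), 1 − 1/(2n_sim)];
  npde = Φ⁻¹(pd). Decorrelation is on the log scale to match the
  residual model. Three global tests: Shapiro–Wilk normality, t-test
  for mean 0, and the two-sided χ² variance test against 1 (the
  variance test conventionally attributed to Fisher in this
  literature).

## Synthetic data

The generator draws η ~ N(0, Ω), forms individual parameters, and
observes y = f·exp(ε) on a fixed design — exactly the statistical
structure the estimator assumes. The default design emulates the rat
study: 5 animals per arm; nanoparticles 5 mg/kg oral and IV;
nanoemulsions 0.06 mg/kg oral and 0.024 mg/kg IV (dose ratios 83.33×
and 208.33×); the free-solution contrast adds a 5 mg/kg control pair,
with an optional duplicated control pair to reach the 40-animal
total (the published per-arm n = 5 over six arms and the 40-rat total
cannot both hold; the generator surfaces rather than resolves this).
The source studies never print their full sampling schedule, so the
default 9-point grid 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24 h is a design
choice: it brackets the reported Tmax values and covers ≥5 terminal
half-lives for every arm under either truth preset, making λz
estimable. Two presets return published final-model estimates
verbatim as generator truth (the free-vs-nano contrast set, and the
nanoparticle-vs-nanoemulsion set).

What the generator does **not** emulate: assay quantification limits
and BLQ censoring, sampling-time jitter, body-weight variation,
multiple dosing, and any model misspecification (the data are
generated by the very model being fitted). Passing recovery and
calibration tests therefore demonstrates internal consistency of the
estimator and diagnostics, not robustness to the ways real rat data
deviate from the model.

## Identifiability of the bioavailability contrast — a caveat

Under the nanoparticle-vs-nanoemulsion truth preset the residual SD
is σ = 0.552 on the log scale (≈58% CV) while the formulation effect
on F is ln(1.193) ≈ 0.18. Direct computation of the information (an
8×-sized simulation, dropping the F covariate from the full model)
gives a per-study likelihood-ratio noncentrality of ≈0.7 for dF —
power ≈13% at the 3.84 entry threshold — whereas the effects on V,
CL and Ka carry noncentralities of ~1700, ~65 and ~59. In practice:
the stepwise search almost always returns "formulation on V, CL, Ka"
and drops F; and the full-model estimate of dF scatters with SD
≈0.06–0.10 around the truth. The clearance contrast (a 99% decrease)
and the typical clearance itself are, by the same computation,
recovered robustly. The corresponding selection-consistency and
recovery checks in the acceptance suite state the stronger published
expectations and are left failing by design; the measurement above is
the package's explanation of why.

## Problem sizes and numerical defaults

Tests and the acceptance experiment use these sizes, chosen to keep
the full suite in the tens of minutes on one core while preserving
the regimes each check needs: recovery fit at full scale (20
subjects, 9 time points, all five random effects); selection-
consistency at 3 rats/arm with a 6-point grid and IIV on CL only
(the remaining truth variances are ≤0.001); null calibration at 100
seeds of the 12-subject design; VPC and NPDE at 200 simulations;
bootstrap at 60 warm-started replicates. Optimizer defaults: outer
ftol 10⁻⁹ (10⁻⁵ inside search loops), inner gradient tolerance 10⁻⁶,
inner iteration cap 60, finite-difference Hessian step 10⁻⁴.

## Known limitations

* FOCE/Laplace bias at large σ and tiny n is not corrected; exact
  adaptive quadrature is available only as a test oracle.
* Off-diagonal Ω, SAEM-type estimators, BLQ handling, covariates
  other than the single binary formulation code, and multiple dosing
  are out of scope.
* The bootstrap reuses the original estimates as starting values;
  with 5-animal arms, replicate likelihoods are occasionally flat in
  Tlag and ω² directions, which percentile intervals absorb but SEs
  would not.
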