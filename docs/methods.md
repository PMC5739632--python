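# Methods

`vancopk` implements a population-pharmacokinetic (PopPK) analysis of
intravenous vancomycin in neonates and young infants: a two-compartment
nonlinear mixed-effects (NLME) model estimated by first-order conditional
estimation (FOCE), stepwise covariate selection on likelihood-ratio
thresholds, bootstrap and visual-predictive-check evaluation, and
individual trough prediction for therapeutic drug monitoring (TDM).
This note records the model, the numerical choices, and what the synthetic
data do and do not establish.

## Structural and statistical model

Drug amounts follow the linear two-compartment model with constant-rate
infusion input, parameterised by central and peripheral volumes V1, V2 (L),
clearance CL (L/h) and inter-compartmental clearance Q (L/h).  Micro
constants are k10 = CL/V1, k12 = Q/V1, k21 = Q/V2; the disposition
exponents α ≥ β are the roots of x² − (k10+k12+k21)x + k10·k21, computed
with the numerically stable form β = k10·k21/α.  Concentrations are the
closed-form superposition of per-dose infusion responses

    C(t) = Σ_doses R·[A·φ(t−t_d; T, α) + B·φ(t−t_d; T, β)],
    φ(τ; T, λ) = (1 − e^{−λ·min(τ,T)})·e^{−λ·max(τ−T,0)}/λ,

with R the infusion rate, T the duration, and A = (α−k21)/(V1(α−β)),
B = (k21−β)/(V1(α−β)).  Q = 0 degenerates continuously to the
one-compartment model (B = 0).  The closed form is verified against a
piecewise stiff-ODE oracle to 1e−6 relative on randomized regimens.

Individual parameters are log-normal around covariate-adjusted typical
values: continuous covariates enter as power functions normalised at a
reference (median) value, categorical 0/1 covariates log-linearly, and
inter-individual variability (IIV) as P_i = P_pop·exp(η_i), η_i ~ N(0, ω²).
Residual error is additive, proportional or combined Gaussian noise.

The packaged `FINAL_MODEL` (also shipped as `specs/final_model.yaml`) is the
published neonatal model: tvV1 = 1.27 L, tvV2 = 2.422 L, tvQ = 1.161 L/h,
CL(L/h) = 0.42·(BBW/3.22)^0.888·(PNA/29)^0.449·exp(η_CL), ω_CL = 0.317
(SD scale), additive residual SD 2.187 μg/mL.  η is carried on CL only —
the other parameters' random effects showed shrinkage > 0.5 in the source
analysis and were removed — but the engine supports η on any parameter set
(diagonal Ω).  The 0.317 value is interpreted as ω (an SD), the
conventional reporting scale; treating it as ω² would imply a 56% CV of
clearance, implausible against the reported parameter precision.

Units are strict: μg/mL ≡ mg/L exactly, doses in mg, volumes in L, times in
hours.  Infusion durations are rarely recorded in TDM datasets; the default
is 1.0 h (standard neonatal vancomycin practice), configurable per dose and
globally.  PNA is a per-subject scalar taken at concentration measurement.

## Likelihood and estimation

The marginal likelihood of each subject's sparse observations is
approximated FOCE-style.  The inner problem finds each subject's
conditional mode η̂ (the empirical Bayes estimate, also used for MAP trough
prediction) by damped Gauss–Newton on

    h(η) = Σ_j [(y_j − f_j(η))²/σ²_j + log σ²_j] + η'Ω⁻¹η  (+ LLOQ term, below)

with σ²_j evaluated at the conditional prediction (FOCE with interaction;
for additive error this coincides with plain FOCE).  df/dη is obtained by
central differences (step 1e−5); iterations run vectorised across all
subjects at once and stop at max-gradient < 1e−6 — the objective error is
quadratic in this gradient (~1e−12), so tightening further only costs time.
The objective is then the linearised marginal Gaussian,

    OFV = Σ_i [n_i log 2π + log|V_i| + r_i'V_i⁻¹r_i],
    V_i = G_iΩG_i' + Σ_i,  r_i = y_i − f_i(η̂) + G_iη̂,

evaluated with the Woodbury identity so only q×q systems appear (q = number
of random effects).  A Laplacian variant (same modes, Gauss–Newton
curvature) is available by flag; both reduce exactly to the closed-form
marginal Gaussian when the prediction is linear in η, which is tested
against a direct linear-mixed-model oracle.

**Quantifiability conditioning.**  Event tables — the study's and the
generator's alike — contain only quantifiable concentrations: an assay
result below the 1 μg/mL LLOQ is not recorded as a concentration.  The
default likelihood therefore conditions each observation on y ≥ LLOQ,
adding +2·log Φ((f_j − LLOQ)/σ_j) per observation (the normaliser of the
truncated Gaussian).  For observations well above the LLOQ the term is
negligible; at trough-like predictions a few σ above the LLOQ it corrects a
systematic few-percent underestimation of the residual SD.  The plain
Gaussian likelihood is available via `condition_on_quantifiable=False`.
Records explicitly flagged below the LLOQ are excluded from the likelihood
(M1); this path only arises when the generator is run with
`resample_bql=False`.

The outer problem maximises over log-transformed positive parameters
(typical values, ω, residual scales) and unconstrained covariate exponents
with L-BFGS-B (forward-difference gradients, step 1e−6; ftol 1e−9, gtol
1e−4, ≤ 500 iterations).  Conditional-mode warm starts are carried between
objective evaluations.  Standard errors come from the inverse
central-difference Hessian of OFV/2 (step 1e−4 on the transformed scale),
delta-method mapped to the natural scale; a non-invertible Hessian yields
missing SEs with the fit still usable.  Identifiability is pre-checked
(observations ≥ fixed effects).  Non-finite objective values return a large
penalty to the optimizer rather than raising.

Diagnostics: PRED is the population prediction (η = 0), IPRED the
conditional prediction (η = η̂); CWRES whitens the linearised residual
r_i by the Cholesky factor of V_i and is ~N(0, 1) under a correct model;
η-shrinkage is 1 − SD(η̂)/ω with the sample SD across subjects.

## Covariate selection

Forward inclusion fits each remaining candidate relation singly and accepts
the largest OFV drop if it exceeds 6.635 (χ², 1 df, p < 0.01); backward
elimination removes, one at a time, the effect whose deletion raises the
OFV least, retaining an effect only if its removal costs more than 10.828
(p < 0.001).  Candidate fits warm-start at the incumbent optimum with a
zero exponent, so a nested candidate can never appear to worsen the fit.
Continuous candidates are centred at the dataset median of their covariate.
Ties break lexicographically on covariate name; candidates target CL by
default (effects on other parameters are configurable).  Non-converged
candidate fits are skipped with a warning.  The trace serialises to a CSV
ledger (model, OFV, ΔOFV, decision per row).

## Evaluation

*Bootstrap* resamples **subjects** with replacement — the only exchangeable
unit in hierarchical data — refits each replicate starting from the
original estimates, excludes and counts non-converged replicates, and
reports per-parameter medians, SEs (SD across replicates) and both
percentile and Wald (median ± 1.96·SE) 95% intervals.

*VPC* re-simulates the observed design (each subject's doses, covariates
and sampling times) with fresh η and ε, summarises pooled simulated
concentrations at the 5th/50th/95th percentiles per quantile bin of
time-after-most-recent-dose (8 bins by default; the binning variable makes
dosing-interval phases comparable across q6/q8/q12 regimens), and reports
the fraction of observations inside the 5–95% band.  Negative simulated
concentrations are truncated at zero.

*External validation* reports MPE = mean(pred − obs), MAE = mean|pred −
obs| and MSPE = mean((obs − pred)²) with SDs across pairs, in μg/mL and
(μg/mL)²; per-case prediction error is 100·|pred − obs|/obs.

*Trough prediction* evaluates the concentration immediately before the
n-th dose of a regimen: a population prediction (η = 0) by default, or a
MAP prediction through the subject's empirical Bayes η when prior
concentrations are supplied.

## Synthetic cohorts

The generator emulates the study's data structure so the whole pipeline is
testable without any accession: 316 subjects; continuous covariates drawn
from truncated log-normals matching the published medians with ~99% of
mass inside the published ranges (only medians and ranges are published —
the marginals are an emulation, not an estimate of the true joint
distribution); preterm status Bernoulli(102/316) with gestational age drawn
conditionally (preterm median 33.5 weeks on 28–36.9, term median 38.5 on
37–41); sex, panipenem and furosemide Bernoulli at the published
frequencies; body weight grown from birth weight as BBW·(1 + g·PNA) with
g = 0.0077/day jittered ±30% (reproducing the 3.95 kg median weight);
BSA, Schwartz GFR and PMA derived from the sampled primitives.  Renal and
hepatic markers are generated independently of the PK truth so selection
tests can treat them as calibrated nulls.

Dosing draws 13.7–73.5 mg/kg/day uniformly, split evenly over 2–4 daily
infusions (τ = 12/8/6 h) for 2–7 days, amounts rounded to 0.1 mg.
Sampling is sparse and trough-biased: 1–6 samples per subject with mean
≈ 1.33 (matching 421 observations from 316 patients; pmf 0.80/0.12/0.04/
0.02/0.01/0.01), 70% drawn within 1 h before a scheduled dose and 30%
uniform within a dosing interval, all after the third dose.  Residual
draws below the LLOQ are re-drawn (the study dataset contains no sub-LLOQ
record; its minimum is 1.34 μg/mL), and a subject whose draws are all
unquantifiable is re-drawn entirely, mirroring the enrolment requirement of
at least one recorded concentration.  With `resample_bql=False` sub-LLOQ
values are instead kept and flagged.  Under the default design roughly
two-thirds of trough samples fall below 10 μg/mL, matching the reported
therapeutic-attainment pattern.

What passing tests show — and do not.  Recovery, calibration and coverage
results condition on this generator: they demonstrate that the estimation
machinery is correct and calibrated under the study's design (sparse,
trough-biased, LLOQ-selected sampling), not that the published model is
true of any real population.  Real datasets add covariate correlation
structure, time-varying covariates within therapy, assay error that is not
Gaussian-additive, and dose-adaptation feedback, none of which are
emulated.

## Problem sizes and determinism

Simulation studies in the test suite and the reproduction script use the
study's own size where the quantity depends on it (316 subjects for
recovery and VPC coverage; 20 simulation seeds for bias summaries) and
scaled replicate counts where the quantity is a stability summary
(bootstrap 200 resamples on a 100-subject cohort; VPC 200 simulated
cohorts; stepwise calibration 10–20 replicates).  Every stochastic entry
point takes an explicit seed; the estimation engine itself draws no random
numbers, and repeated calls are bit-identical.

At the default sparse design (≈1.33 observations/subject) the additive
residual SD and ω_CL are weakly separable: single fits estimate sd0 with an
SE of ≈0.11–0.15 around the generating 2.187, and cohort-to-cohort spread
of the MLE matches that SE.  This is a property of the design, not of the
optimizer; richer sampling in the generator collapses the spread.

## Known limitations

- FOCE linearisation carries a small (~2–3%) downward bias in variance
  components at this sparsity; adaptive quadrature is not implemented.
- Ω is diagonal; correlated random effects and SAEM/MCMC estimation are out
  of scope, as are Michaelis–Menten elimination, oral absorption and
  three-compartment kinetics.
- The VPC simulates unconditionally on quantifiability (observed records
  are LLOQ-selected); at the default design the effect on band coverage is
  within the tested tolerance.
- Bootstrap SEs assume exchangeable subjects; stratified resampling is not
  provided.
- The two printed external-validation troughs cannot be reproduced exactly
  from their nominal prescriptions: the published values are mutually
  inconsistent under linear kinetics with identical regimen shapes (ratio
  8.73/3.79 = 2.30 vs a maximum achievable ≈1.45 from the dose and
  clearance differences), indicating the source predictions used
  unpublished dose histories.  The package documents its 1-h-infusion,
  nominal-regimen population prediction (5.45 and 7.27 μg/mL for the two
  cases) rather than matching those numbers.
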