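# Methods

`tacmpa` implements a population-pharmacokinetic analysis of the
drug–drug interaction between tacrolimus (TAC) and mycophenolate mofetil
(MMF) as observed in a three-period, fixed-sequence, single-dose crossover
study in healthy male volunteers (period 1: MMF 1,000 mg alone; period 2:
TAC 5 mg alone; period 3: the combination; one-week washouts; samples
predose and 1, 2, 4, 6, 8, 12, 24, 48, 72 and 168 h post dose).  Because
the raw concentration data of that study are not public, every stage of
the pipeline is exercised on synthetic trials generated from the study's
published population estimates.

## Structural models

**Tacrolimus.**  Two-compartment disposition with first-order absorption,
absorption lag and first-order elimination from the central compartment.
When clearance is constant the model has the standard tri-exponential
closed form, which the package uses both as the fast path for TAC-alone
data and as the analytic oracle for the ODE integrator (the two agree to
better than 1e-6 relative on a 0–168 h grid; tested).

**Mycophenolic acid and metabolites.**  MPA (dosed as the prodrug MMF)
follows two-compartment disposition with first-order absorption.  A fixed
fraction f_MPAG = 0.85 of MPA elimination forms the 7-O-glucuronide MPAG
(k57 = f·CL/V5), the remainder forms the acyl glucuronide AcMPAG
(k59 = (1−f)·CL/V5).  MPAG is secreted into a gallbladder compartment at
k78 and eliminated at k70; the recirculating fraction is
EHC = k78/(k70+k78), so k78 = EHC·k70/(1−EHC).  During the meal-triggered
emptying window [mtime1, mtime1+mtime2) the gallbladder empties at k84
into the MPA absorption depot, where deconjugated drug is reabsorbed with
the MPA absorption rate constant — this reproduces the secondary MPA peak
at 6–12 h.  Deconjugation is treated as instantaneous and mass-conserving
in dose-equivalent units; no molar-mass corrections are applied anywhere
(all "/F" parameters absorb the MMF→MPA conversion, matching the study's
parameterization).  AcMPAG distributes in a fixed V9 = 23 L and is
eliminated at k90 = 2.15 1/h.

**Interaction.**  In the integrated model the model-predicted MPA central
concentration C(t) (µg/mL) scales TAC clearance continuously inside the
ODE.  Three forms are supported, all as multiplicative factors on CL/F:
exponential exp(−slope·C) (the study's selected form, slope 0.0294),
linear 1 + slope·C, and Emax 1 + Emax·C/(EC50+C).  The published
arithmetic follows: at C = 5 µg/mL the exponential factor is 0.8633, a
13.7% clearance reduction.  CYP3A5 expressers carry a multiplicative fold
on CL/F (1.26 in the single-drug model, 1.48 in the integrated model).

Design choices where the source material was open:

- The linear and Emax interaction "effects" are entered multiplicatively
  on CL/F like the exponential form, with the sign of the estimated
  parameter encoding direction; only the exponential form's placement was
  shown explicitly.
- The gallbladder window is dose-relative (mtime1 h after the period's
  dose), one window per period; multi-meal variants are out of scope.
- ka colliding with a disposition eigenvalue in the closed form is
  perturbed by 1e-9 relative (measure-zero configuration).

## Units

Doses are salt/ester milligrams (MMF 1,000 mg, TAC 5 mg); internal amounts
mg and volumes L, so predicted mg/L equals µg/mL for the plasma analytes,
with ×1,000 to ng/mL for whole-blood TAC only.  Assay ranges: TAC
0.5–100 ng/mL; MPA and MPAG 0.1–100 µg/mL; AcMPAG 0.2–20 µg/mL.  A value
equal to the LLOQ is quantifiable; only 0 < value < LLOQ is flagged BLQ by
the censoring operation (the generator additionally flags structural zeros
such as predose samples).

## Statistical model and estimation

Interindividual variability is log-normal (parameter × exp(η), diagonal
Ω).  Published CV% values are converted by ω² = ln(1+CV²).  Residual
errors are proportional, additive or combined per analyte; printed σ
values are interpreted as standard deviations (e.g. σ_prop 0.131 = 13.1%
CV).  IIV on the EHC fraction is log-normal with simulated individual
fractions above 0.999 rejected and redrawn; during estimation the
individual fraction is capped at 0.999.

The marginal likelihood is approximated by FOCE-I or Laplace at the
subject's empirical-Bayes mode η̂:

- Inner problem: damped Gauss-Newton on the joint −2LL with the exact
  gradient (including the log-variance terms that give the "interaction"
  flavour), Gauss-Newton Hessian 2F'WF + 2Ω⁻¹, and step halving; for the
  non-Gaussian M3 objective a quasi-Newton fallback is used.  Warm starts
  are taken from the previous outer iteration but only kept if they beat
  η = 0, so the OFV is essentially evaluation-order independent.
- FOCE-I: −2LL_i = log|V| + r'V⁻¹r with V = FΩF' + Σ(f(η̂)) and
  r = y − f(η̂) + Fη̂ (residual variance at the conditional prediction).
- Laplace: joint −2LL at η̂ plus log det of half the inner Hessian
  (central finite differences via statsmodels, eigenvalues floored at
  1e-8).  On linear-Gaussian models this reproduces the closed-form
  marginal likelihood exactly (tested), which pins down the constant
  convention: all 2π terms are dropped, so OFV differences are LRT
  statistics in the usual pharmacometric convention.
- Outer problem: L-BFGS-B on log-transformed parameters with
  finite-difference gradients (step 1e-3 on the log scale); the reported
  OFV is the best value seen and never exceeds the initial one.

BLQ handling follows the 10% routing rule: analytes with strictly fewer
than 10% BLQ observations are fitted by FOCE-I after omitting them;
otherwise Laplace is used with BLQ values replaced by individual
predictions (refreshed from the current empirical-Bayes mode at every
objective evaluation).  The M3 censored-likelihood term
−2·log Φ((LLOQ−f)/sd) is available as the statistically standard
alternative.  Estimation is sequential: single-drug models first, then
the integrated model initialized from them.  Standard errors / covariance
steps are not computed.

## Non-compartmental analysis

Linear-up/log-down trapezoids (the common WinNonlin default; the source
is silent on the rule); λz by best adjusted-R² log-linear regression over
terminal windows of ≥3 post-peak points excluding Cmax; AUC_0-inf =
AUC_last + C_last/λz; CL/F = dose/AUC_0-inf; Vz/F = CL/F/λz.  BLQ samples
are excluded except a predose BLQ kept as a zero anchor at t = 0.  Paired
period comparisons gate on Shapiro-Wilk normality of the differences at
α = 0.05 (paired t vs Wilcoxon signed-rank); tmax is summarized as median
(min–max) without a test.

## Covariate search

Stepwise covariate modelling on CL/F and V/F with linear, power and
exponential forms for continuous covariates (median-centred) and a fold
factor for binary covariates.  Greedy forward inclusion at ΔOFV > 3.84
(χ²₁, p<0.05) and backward elimination retaining only ΔOFV > 6.63
(p<0.01), both strict inequalities, one functional form per
covariate-parameter pair.  The selection engine accepts any fitter
callable; the null calibration of the forward step (type-I error ≈ 5%) is
verified with an exact linear-Gaussian ML fitter, which exercises the
identical threshold logic without nonlinear refits.

## Diagnostics

Prediction-corrected VPC: replicate trials simulated on the observed
design, binned by nominal sampling time (the design is fixed-time, so
quantile binning is unnecessary), Bergstrand-style median normalization
within bins, 95% confidence bands for the 5th/50th/95th percentiles.  BLQ
observations are excluded from the percentiles.  CWRES uses the FOCE
linearization at η̂ with the symmetric inverse square root of
V = FΩF' + Σ; eta shrinkage is 100·(1 − SD(η̂)/ω) with SD on n−1.

## Synthetic trials

The generator reproduces the study design exactly: 17 subjects by
default, the three-period fixed sequence, the 11-point sampling grid,
CYP3A5 expresser prevalence 23.5%, and the published parameter values
with their IIV and residual error.  One η vector per subject is shared
across periods (a crossover in the same individuals; no between-occasion
variability, as in the source analysis).  Covariates are drawn
independently from median-anchored two-piece uniforms on the reported
[min, max] ranges — a plain triangular with mode at the median cannot
reproduce the skewed cohort medians (e.g. age median 25 on [20, 42]), so
the two-piece form was chosen to make population medians match the
reported medians exactly.  Covariate correlations are not modelled (only
univariate summaries were reported).

What the synthetic data do *not* emulate: assay-specific error structure
beyond the fitted residual models, meal-time variation in gallbladder
emptying, dropout, or any covariate effect other than the CYP3A5 fold.
Passing recovery tests therefore demonstrate the correctness and
calibration of the estimation machinery under the published model, not
the clinical findings themselves.

## Problem sizes and numerical settings

- TAC-alone recovery: 100 subjects, all seven structural thetas plus
  three IIV variances and the proportional sigma estimated from initials
  perturbed ±30–40%; runs in a few minutes via the closed form.
- Integrated recovery: 12 subjects, combination period only, IIV
  restricted to CL/F_TAC and CL/F_MPA, estimating CL/F_TAC, the CYP3A5
  fold, the interaction slope and the EHC fraction with the remaining
  parameters held at their generating values.  This is the package's
  scaled version of the full integrated refit, chosen so ODE-based
  optimization stays tractable; tolerances are correspondingly loose
  (15–25%).
- ODE solver: LSODA integrated piecewise across the lag and gallbladder
  switching times (rtol 1e-8 for simulation, 1e-6 inside fits, 1e-10 for
  mass-balance audits).  Mass balance holds to 1e-8 relative including
  cumulative elimination accumulators.
- VPC: 1,000 replicates by default (400 in the calibration test); bands
  are 2.5th–97.5th percentiles of the replicate percentile distribution.

## Known limitations

- No SAEM or importance-sampling estimators; no mixture models; no
  between-occasion variability; no infusion or steady-state dosing.
- The FOCE/Laplace implementations use finite-difference sensitivities;
  gradients of the outer problem are noisy at the 1e-6 level, which
  bounds achievable outer tolerances.
- The bootstrap hook for standard errors is provided but deliberately
  unvalidated (point estimates only are in scope).
- Whether the source analysis measured the gallbladder window from dose
  or clock time, used SDs or variances for σ, and used log- or
  logit-normal IIV on the EHC fraction is unstated; this package uses
  dose-relative timing, SDs, and log-normal with capping, respectively.
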