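# Methods

`rivapk` implements a complete population-pharmacokinetic workflow for
once-daily oral rivaroxaban in non-valvular atrial-fibrillation patients:
study simulation, nonlinear mixed-effects estimation, covariate selection,
model qualification, and Monte Carlo dose optimization by renal function.
This note records the model, its assumptions, the defaults and why they are
what they are, and the places where a design choice was genuinely open.

## Structural and statistical model

Disposition follows a one-compartment model with first-order absorption and
first-order elimination at steady state under a fixed 24 h dosing interval:

    C(t) = (D ka) / (V (ka - ke)) [ e^{-ke t} / (1 - e^{-ke tau})
                                  - e^{-ka t} / (1 - e^{-ka tau}) ],
    ke = CL/V,

computed internally in mg/L and reported in ng/mL (single 1000x
conversion).  When |ka - ke| < 1e-8 the analytic equal-rates limit is used
to avoid catastrophic cancellation; both branches are validated against a
term-by-term superposition of single-dose profiles.

Covariates enter the typical parameters as power functions centered near
the cohort medians:

    CL/F = 4.19 (CrCl / 57.5)^0.277  L/h
    V/F  = 37.5 (WT / 63)^0.412      L
    ka   = 0.697                     1/h

Between-subject variability is log-normal (exponential eta) on CL/F
(21.94 %CV) and ka (75.91 %CV).  The IIV of V/F is fixed to zero by default
— with only two samples near the peak per occasion the volume's variance is
not estimable from this design — but can be switched on in the
configuration.  The random-effect covariance is diagonal: no CL-ka
correlation is modeled.

### Residual error scale

The residual model is additive with SD 0.092, by default on the natural-log
concentration scale (approximately a 9.2% CV).  A strict linear-additive
mode on the mg/L scale is available via `FitConfig(error_model="additive")`.
The log scale is the package default because a 0.092 mg/L (92 ng/mL)
additive SD would exceed typical trough concentrations (12–137 ng/mL),
making simulated troughs frequently negative; on the log scale the
generated data are internally consistent at every sampling time.  Synthetic
data generation and estimation always share the configured scale, so
parameter-recovery results hold under either mode.

## Estimation: FOCE with a frequentist prior

The marginal -2 log-likelihood is approximated by first-order conditional
estimation.  Per subject, the conditional mode minimizes

    sum_j (y_ij - f_ij(eta))^2 / sigma^2 + eta' Omega^{-1} eta,

and the objective linearizes the model about that mode:

    OFV = sum_i [ log det V_i + r_i' V_i^{-1} r_i + n_i log 2 pi ],
    V_i = G_i Omega G_i' + sigma^2 I,
    r_i = y_i - f_i(eta_hat_i) + G_i eta_hat_i.

With a purely additive error model on the chosen scale, sigma does not
depend on eta and the FOCE "interaction" term is vacuous; FOCE and FOCE-I
coincide here.

Because the design contains only steady-state peak (2–4 h) and trough
(22–24 h) samples, absorption is weakly identified.  A frequentist prior
anchors the typical ka and its IIV:

    penalty = (tv_ka - mu_ka)^2 / se_ka^2
            + nu [ omega2_ka_prior / omega2_ka + log omega2_ka ],

with defaults mu_ka = 0.61 1/h (midpoint of the 0.600–0.617 1/h absorption
constants reported for comparable Asian AF cohorts), se_ka = 0.1,
omega2_ka_prior = 0.76^2 (76 %CV) and nu = 10.  All hyperparameters are
configurable and serialized with every fit.  Fitting trough-only data with
the prior disabled drives the Hessian condition number far above the usual
1000 heuristic and the result is flagged ill-conditioned — the observable
motivation for the prior.

### Numerical scheme

* Outer problem: L-BFGS-B over log-transformed positive parameters
  (typical values, variances, sigma) and untransformed exponents, with
  finite-difference gradients (step 1e-5) and wide box bounds that only
  keep the search out of overflow territory.
* Inner problem: per-subject damped Newton with exact Hessians
  (complex-step first derivatives; mixed complex/central second
  derivatives) and Levenberg–Marquardt damping, vectorized across all
  subjects that share an observation count.
* Mode tracking: the conditional deviance can be bimodal in eta_ka (the
  absorption "flip-flop" — a peak sample is explained equally well by fast
  absorption or fast elimination).  Newton starts from eta = 0 and, within
  a trust radius of the previous outer iterate, also from the cached warm
  modes, keeping the per-subject better basin.  This follows the
  conventional mode-tracking behavior of established FOCE implementations;
  a check against dense-quadrature exact marginals showed that jumping to
  the global deviance minimum approximates the likelihood no better and
  destabilizes the outer search.
* Standard errors: central finite-difference Hessian of the OFV at the
  optimum; covariance = 2 H^{-1}; a non-positive-definite Hessian or an
  eigenvalue ratio above 1000 flags the fit as ill-conditioned (SEs are
  then reported as unavailable).
* %CV convention: 100 sqrt(omega2); the alternative
  100 sqrt(exp(omega2) - 1) differs by <2% at these magnitudes.
* Estimation consumes no random numbers; results are deterministic given
  the dataset.

FOCE accuracy was qualified against a 64-node adaptive Gauss–Hermite
oracle: on dense-sampling toys it agrees within 0.5%, and on a sparse
1-eta toy within 0.1 OFV units.  The approximation degrades (order 0.1 OFV
units per subject) exactly where FOCE theory predicts — large residual
times model curvature relative to sigma^2 — which is visible on sparse
designs with large omega_ka.

## Synthetic study generator

The generator reproduces the source study's design: 60 patients, a
two-period crossover (standard dose, then the reduced Japan-specific dose)
assigned by the CrCl 50 mL/min cut-off (20/15 mg above, 15/10 mg below),
one peak sample uniform in [2, 4] h and one trough uniform in [22, 24] h
per period, 240 observations in all.  Each period is simulated at its own
steady state (patients took each dose for at least a week; washout is
irrelevant at steady state) and etas are drawn once per subject (no
inter-occasion variability is modeled).

Demographics are truncated normals matched to the reported cohort:
age 69.4 (9.2) y in [40, 95]; weight 64.0 (14.1) kg in [35, 120];
serum creatinine 1.1 (0.3) mg/dL in [0.5, 2.5]; CrCl 59.0 (22.8) mL/min in
[15, 120]; 63.3% male.  Truncation bounds are not reported quantities;
they were chosen to keep well over 95% of each marginal's mass and shift
the realized means by at most ~2% (e.g. mean CrCl ≈ 60.2 after
truncation).  CrCl is sampled directly from its marginal rather than
computed via Cockcroft–Gault from the sampled age/weight/creatinine: this
pins the reported CrCl moments exactly but does not model the CrCl–weight
correlation — a documented limitation of the generator, not of the
estimation code (the Cockcroft–Gault operation is available for real
datasets).  BMI is only sampled (log-normal matched to the reported
quartiles) when explicitly requested.

What passing tests on these data do and do not show: they demonstrate that
the pipeline recovers a known generating model under the published design
and parameter values — they cannot validate assay behavior, adherence
patterns, covariate correlations or model misspecification present in real
patients.

## Covariate search

Stepwise forward inclusion (dOFV > 3.84, one degree of freedom) followed by
backward elimination (retention requires dOFV > 6.63).  The default
candidate set crosses {age, weight, BMI when present, serum creatinine,
CrCl, sex} with {CL/F, V/F}; candidates on ka are excluded by default
because ka is prior-stabilized.  Continuous candidates enter as power
functions centered at the cohort median; sex as a multiplicative exp(beta)
factor for males.  Ties break by larger OFV drop, then declaration order.
Candidate fits that fail to converge are retried from neutral initials and
otherwise skipped with a record in the trace; the trace stores every tested
candidate's dOFV so each decision replays deterministically.

## Qualification diagnostics

* Residuals: PRED (eta = 0), IPRED (at the EBE), IWRES = (y - IPRED)/sigma,
  and CWRES obtained by whitening the FOCE-linearized residual with the
  Cholesky factor of V_i.
* VPC: 1000 simulations of the exact design; bins are the four design
  cells (peak/trough x period) because the design has no other time
  resolution; the observed median is overlaid on the simulated 5th–95th
  percentile band.
* Bootstrap: subjects (never rows) resampled with replacement to the
  original cohort size; each replicate refits warm-started from the
  original estimates; medians and 2.5/97.5 percentiles are reported, with
  replicate failures counted and the summary flagged unreliable above 20%
  failures.  Replicate seeds derive from the master seed by a counter
  scheme.

## Dose optimization

For every CrCl bin (15–29, 30–49, 50–69, 70–89, 90–110 mL/min), weight bin
(15–29, 30–59, 60–89, 90–119 kg) and dose (10, 15, 20 mg once daily), 1000
virtual patients are drawn with CrCl and weight uniform within the bin and
log-normal IIV on CL/F and ka; steady-state C_MAX (closed-form peak time),
C_MIN and AUC_0-24 = dose/CL are computed without residual error, and the
fraction inside each typical exposure range (184–343 ng/mL, 12–137 ng/mL,
1860–5434 ng*h/mL) is reported.  CrCl/eta draws stream-separate from the
weight draws, so AUC results are numerically identical across weight bins
and dose changes re-dose the same virtual patients.

The per-subgroup "recommended" dose maximizes the unweighted mean of the
three in-range proportions (ties break to the lower dose).  This summary
rule is an artifact decision — the source analysis reports proportions and
argues qualitatively.  At the final-model parameters the rule reproduces
the renal dose logic across adult weights, with two caveats worth knowing:

* the 15–29 kg weight bin is implemented exactly as specified even though
  no adult cohort contains such weights; there every adult dose overshoots
  the peak range and the smallest dose trivially wins;
* two weight-extreme cells are knife-edges under uniform-within-bin
  weights (mean scores at n = 20000): in (CrCl 30–49, 90–119 kg) 15 mg
  edges out 10 mg (0.91 vs 0.85) because the 10 mg peak straddles the
  lower edge of the target range in heavy patients, and in (CrCl 50–69,
  30–59 kg) the two doses are within one point (0.795 vs 0.785) because
  the 15 mg peak begins to overshoot in light patients.  The direction of
  the renal-adjustment conclusion is unaffected; the 10-vs-15 mg split at
  the weight extremes is sensitive to the within-bin covariate
  distribution and the scoring rule, neither of which the source analysis
  specifies.

## Problem sizes used by the test suite

The suite exercises the full pipeline at sizes chosen to keep a complete
run in the tens of minutes on one CPU while leaving Monte Carlo margins
well away from the assertion thresholds: 20 replicate recovery fits,
6 covariate-search power replicates and 8 null replicates (the null check
pools per-candidate decisions, 90+ tests of the alpha = 0.05 criterion),
200 bootstrap resamples, and 1000-simulation VPC and dose grids.  The
pipeline defaults remain the full published sizes (1000 bootstrap
resamples, 1000 VPC simulations, 1000 virtual patients per subgroup).

## Known limitations

* Single-compartment, steady-state-only kinetics: no lag time, transit
  absorption, or dosing-history effects.
* The generator draws covariates independently (no CrCl-weight
  correlation) and models neither assay calibration error nor
  non-adherence.
* FOCE is a linearization; its known small-sample downward bias in
  variance components (visible as a few-percent understatement of
  omega2_cl in recovery simulations) is inherited.
* The frequentist-prior hyperparameters are defaults informed by external
  cohorts, not estimated quantities; sensitivity to them is not explored
  automatically.
* Exposure targets are population typical ranges, not an
  outcome-validated therapeutic window; "optimal" doses are optimal only
  with respect to those ranges.
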