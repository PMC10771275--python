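# Methods

`meningrowth` analyses longitudinal tumor-volume series from surveillance of
untreated intracranial meningiomas: which growth law describes the cohort,
which patient factors are associated with growth, and how much of an observed
volume change could be measurement error. This note documents the models,
the estimation machinery, the synthetic-data generator, the numerical
choices, and the limits of what the tests demonstrate.

## Data model

The unit of analysis is a patient with a strictly time-ordered series of
MRI-derived total tumor volumes (mL; multifocal tumors pre-summed into one
series) and time-invariant covariates. Time is months since the patient's
first scan. Patients enter the analysis when they have at least 3 scans
spanning at least 6 months (both boundaries inclusive; the span is
interpreted first-to-last scan). When calendar dates rather than offsets are
supplied upstream, months are days/30.4375; the package itself only consumes
month offsets.

## Growth laws

Four candidate laws are fitted, each on a declared response scale:

| law          | mean function                                      | scale      |
|--------------|----------------------------------------------------|------------|
| linear       | V(t) = a + b t                                     | volume     |
| exponential  | log V(t) = log V0 + alpha t                        | log volume |
| linear radial| log V(t) = log(4 pi/3) + 3 log(r0 + alpha t)       | log volume |
| Gompertz     | log V(t) = log K + log(V0/K) exp(-alpha t)         | log volume |

The radial law assumes a sphere (volume mL == cm^3, radius cm) whose radius
grows linearly. The Gompertz law rises exponentially at small t with
log-slope alpha*log(K/V0), passes through a near-linear phase and plateaus
at the carrying capacity K; alpha (1/month) sets how fast the log-volume
deficit log(K/V) decays.

## Mixed-effects estimation

Scans are nested in patients, so each law is fitted as a two-level nonlinear
mixed-effects model: y_ij = mu(t_ij; theta + A b_i) + eps_ij with
b_i ~ N(0, Psi) on a chosen subset of parameters and eps ~ N(0, sigma^2) on
the model's response scale. Default random effects: (log V0, log K)
unstructured for the Gompertz law — across patients baseline and attained
size vary over almost three decades, far more than growth rate plausibly
does — and both parameters for the two-parameter laws.

The marginal likelihood integrates b_i out patient by patient with the
Laplace approximation, using the Gauss-Newton curvature
J'J/sigma^2 + Psi^{-1} at the conditional mode (the standard first-order
scheme of nonlinear mixed-model software). Two properties anchor its
accuracy:

* models linear in their random effects — linear, exponential, and Gompertz
  with effects on (log V0, log K) — have exactly Gaussian integrands, so the
  Laplace value is exact and is verified in tests against the closed-form
  Gaussian marginal and against statsmodels' linear mixed model;
* for genuinely nonlinear cases (the radial law) an adaptive tensor-product
  Gauss-Hermite quadrature (21 nodes default, up to 2 random effects) serves
  as a brute-force oracle; observed Laplace error is of order 1e-3 per
  patient at realistic parameters.

The inner mode search is damped Gauss-Newton with step halving. It stops on
the Newton decrement g'H^{-1}g, whose half is (to second order) the
log-likelihood error of stopping — the threshold 1e-11 keeps the outer
objective smooth enough for finite-difference gradients. Warm-starting the
inner search from the previous outer iterate was deliberately rejected: the
inner problem of a nonlinear law can be multimodal and a cached start can
track the wrong mode, silently deforming the outer surface.

The outer maximization over (theta, Psi, sigma^2) is multi-start L-BFGS-B:
positive natural parameters travel as logs, Psi as a log-Cholesky factor
(positive definite at every iterate), sigma^2 as log sigma^2. The first
start comes from per-patient curve-fit moments (for the Gompertz law a small
alpha grid is profiled with per-patient least squares on the induced basis);
remaining starts are seeded perturbations (5 starts by default; the large
simulation studies in the test-suite use 1-2 starts, which the
moment-based initialization makes sufficient in practice). Standard errors
are square roots of the fixed-effect diagonal of the inverse numerical
observed information (central differences over all parameters jointly);
they reproduce statsmodels' LMM standard errors to ~4 decimals on linear
fixtures.

Model comparison reports log-likelihood, AIC = 2k - 2 logL and
BIC = k log(n_obs) - 2 logL per law, ranked by AIC with a stable tie-break
on the model name. k counts fixed effects + free elements of Psi + 1
(sigma^2); n_obs is the total scan count. By default each model is scored on
its own response scale — the volume-scale linear law is therefore not on a
common likelihood scale with the log-scale laws, which is exactly how a
per-model goodness-of-fit table reads; `jacobian_correction=True` adds a
column transporting the log-scale likelihoods to the volume scale
(subtracting the sum of log V) for a statistically proper cross-scale
comparison.

## Covariate inference

Risk factors enter linearly on one fixed-effect parameter, by default log K:
a positive coefficient means a larger attained size. All requested
covariates are fitted jointly in one multivariable model (univariable use is
a parameter choice away); patients missing any requested covariate are
dropped casewise and counted. The T2 signal category expands to two
contrasts against the hypointense reference. Initial tumor volume enters
log-transformed — raw mL over a 0.1-64.2 range would let a handful of large
tumors dominate the linear predictor. Continuous covariates are standardized
internally and reported back on per-unit natural scales. Inference is Wald
(z = coef/SE, normal reference, quantile 1.959964), unadjusted for
multiplicity. A sensitivity refit excludes multifocal patients (dropping
the then-constant multifocality covariate).

One caveat specific to the synthetic generator: baseline volume is itself
the realization of the log V0 random effect, so the "initial volume"
covariate is confounded with the correlated (log V0, log K) random effects
and its coefficient is weakly identified there. That is a property of the
generator's truth, not of the inference code; recovery tests for covariate
effects therefore inject effects through independent covariates (e.g. a
binary one).

## Growth classification and margin of error

A tumor is classified on its first-to-last relative volume change
(v_last - v_first)/v_first against a +/-15% cutoff; the boundary counts as
change ("15% or more"). The cutoff is motivated by the measurement-error
analysis: for repeated segmentations of the same tumor the per-pair error is
the symmetric relative difference |v_a - v_b| / mean(v_a, v_b) (neither
segmentation is the truth), the statistic is the median over pairs, and its
uncertainty is a percentile bootstrap (B = 10,000, seeded) over resamples of
the pairs. With ~20 pairs a typical run gives a median error near 0.09 with
an upper confidence limit not far below 0.15, which is what makes 15% a
defensible change threshold.

## Synthetic cohort generator

The generator is the package's test bed and defines the conditions under
which every downstream claim is validated. Defaults emulate a surveillance
cohort of 235 patients:

* scan count: 3 + Poisson(2.4) truncated to at most 14 extra scans
  (median 5, range [3, 17]);
* follow-up: log-normal, median 63 months, log-SD 0.65, truncated to
  [7.2, 188.3] months; scan times are 0 and the follow-up end plus uniform
  order statistics, resampled until consecutive gaps are >= 3 months (the
  scan count is reduced if the follow-up cannot fit it);
* Gompertz truth: log V0 ~ N(log 2.6, 1.1^2) truncated to volumes in
  [0.1, 64.2] mL; growth reserve g = log(K/V0) ~ N(1.0, 0.5^2) truncated
  positive (equivalently, (log V0, log K) jointly normal with
  SD(log K) = sqrt(1.1^2 + 0.5^2) and correlation 1.1/SD(log K), rejected
  until V0 is in range and K > V0); alpha = 0.02/month shared; residual
  log-scale SD sigma = 0.09, matching the ~9% repeat-segmentation error;
* covariates: sex Bernoulli(0.5), age N(63, 12^2) in [18, 90], multifocality
  9.8%, edema 10.1% (7% missing), T2 hypo/iso/hyper 75.7/17.1/7.2%
  (23% missing) — missingness rates chosen so covariate denominators fall
  short of the patient count the way clinical tables do;
* measurement pairs: latent volumes from the baseline distribution, each
  measured twice with independent log-normal errors of log-SD 0.094,
  calibrated analytically (median symmetric difference
  = 0.6745*sqrt(2)*sd = 0.0895) and confirmed by Monte Carlo.

All draws flow from named sub-streams (design, random effects, covariates,
noise) of one root seed, so extending one stream never perturbs another and
cohorts are byte-reproducible.

What the generator does **not** emulate: surgery-triggered censoring,
scanner/slice-thickness effects on error, informative scan scheduling
(scans in response to suspected growth), measurement error that grows for
small tumors, and any real association between covariates and growth other
than those explicitly injected. Passing recovery tests therefore shows the
estimator is correct under the assumed model, not that the model is correct
for any given clinic's data.

Because the true random effects are *truncated* normals while the fitted
model assumes untruncated ones, estimates vary slightly less across
replicates than the model-based standard errors predict; observed Wald
coverage in the recovery study runs a little above the nominal 95% (and the
fixed-effect estimates carry a small (<2%) truncation-induced shift). Both
effects are visible in, and bounded by, the acceptance tests.

## Study sizes used in the validation suite

Simulation studies are sized to be decisive yet cheap: parameter recovery
uses 50 replicate cohorts at the full design size n = 235; model-selection
consistency uses 25 replicates per generating law at n = 50 (AIC gaps
between laws are two orders of magnitude larger than replicate noise at
this size); null-calibration of covariate tests uses 200 replicates of
n = 40 cohorts with shortened scan schedules. The quadrature oracle runs on
10-patient fixtures where 41-node tensor AGQ is effectively exact.

## Known limitations

* The Laplace objective is first-order (Gauss-Newton curvature); for
  strongly nonlinear random effects with few scans per patient it can bias
  variance components, which is why the radial law carries an AGQ
  cross-check rather than a claim of exactness.
* No REML: variance components are ML and biased low in small cohorts.
* The radial law's marginal likelihood is multimodal in (r0, alpha) space;
  the multi-start default (5) is the defense, and `converged` plus the
  comparison table's flags should be inspected on real data.
* Cross-scale model comparison mixes response scales unless the Jacobian
  correction is requested.
* No time-varying covariates, interactions, or multiplicity adjustment.
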