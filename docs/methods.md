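# Methods

## Scientific setting

Active tuberculosis raises heart rate (HR); successful treatment lowers it
back towards a healthy baseline over weeks.  Because the QT interval
shortens as HR rises, QT assessment uses a heart-rate-corrected QTc —
typically a power law `QTc = QT / RR^x` with RR in seconds (Fridericia
x = 0.33, Bazett x = 0.5).  A fixed exponent calibrated to healthy subjects
undercorrects at the elevated pretreatment heart rates of TB patients and
drifts as HR normalises, which can both hide true QT prolongation early in
treatment and fabricate apparent prolongation later.  This package
implements (i) a nonlinear mixed-effects model of HR normalisation on
treatment, (ii) a time-varying correction exponent derived from that
model's recovery rate, and (iii) the machinery to generate synthetic
cohorts, estimate the model, and quantify correction performance.

## Heart-rate model

For subject *i* at treatment time *t* (weeks), clock time *CTIME* (h) and
metabolite (M2) concentration *C* (ng/mL):

```
HR = [B_i + (R_i - B_i)(1 - 2^(-t/Tprog)) + DIUR_i(CTIME)]
     * (1 - Emax * C / (EC50_i + C)) * F_study * F_weight(t) * F_albumin
```

* `B_i = HRbase * e^(eta_B) * (TTP/230.5)^(-0.05)` — individual baseline HR
  (bpm); bacterial burden (MGIT time-to-positivity, h) acts on the baseline.
* `R_i = HRrec * e^(eta_R) * (age/33)^(0.08)` — individual recovered HR; age
  acts on the recovered level.
* `DIUR_i = A24_i cos(2*pi*(CTIME - 15.7)/24) + A12_i cos(2*pi*(CTIME - 10.1)/12)`
  — circadian deviation; one shared random effect scales both amplitudes
  and is Box-Cox shaped, `eta* = (e^(lambda*eta) - 1)/lambda`, lambda = -0.77
  (the identity in the lambda -> 0 limit).
* Drug effect: Emax model, Emax = 0.179 (fraction), EC50 = 2600 ng/mL.
* Composite-HR covariates: body weight (exponent -0.2, reference 56 kg),
  albumin (-0.22, 35 g/L), and a study factor (1 - 0.047) for the
  single-arm study whose population ran typically lower.
* Defaults: HRbase 78.2 bpm, HRrec 73.1 bpm, Tprog 7.74 weeks, A24 6.2 bpm,
  A12 1.65 bpm.

The source publication reports the sub-models and the fitted parameters but
not the fully assembled equation; the assembly above — additive structural
core, multiplicative drug effect and composite covariates, with
parameter-targeted covariates applied inside the core — reproduces every
reported typical value (78.2/73.1 bpm, the ~2% HR decrease at 300 ng/mL,
the ~4.8 bpm circadian maximum in early afternoon) and is documented here
as this package's reconstruction.

Pretreatment observations (t < 0, Day -1 = -1/7 weeks) evaluate at the
t = 0 structural state: the recovery clock starts at treatment start.

Inter-individual variability is log-normal (`p_i = theta * e^eta`) with
variances from the reported CVs via `omega^2 = ln(1 + CV^2)` (CV 15% /
15.4% for baseline/recovered HR, 95.3% shared amplitude, 883.4% EC50) and
the reported correlations (base:rec 0.41, base:amp -0.26, rec:amp -0.421,
prop:add residual 0.38).  Residual error has two levels: a proportional
component (8.4%) drawn per replicate and an additive component (2.7 bpm)
drawn once per triplicate occasion and shared by its replicates — the
sharing rule is this package's reading of "between-triplicates" error; the
alternative (independent per replicate) is not reported distinguishably.

## Estimation

The marginal likelihood integrates the conditional Gaussian density over
each subject's random effects.  We use a Laplace approximation at the
per-subject posterior mode, found by damped Newton iteration on
finite-difference derivatives (inner step tolerance 1e-6, Nelder-Mead
fallback).  Conditional on the random effects, the occasion-shared
additive error gives a compound-symmetric covariance per occasion,
`Sigma = diag((pred*sp)^2) + sa^2 * J`, evaluated by Sherman-Morrison.
With no active random effects the likelihood is closed-form.  The Laplace
approximation is verified in the test suite against adaptive quadrature on
one- and two-random-effect instances (relative agreement 1e-4; exact on a
linear-Gaussian toy).  Accuracy degrades gracefully with very few
observations per subject (the posterior is then visibly non-Gaussian);
the oracle tests use designs with enough replicates per subject for the
expansion to hold.

Fixed effects are optimised by L-BFGS-B on transformed scales (log for
positive parameters and variances, logit for Emax); standard errors come
from the inverse finite-difference Hessian of OFV/2 (OFV = -2 log L) at
the optimum.  Stepwise covariate selection uses the conventional
likelihood-ratio thresholds: forward inclusion at dOFV > 3.84 (P < 0.05,
1 df), backward elimination at dOFV < 6.63 (P < 0.01).

## Time-varying correction factor

```
CF(t) = 0.4081 - 0.0781 * (1 - 2^(-t / 7.74)),   t in weeks (t < 0 -> 0.4081)
```

The exponent starts at the TB-pretreatment value 0.4081 (Olliaro's
population estimate) and relaxes to Fridericia's 0.33 with the same
half-life as HR recovery (7.74 weeks) — the prespecified assumption being
that the HR change rate drives the change in the QT-HR correlation.
`QTcTBT = QT / RR_s^CF(t)`.  Constant-exponent corrections (Bazett,
Fridericia, Olliaro) plus the linear Framingham (`QT + 154*(1 - RR_s)` ms)
and Van de Water (`QT - 0.087*(RR_ms - 1000)`) formulas are provided with
units exactly as each formula is conventionally printed.  Fridericia's
exponent is taken as 0.33 (not 1/3), matching the correction-factor
endpoints.

## Correction-quality evaluation

Two steps over eight prespecified bins (pretreatment, weeks 0-1, 2-3, 3-4,
5-8, 9-12, 13-20, 20-24; shared boundaries belong to the earlier bin, gaps
such as week 1.5 are excluded):

1. Per bin, OLS of QTc (ms) on HR (bpm).  Replicates enter individually;
   because triplicates share a subject-level QTc, slope standard errors
   are clustered by subject (classical OLS SEs are available but
   anticonservative on exactly this structure).
2. Weighted least squares of the bin slopes on bin midpoint time
   (pretreatment maps to midpoint 0), weights 1/SE^2.  The intercept is
   the QTc-HR slope at treatment start and the slope is the drift in
   correction quality; both should be ~0 for a successful correction.

The WLS *point estimates* follow the conventional two-step procedure, but
the default confidence intervals do not use the plain WLS variance: the
same subjects contribute to every bin of a longitudinal study, so
bin-slope errors are positively correlated and the naive interval
undercovers badly (we measured ~25-60% coverage for a nominal 95% trend
CI on matched simulations).  Instead the between-bin covariance of the
slopes is estimated from per-subject influences (a cluster outer-product,
as in cluster-robust meta-regression) and propagated through the WLS
projection; measured coverage is then at the nominal level.  `ci="wls"`
restores the plain interval.

## Synthetic cohorts

The generator emulates the design of the estimation trials: ~440 subjects
(placebo fraction 105/440, nested in the two-arm study), Day -1 plus
weeks 1, 2, 4, 8, 12, 16, 20 and 24, triplicate ECGs at daytime clock
times drawn uniformly on [8, 17] h (the real schedule is not published;
this is a plausible emulation covering every reporting bin).  Covariates
are independent truncated log-normals matched to the published medians and
ranges (age 33 y, weight 55 kg, albumin 35 g/L, TTP MGIT 230.5 h); the
joint distribution is not published, so no correlation is imposed.
Metabolite exposure uses a phenomenological accumulation curve
`Conc(t) = Css_i * (1 - 2^(-t/t_acc))` with t_acc = 2 weeks and Css
log-normal with median 600 ng/mL (CV 45%), putting the population mean at
Week 2 at ~300 ng/mL as observed; it replaces a full population-PK
simulation, which is out of scope.  QT is generated as
`QT = QTc0_i * RR^CF_true(t) * e^(sigma_qt*eps)` with QTc0 median 400 ms
(5% CV) and sigma_qt 2% — deliberately simple but realistic values.
HR positivity is enforced by resampling offending residual draws (at
most 100 attempts).

What the generator does *not* emulate: treatment non-response (HR that
fails to normalise), dropout and missed visits, correlated covariates,
drug effects on QT itself, and mechanistic pharmacokinetics.  Passing
tests therefore show that the pipeline is internally consistent and
recovers its own truth under the trial-like design — not that the model
fits any particular real dataset.

## Prespecified simulation studies

* **HR recovery** (`hr_recovery_study`): 3 replicate cohorts of 200
  subjects, baseline/recovered-HR IIV only, covariates at reference, no
  exposure; fit of (HRbase, HRrec, Tprog, both omega^2, both sigmas) from
  deliberately misspecified starting values; the study summary is the
  median per parameter.  Replicate SEs at this n are ~1% for the HR levels
  and ~13-15% for Tprog.
* **Emax recovery** (`emax_recovery_study`): 5 replicate cohorts of 200
  subjects with individual steady-state concentrations uniform on
  0-8000 ng/mL (no EC50 IIV); joint fit of the structural and drug-effect
  parameters.  The concentration cap reaches only ~75% of saturation, so
  (Emax, EC50) lie on a likelihood ridge and single-cohort Emax estimates
  scatter with ~17% relative SD; the median across replicates is the
  study's summary.
* **Correction quality** (`correction_quality_experiment`): 100 replicate
  cohorts of 440 subjects whose QT is generated under the true
  time-varying exponent; per replicate, the two-step evaluation for
  Bazett, Fridericia and the time-varying method.  Reported: per-bin
  zero-coverage, the trend-CI coverage rate for the time-varying method,
  and the rates at which Fridericia's intercept is significantly negative
  (undercorrection) and Bazett's significantly positive (overcorrection).

Problem sizes (200 x 3 / 200 x 5 / 440 x 100) were chosen so each study
runs in minutes on a single core while keeping Monte-Carlo error well
inside the tolerances above.

## Numerical choices and edge cases

* Seeds propagate through `numpy.random.SeedSequence`; every simulation
  and fit is bit-reproducible at a fixed seed.
* Degenerate inputs: subjects with a single observation keep a
  well-defined likelihood; bins with < 3 records or zero HR variance are
  skipped with a warning; empty VPC bins are dropped; a missing arm in a
  placebo-corrected bin omits the bin.
* Missing concentration values are treated as 0 (no exposure) with a
  logged warning.
* Non-positive HR predictions during estimation mark the parameter region
  as pathological (large penalty) rather than crashing the line search.

## Known limitations

* The composite-model assembly and the Box-Cox formula are
  reconstructions; alternatives that reproduce the same typical values
  exist.
* The Laplace approximation, like any, can bias variance components at
  very sparse designs; the quadrature oracle covers 1-2 random effects
  only.
* The study-effect direction (lower HR in the single-arm study) follows
  the narrative description; the tabulated coefficient is printed with the
  opposite sign, and the package makes the direction configurable.
* Real ECG waveform formats, individual (subject-specific) correction
  factors, and re-analysis of the original trial data are out of scope.
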