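# Methods

## Generative model

Time to CVD event and time to non-CVD death are Weibull
proportional-hazards processes sharing one individual random effect
(log-frailty) ε ~ N(0, σ²):

    H_c(t | X, ε) = (t/λ_c)^γ_c · e^(βX + ε),   H_m(t | ε) = (t/λ_m)^γ_m · e^ε.

The baseline is parameterised with the scale λ in the denominator, in
years: H₀(t) = (t/λ)^γ.  This is the only parameterisation under which the
default constants give a sensible cohort — untreated ten-year CVD risk
0.1935 at ε = 0 and ≈ 0.22 on average — and it makes λ directly
interpretable as a characteristic time.  Event times are drawn by inverse
transform, T = λ(−ln U)^{1/γ}e^{−η/γ}, so the same uniform draw maps
monotonically to a time for any linear predictor η, and results are
platform-reproducible given the generator.

The shared frailty serves two purposes: it creates between-patient risk
heterogeneity (the quantity refusal can correlate with) and it couples the
two event processes, making censoring by death informative.  On the log
scale the induced correlation is exactly σ²/(σ² + π²/6) = 0.2295 at
σ = 0.7 (the Weibull shape cancels); the Pearson correlation of the raw
latent times is slightly higher, ≈ 0.29, because the exponentiated frailty
is right-skewed.  Both are computed by the package; the raw-scale value is
what a correlation of simulated time pairs measures.

Treatment acts only on the CVD hazard, with conditional log hazard ratio
β = −0.32 (default), i.e. an average 25% reduction in individual ten-year
risk.  There is no effect on mortality, no time-varying covariate, and the
treatment effect is homogeneous.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| λ_c, γ_c | 36 y, 1.2 | CVD-event Weibull scale and shape |
| λ_m, γ_m | 55 y, 1.2 | mortality Weibull scale and shape |
| σ | 0.7 | SD of the individual random effect |
| β | −0.32 | log HR of the intervention on CVD |
| T_max | 3 y | administrative follow-up |

One calibration caveat is worth stating plainly: with σ = 0.7 the SD of the
untreated ten-year risk across the cohort is ≈ 0.135 (coefficient of
variation 0.60).  A cohort with risk SD ≈ 0.087 at the same mean would
require σ ≈ 0.45; with the parameters above, the larger spread is a
property of the model and the package reports it honestly rather than
adjusting σ.

## Refusal structure

Individual patient refusal probabilities are an equally spaced grid on
(LL, UL), with (LL, UL) = ((1∓w)p, (1±w)p) for w ∈ {0, ⅓, ⅔, 1} (levels
zero/low/medium/high).  The grid is assigned to the whole cohort by the
rank of ε before randomisation, ascending for positive risk–refusal
correlation and descending for negative; ties (measure-zero) break by
index.  The construction keeps the cohort mean exactly p at every level, n
and direction, which the tests assert to 1e−12.  Clinician refusal q_i uses
the same mechanism with its own level and direction, defaulting to
risk-uncorrelated (level zero), since only its average is specified in the
study design the grids replicate.  Uptake in the intervention arm is the
conjunction of two independent Bernoulli acceptances; the control arm never
receives treatment, so X ≤ Z is structural.

## Estimators

All four methods fit Cox proportional-hazards models to (Y, 1−C):

* ITT: covariate Z, all rows.
* PP: rows with Z=1, X=0 removed; covariate X.
* 2SPS: covariate X̂ = E(X|Z).  With a binary instrument the first stage is
  saturated, so X̂ is the arm-wise mean of X and linear/logistic first
  stages coincide.  Because X̂ = c·Z for the uptake rate c, the 2SPS
  coefficient is exactly the ITT coefficient divided by c and the Wald
  tests are identical — asserted to machine precision in the tests.
* 2SRI: covariates (X, R) with R = X − X̂; the coefficient of X is
  reported.  Under perfect compliance R ≡ 0; the column is dropped with a
  logged warning and the fit degrades gracefully to the ITT fit.

Second-stage standard errors are the model-based ones, with no correction
for first-stage uncertainty; they are used for p-values (hence power)
only.  Precision comparisons between methods use the empirical SD of
estimates across replicates, which requires no such correction.  This is
the standard plug-in two-stage limitation and is deliberate.

### The Cox fitter

Replicate loops refit thousands of Cox models, so the package carries its
own vectorised Newton–Raphson partial-likelihood solver (`cmrctsim.coxph`):
times sorted once, risk-set sums as prefix sums, Efron tie corrections
computed group-wise with `reduceat`, step-halving for monotone ascent.  It
handles one or two covariates (all this package needs) in ~4 ms at
n ≈ 10⁴.  lifelines' `CoxPHFitter` is the independent oracle in the test
suite: coefficients, SEs and p-values agree to 1e−6 with and without tied
times.

## Performance measures

Per scenario and method, over n_sim replicate trials: mean estimate β̄,
relative bias (β̄ − β)/β × 100 (so attenuation of a protective effect is
negative), power = fraction of Wald p-values < 0.05, empirical SE =
SD(β̂_j), and the Monte-Carlo SE of β̄ = SD/√n_sim.  The last two are
reported separately and never interchanged.  All methods are applied to the
same replicate datasets within a scenario, so method contrasts are paired;
each scenario gets an independent substream.

## Sample size

`required_sample_size` inverts the power simulation: double n from 100
until the target (default 0.80 at α = 0.05, ITT, 4:1 allocation) is
bracketed, bisect to a granularity of 50, confirm the candidate at a larger
replicate count, stepping up by one granule if the confirmation falls
short.  Each candidate n is evaluated with a seed derived
deterministically from (search seed, n), making the search stable and
repeatable.  Sizing drives ITT because that is the primary analysis the
design anticipates; "with refusal" sizing simulates level-zero
(risk-uncorrelated) refusal at the expected rates, i.e. treats refusal as
non-informative for sizing while the evaluation scenarios keep it
informative.  At the defaults this yields roughly n ≈ 9,500–10,000 without
refusal and n ≈ 15,500–16,500 with refusal at p = 0.2; the exact value
moves a few hundred with the search seed, as expected of a Monte-Carlo
calibration with 200-replicate bracketing.

## Randomness discipline

Everything flows from integer seeds through `numpy.random.SeedSequence`:
one master seed per run, one child per scenario cell, one grandchild per
replicate trial.  Replicates are therefore independent of evaluation order
and of how many are requested (the first 200 replicates of a 1000-replicate
run are the same trials).

## Problem sizes used by the shipped checks

Population calibration summaries use 100,000 simulated individuals.
Scenario evaluations in the acceptance script use 1000 replicate trials per
cell (2000 for the IV-bias cell, whose quantities are smallest relative to
Monte-Carlo noise); the test suite uses 200–400 replicates with
correspondingly wider Monte-Carlo tolerances (power SE ≈ 0.035 at 200
replicates; bias tolerances of a few percentage points).  These are the
package's chosen desk-scale conditions; rerunning any cell at higher
replication only narrows the Monte-Carlo bands.

## What the simulator does and does not emulate

It emulates: risk heterogeneity, informative censoring by death through
the shared frailty, refusal confined to the intervention arm with
controllable risk correlation, unequal allocation, administrative
censoring, and sizing under two recruitment assumptions.  It does not
emulate: staggered entry or loss to follow-up beyond death and T_max,
partial compliance short of refusal, heterogeneous treatment effects,
effects of treatment on mortality, cluster randomisation, or several
concurrent trials drawing on one cohort.  Conclusions from passing tests
are therefore about this idealised design, not about any particular real
cohort.

## Known limitations

* Two covariates maximum in the Cox fitter — sufficient for the four
  methods, not a general regression tool.
* IV p-values ignore first-stage uncertainty (see above); empirical SEs
  across replicates are the precision measure of record.
* The 2SRI power band claimed for the without-refusal design
  (0.65–0.70) is not reproduced at average refusal p = 0.3, where this
  simulator finds ≈ 0.48–0.56; the band is consistent with our results
  only at p ≤ 0.2.  With IV standard errors ≈ 0.16 and 2SRI mean bias
  ≈ +11% at p = 0.3, a power below 0.65 is what a normal-approximation
  back-of-envelope also gives, so the discrepancy is documented rather
  than calibrated away.
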