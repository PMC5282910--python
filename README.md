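# cmrctsim

Simulation and estimation toolkit for **individually randomised
trials-within-cohorts** (the cohort multiple randomised controlled trial,
cmRCT) with a time-to-event endpoint, where **refusal of the intervention
exists only in the intervention arm** and may be correlated with each
patient's underlying event risk.

In a cmRCT, eligible patients in a consented observational cohort are
randomly *offered* an intervention; the rest continue on standard of care.
Only the offered patients can refuse, so the intervention arm is a mixture
of treated and untreated individuals — and if refusers differ systematically
in risk, naive analyses are biased. `cmrctsim` generates such trials and
compares four analysis methods on bias, statistical power and precision:

* **ITT** — intention-to-treat, outcome on allocation *Z*;
* **PP** — per-protocol, excluding intervention-arm refusers;
* **2SPS** — two-stage predictor substitution, outcome on the first-stage
  fitted value X̂ = E(X|Z);
* **2SRI** — two-stage residual inclusion, outcome on treatment received *X*
  plus the first-stage residual R = X − E(X|Z).

All effect estimates are Cox proportional-hazards log hazard ratios.

## The generative model

Each individual *i* carries a normal random effect ε<sub>i</sub> ~ N(0, σ²)
(a log-frailty) entering both the CVD-event hazard and the competing
mortality hazard, inducing informative censoring by death:

    H_c(t) = (t/λ_c)^γ_c · exp(β·X_i + ε_i)      (CVD event)
    H_m(t) = (t/λ_m)^γ_m · exp(ε_i)              (mortality)

with defaults λ_c = 36, γ_c = 1.2, λ_m = 55, γ_m = 1.2, σ = 0.7,
β = −0.32 and administrative follow-up T_max = 3 years.  The observed data
per individual are {Y_i, C_i, Z_i, X_i} with Y = min(T_c, T_m, T_max) and
C = 1 when death or follow-up end precedes the CVD event.  β = −0.32
corresponds to an average 25% reduction in ten-year CVD risk.

Refusal scenarios spread individual refusal probabilities on an equally
spaced grid between limits (LL, UL) ∈ {(p,p), (2p/3,4p/3), (p/3,5p/3),
(0,2p)} — correlation levels zero/low/medium/high — handed out in the order
of ε, ascending (positive correlation: higher risk refuses more) or
descending (negative).  Treatment received is
X = min{Bern(1−p_i), Bern(1−q_i)} in the intervention arm, 0 otherwise.

Trial sizes come from a simulation-based search (0.80 power, α = 0.05,
4:1 control:intervention allocation), either ignoring refusal
("recruitment without refusal") or inflating for the expected,
non-informative refusal rate ("recruitment with refusal").

## Worked example

Simulate one trial of 10,000 patients with average patient refusal p = 0.2
strongly positively correlated with risk, then analyse it:

```sh
cmrctsim simulate --out trial.csv --n-obs 10000 --p 0.2 \
    --level high --direction positive --seed 7
cmrctsim analyze trial.csv
```

```
method  beta_hat  hazard_ratio   se_hat  p_value  n_used
   ITT -0.267217      0.765507 0.115139 0.020297   10000
    PP -0.539810      0.582859 0.143752 0.000173    9567
  2SPS -0.341055      0.711020 0.146955 0.020297   10000
  2SRI -0.438195      0.645200 0.155355 0.004793   10000
```

The true conditional log hazard ratio is −0.32.  On this single realisation
the ITT estimate is diluted toward zero by the ~20% refusal (−0.27), PP
overshoots because the high-risk patients removed themselves from the
intervention arm (−0.54), and the two IV methods land nearer the truth,
with visibly larger standard errors — exactly the qualitative pattern the
replicate machinery quantifies.  Note 2SPS reproduces the ITT p-value: X̂ is
an affine function of Z, so the two tests are identical.

The same machinery is available from Python:

```python
import numpy as np
from cmrctsim import ModelParams, population_risk_summary

mean, sd = population_risk_summary(100_000, ModelParams(), np.random.default_rng(0))
print(f"mean {mean:.3f} sd {sd:.3f}")   # mean 0.225 sd 0.135
```

i.e. the untreated cohort has a mean ten-year CVD risk of about 22% —
a population eligible for lipid-lowering therapy.

Scenario grids (`cmrctsim grid config.yaml --out results.csv`) run the full
factorial of refusal means × correlation levels × directions × recruitment
methods, one tidy CSV row per cell and method, resumable after
interruption.  `cmrctsim samplesize` and `cmrctsim power` expose the sizing
engine directly.

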