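# clearmark

Early monoclonal-antibody **clearance** as a prognostic biomarker for
non-response in immune-checkpoint-inhibitor therapy — implemented as a
tested, reusable analysis pipeline exercised end to end on synthetic
cohorts.

Checkpoint-inhibitor antibodies such as pembrolizumab are eliminated mainly
by catabolism, and cancer-associated hypercatabolism both raises baseline
clearance and blunts the clearance *decline* normally seen in patients who
respond to treatment. Both signals are measurable from sparse drug
concentrations early in therapy, making individual clearance an attractive
early biomarker in advanced NSCLC, where switching away from an ineffective
drug quickly matters. This package provides the complete chain needed to
study that idea:

1. **Population-PK simulation** (`clearmark.cohort`) — virtual patients
   with demographics, 200 mg q21d dosing, sparse peak/mid/trough/post
   sampling, log-normal between-subject variability, combined residual
   error and LLOQ censoring; PFS/OS drawn from Weibull
   proportional-hazards models whose hazards increase with baseline
   normalized clearance and with a diminished clearance decline.
2. **Individual clearance estimation** (`clearmark.estimate`) — empirical
   Bayes (MAP) estimation of per-patient random effects under a frozen
   population model, statsmodels-style:
   `IndividualPKModel(times, conc, doses, lbw, pop).fit()` returns an
   `IndividualPKResults` with the lean-body-weight-normalized clearance at
   the first dose, at 6 weeks, their percent change, and a `summary()`.
3. **Cut-point discovery and survival analysis** (`clearmark.survival`) —
   maximally selected rank statistics with the Lausen–Schumacher adjusted
   p-value, Kaplan–Meier curves, log-rank tests and univariate Cox
   regression (Efron ties).
4. **Response diagnostics** (`clearmark.diagnostics`) — disease control at
   6 months as the response definition; sensitivity, specificity, PPV and
   NPV with Wald (or Wilson) intervals.
5. **Limited-sampling evaluation** (`clearmark.sampling`) — Monte Carlo
   comparison of a two-sample design (peak directly after the first
   infusion, trough on day 21) against study-like sparse sampling, scored
   by MPE (bias) and NRMSE (precision) of the recovered baseline clearance
   against the simulated truth.

## The model

Drug disposition is a two-compartment model with zero-order infusion input
and a clearance that declines sigmoidally over treatment time

```
CL_i(t) = CL0_i · (1 − Imax_i · t^γ / (T50^γ + t^γ)),
```

with `CL0_i = CL0_pop · (LBW_i/52.5)^0.75 · exp(η_CL)` and analogous
allometric/log-normal terms for the volumes. Lean body weight comes from
the Janmahasatian equations, and clearances are compared across patients
after normalization to the 52.5 kg LBW reference. Individual random
effects are estimated by minimizing the standard penalized least-squares
MAP objective

```
Σ_j [ (DV_j − F_j(η))² / g_j² + ln g_j² ]  +  ηᵀ Ω⁻¹ η,
g_j² = (σ_prop · F_j)² + σ_add² .
```

Cut points on the two derived markers — normalized first-dose clearance
and its percent decline over 6 weeks — maximize the standardized log-rank
statistic over candidate splits between the 10th and 90th marker
percentiles ("high" group = marker ≥ cut point everywhere).

## Worked example

```python
from clearmark.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, outdir="cm_demo")
cfg.cohort.n = 303          # cohort size
cfg.analysis.eval_n = 300   # Monte Carlo size for the design comparison
run_pipeline(cfg)
print(open("cm_demo/summary.txt").read())
```

prints

```
clearmark pipeline report  (seed=1, config=54463775bde7)

cohort: n=303, median CL0_norm=0.278 L/day, median 6-week decline=22.7%
events: PFS 69%, OS 55%  (non-converged fits: 0)

baseline CL (high): cut PFS=0.275 (adj p=2.6e-05), OS=0.348
  PFS: HR=2.05 [1.55, 2.71], p=4.93e-07
  OS: HR=1.62 [1.18, 2.21], p=0.00253
6-week decline (low): cut PFS=20.143 (adj p=0.000115), OS=30.940
  PFS: HR=2.15 [1.61, 2.86], p=1.9e-07
  OS: HR=2.31 [1.69, 3.16], p=1.68e-07

design limited: MPE=+10.0%, NRMSE=26.1% (n=300)
design rich: MPE=+7.8%, NRMSE=24.0% (n=299)
```

Reading this: the simulated cohort's median normalized baseline clearance
is 0.278 L/day and clearance falls by a median 22.7% over the first six
weeks. Dichotomizing at the data-driven cut points, patients with high
baseline clearance progress about twice as fast (HR ≈ 2), and patients
whose clearance fails to decline do comparably badly — the two biomarker
signals the pipeline is built to quantify. The design comparison shows a
two-sample schedule loses little precision relative to full study-like
sampling (NRMSE 26% vs 24%). The same stages are available from the shell
via `clearmark simulate|estimate|cutpoint|diagnostics|eval-design|run-all`.

## Layout

```
src/clearmark/     params, pk, cohort, estimate, survival, diagnostics,
                   sampling, pipeline, cli
tests/             unit + property tests, acceptance checks
docs/methods.md    model, assumptions, calibration and numerical choices
examples/          example population-parameter JSON
```
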