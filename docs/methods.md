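# Methods

## Structural pharmacokinetic model

Disposition is a linear two-compartment model (central volume V1,
peripheral V2, inter-compartmental clearance Q) with zero-order infusion
input, in days / litres / mg. Elimination clearance varies with treatment
time through a sigmoidal maximum-inhibition (Hill) function

    CL_i(t) = CL0_i · (1 − Imax_i · t^γ / (T50^γ + t^γ)),

the conventional description of the slow on-treatment decline of
checkpoint-inhibitor clearance: CL(0) = CL0, monotone non-increasing,
asymptote CL0·(1 − Imax). Body-size effects enter through allometric
scaling on Janmahasatian lean body weight around a 52.5 kg reference
(exponent 0.75 on CL and Q, 1.0 on volumes, both configurable). Between-
subject variability is log-normal on CL0, V1 and Imax; an individual's
realized Imax is capped at 0.95 so that clearance cannot reverse sign.
Two boundary conditions of the LBW regression are handled explicitly:
anthropometrics are validated to 30–200 kg / 120–220 cm, and below
BMI ≈ 12 (where the male regression exceeds total mass) lean mass is
capped at 99% of body weight.

The model deliberately excludes target-mediated or concentration-dependent
elimination, immunogenicity, and covariates beyond lean body weight.

## Concentration computation

The default engine propagates the two-compartment state with exact 2×2
matrix-exponential steps, holding clearance at its midpoint value within
steps of at most 0.25 day; step boundaries sit on an absolute time grid so
that the discretization — and hence superposition of dose contributions —
is independent of the dose/observation layout. Dose starts, dose ends and
observation times are always breakpoints. An adaptive ODE integration of
the full time-varying system (LSODA, rtol 1e-10) is retained as the
reference; the fast path agrees with it to ≲1e-5 relative under the
default decline and to <1e-6 when clearance is constant, comfortably
inside the 0.5% gate enforced by the test suite.

## Individual (MAP) estimation

Population parameters are fixed; only the individual random effects η are
estimated, by minimizing the standard penalized least-squares objective

    Σ_j [ (DV_j − F_j(η))²/g_j² + ln g_j² ] + ηᵀΩ⁻¹η,
    g_j² = (σ_prop F_j)² + σ_add²,

i.e. the negative log posterior under log-normal random effects and
combined residual error, with the residual variance evaluated at the
model prediction (the "interaction" convention). Minimization is
L-BFGS-B on η with bounds at ±6 prior SDs, objective tolerance 1e-8, and
two additional random restarts when the first attempt fails; a fit is
declared converged when the optimizer succeeds or the finite-difference
gradient norm is below 1e-3·(1+|f|), the noise floor of the numerical
gradient. Patients whose observations are all below the LLOQ are
ineligible (mirroring the cohort's eligibility rule); BLQ observations of
eligible patients are discarded (M1 handling). The quantities reported
per patient are CL at the first dose, CL at day 42 under the individual
decline curve, the LBW-normalized baseline value, and the percent change
— 6 weeks being the conventional first-response-evaluation window.

Known behaviour, not a defect: with 1–3 samples per patient the MAP
estimate shrinks toward the population-typical value, and the ln g²
term biases predictions slightly low (hence clearance slightly high).
Both effects are inherent to empirical-Bayes estimation under sparse
designs and are visible in the Monte Carlo results below.

## Synthetic cohort

The generator emulates a 303-patient advanced-NSCLC cohort treated with a
flat 200 mg q21d regimen: weight truncated-normal (mean 72, SD 16, range
38–124.5 kg), 45% female, sex-specific heights, regimen mix 26/59/15%
(monotherapy / pemetrexed-platinum / paclitaxel-platinum combinations),
40% PD-L1 ≥ 50%. Per-patient sample counts follow a discretized
log-normal with median 3 (clipped to 1–16); kinds are drawn as
peak / mid / trough / post with probabilities 0.30/0.20/0.40/0.10 and
timed accordingly (peak = end of a 30-minute infusion; trough =
immediately pre-dose; post up to 100 days after the last cycle).
Observations get combined proportional-plus-additive error and are
flagged BLQ below the 0.5 mg/L default LLOQ.

Default population parameters (`default_pop_params()`): disposition
V1 = 3.48 L, V2 = 4.06 L, Q = 0.795 L/day and variability magnitudes
(ω²: CL 0.112, V1 0.047, Imax 0.25; σ_prop 0.20, σ_add 0.2 mg/L) follow
the published mAb population-PK convention, while CL0_pop = 0.279 L/day
and the decline parameters (Imax 0.42, T50 40 d, γ 1.5) are anchored
analytically so the cohort reproduces a median normalized first-dose
clearance of 0.279 L/day and a median 6-week decline of 21.7% — the
values reported for the real-world cohort this generator emulates.

Survival: PFS and OS are Weibull proportional-hazards draws with linear
predictor β_CL·log(CL0_norm/0.279) + β_Δ·(0.217 − Δ), Δ the fractional
6-week decline; covariates are centered at the cohort medians so the
configured marginal medians (9.6 / 18.1 months) are preserved. The
coefficients (PFS: shape 1.1, β_CL 1.32, β_Δ 2.62; OS: shape 1.2,
β_CL 1.44, β_Δ 4.18) were calibrated once, by simulation, so that
dichotomizing at the anchored cuts (0.232 L/day; 15.8% decline) induces
group hazard ratios near 2.0/1.46 (PFS) and 2.04/1.82 (OS). Censoring is
administrative (uniform 13–44 months, a staggered-enrollment window) plus
exponential loss to follow-up (means 40 / 150 months for PFS / OS),
giving event fractions near 65% / 60%.

What the generator does **not** emulate: RECIST lesion dynamics (response
labels derive from simulated PFS only), treatment discontinuation or dose
modification, correlation between PFS and OS beyond their shared
dependence on the clearance markers, covariate effects (albumin, eGFR,
ECOG) on clearance or hazard, and assay drift. Passing tests therefore
demonstrate internal consistency of the method chain under a faithful
statistical emulation, not clinical performance on real data.

## Cut points, survival analysis, diagnostics

Maximally selected rank statistics: observations receive log-rank
(Savage) scores a_i = δ_i − H(t_i) with H the Nelson–Aalen cumulative
hazard (scores sum to zero exactly); for a candidate threshold the sum of
scores in the low group is standardized by its permutation variance
m(N−m)/(N(N−1))·Σa², and the threshold maximizing |Z| over candidates
whose low-group proportion lies in the 10th–90th percentile band is
selected, ties resolved toward the smaller cut point. The adjusted
p-value uses the Lausen–Schumacher Ornstein–Uhlenbeck crossing
approximation, clipped to (0, 1]. PFS and OS cut points are computed
independently and both reported. All-equal markers, fewer than 10
records, or an empty candidate band raise errors.

Kaplan–Meier (with Greenwood bands), the two-sample log-rank test and
univariate Cox regression delegate to lifelines; Cox uses Efron tie
handling (sensible at monthly resolution) with Wald intervals
exp(logHR ± 1.96·SE). No events, or a monotone likelihood, yield an
error / a flagged non-converged fit rather than a spurious number. The
"high = marker ≥ cut point" convention is applied everywhere downstream;
for the decline marker the at-risk group is the *low*-decline one.

Response is disease control at 6 months: non-responder iff progression
occurred on or before the horizon. Records censored before the horizon
are classified responders by last known status — chosen so the
responder/non-responder split partitions the whole cohort — with the
count logged; exclusion is available via `classify_cohort` filtering.
Diagnostic metrics carry Wald intervals clipped to [0,1] (Wilson
optional); zero-denominator metrics are NaN and flagged undefined.
`table_from_rates` reconstructs integer 2×2 counts from a cohort split
plus printed sensitivity/specificity, which is how the published
predictive values are re-derived exactly.

## Limited-sampling Monte Carlo

Designs are compared by simulating patients (full between-subject
variability and residual error), MAP-estimating each patient's normalized
baseline clearance *from that design's samples only*, and scoring against
the known truth with per-patient relative errors:

    MPE = 100·mean((est−true)/true),  NRMSE = 100·sqrt(mean(((est−true)/true)²)),

so NRMSE² ≥ MPE² by Jensen's inequality on every run. The limited design
is one peak directly after the first infusion plus one trough on day 21
at 200 mg q21d; the rich arm re-uses the study-like sparse design above.
Headline runs use 1,000 virtual patients per design; a design leaving
more than 10% of patients entirely BLQ aborts with a diagnostic.

Under the default conditions the limited design gives MPE ≈ +9% and
NRMSE ≈ 25%, statistically indistinguishable from the study-like arm —
the qualitative conclusion (two samples suffice; the information gap is
small) is robust. The absolute level, however, scales almost linearly
with the residual-error SD (σ_prop 0.05/0.10/0.15 → NRMSE ≈ 7/13/18%),
so these two numbers should be read as conditional on the assumed 20%
assay error, which is the least certain of the default parameters.

## Pipeline and reproducibility

`run_pipeline` chains simulate → LLOQ filter → outcomes → MAP estimation
→ cut points (both markers × both endpoints) → KM/Cox → subgroup
comparison (chemotherapy addition within PD-L1 ≥ 50%) → diagnostics →
design evaluation, writing CSV/JSON artifacts each stamped with the seed
and a hash of the scientific configuration (output paths excluded from
the hash). A stage failure aborts with the stage name, retaining partial
outputs. Everything is reproducible bit-for-bit from the seed; the
synthetic-data CSVs use the long pharmacometric layout (ID, TIME, AMT,
RATE, DV, BLQ, EVID, WT, HT, SEX) so they can be consumed by external
tools. YAML configurations are validated by the same pydantic models
that define the in-memory API.

Problem sizes in the shipped tests were chosen to keep the full suite in
the minutes range while leaving the stochastic checks well-powered:
n = 2000 for generator calibration checks, 200 replicates for Cox
coverage/recovery, 500 replicates for the cut-point null, 500 patients
for estimator-recovery runs.
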