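# Methods

## Model structure

A cohort of identical patients (65 kg, 1.72 m², CrCl 70 ml/min) starts
progression-free on first-line therapy and is simulated deterministically
over 521 cycles of 21 days (30 years). States: PFS on treatment, PFS off
treatment (after adverse-event discontinuation), progressive disease
(PD), death (absorbing).

Each cycle `t ≥ 1`:

1. **Death** from any alive state with probability
   `1 − S_os(t)/S_os(t−1)`, where `S_os` is the arm's overall-survival
   Weibull. No separate PD mortality is parameterised, so the same OS
   hazard applies from PFS and PD; as a consequence the alive fraction
   equals `S_os(t)` exactly.
2. **Progression** from either PFS substate with probability
   `max(0, [1 − S_pfs(t)/S_pfs(t−1)] − p_death(t))`. The floor matters in
   early cycles, where the fitted OS hazard exceeds the PFS exit hazard;
   flooring preserves the probability axioms.
3. **Discontinuation**: among on-treatment patients who remain
   progression-free and alive this cycle, a constant per-cycle
   probability (combination 0.004298, chemotherapy 0.006372) moves mass
   to PFS-off. Survival transitions are applied first, then
   discontinuation among stayers; the alternative ordering changes
   results well below reporting precision but is fixed for
   reproducibility. Discontinuation is one-way (no restart).

The combination arm applies hazard ratios to the Weibull scales only
(OS 0.654, PFS 0.405); shapes are shared. Exit probabilities are
computed on cumulative-hazard differences with `expm1`, so they stay
accurate when `S(t)` underflows near the end of the horizon.

## Accrual, discounting, effectiveness

Costs and outcomes accrue at cycle start over rows 0..521 (the row-0
accrual is the cohort's first treatment cycle; the lump adverse-event
cost lands there at discount factor 1). Discounting is continuous:
`(1.05)^(−t·21/365.25)`. No half-cycle correction is applied by default;
both the correction and the discount rate are configuration switches.

Two effectiveness accumulators are always computed per arm:

* **discounted life-years** — alive occupancy × cycle length;
* **utility-weighted QALYs** — PFS utility 0.856, PD utility 0.768, with
  the arm's adverse-event disutility (0.061 / 0.080) subtracted while on
  first-line treatment only.

Which one the incremental analysis reports as "effectiveness" is the
`effectiveness_measure` configuration field. **The packaged
base-case configuration uses discounted life-years.** This is a
deliberate reproduction finding: the published per-arm effectiveness
values (1.63 and 2.11, incremental 0.48) are matched to printed
precision by discounted life expectancy on this structure, on both arms
simultaneously, while applying the published utility weights yields
1.26 and 1.64 under every structural variant we examined. We conclude
the original model's effectiveness output corresponds to unit utility
weights, and we reproduce it as such; the full utility machinery remains
implemented, tested, and one switch away (`effectiveness_measure: qaly`).

## Costing

Drug acquisition applies to on-treatment occupancy: LY01008 15 mg/kg
every cycle until progression or discontinuation (maintenance);
paclitaxel 175 mg/m² and carboplatin (Calvert formula, target AUC 6) for
the first 6 cycles. Prices are per small priced unit (US$ 24.99 per
15 mg LY01008, 57.51 per 175 mg paclitaxel, 1.37 per 6 mg carboplatin)
and default to exact per-mg proration (`linear-mg`), which is what
per-small-unit price normalisation implies; whole-vial rounding
(`round-up-vial`) is available. Both PFS substates incur routine
follow-up (55.60/cycle); PD incurs a mix of subsequent therapy
(854.05/cycle) and best supportive care (337.50/cycle) weighted by the
subsequent-therapy proportion; each death incurs one terminal palliative
cycle (2,627.80). Lump AE costs (1,025.82 / 745.01) are charged once at
treatment start — trial AE frequencies are per treatment course, not per
cycle. The nivolumab unit price is carried in the configuration for
sensitivity-analysis completeness, but PD costs use the lump
subsequent-therapy figure. The internal currency is USD; CNY is a
reporting conversion at 6.8974 CNY/USD, the rate implied consistently by
three independent printed USD/CNY pairs.

## Calibration of open structural settings

Three structural inputs are not printed in the source tables and were
fixed once by calibrating the base case against the published per-arm
results, then frozen across all analyses: **chemotherapy cycle cap = 6**
(from the allowed {4, 5, 6}), **subsequent-therapy proportion = 1.0**,
**carboplatin target AUC = 6** (from {5, 6}). At these settings the
model gives chemotherapy (US$ 20,790, 1.633) and combination
(US$ 46,966, 2.107) versus published (22,943, 1.63) and (49,182, 2.11);
incremental cost 26,177 vs 26,240; ICER 55,278 vs 54,430; scenario
combination cost 35,800 vs 38,429 and scenario ICER 31,698 vs 32,125.
The chemotherapy-arm cost is the weakest fit (−9.4%), suggesting the
original model carries some PD- or follow-up-phase cost we cannot see;
the proportion 1.0 is the boundary of its admissible range and lower
values only widen that gap. These values are recorded in every run's
`calibration_metadata`.

## Sensitivity analyses

**One-way (DSA).** Hazard ratios and utilities vary across their 95%
CIs, the discount rate across 0–8%, everything else ±50% of baseline;
Weibull parameters are fixed. Each bound re-runs the full two-arm model.
Entries are ranked by ICER spread; cost-effectiveness at an extreme is
judged by net monetary benefit, never by the raw ratio (a dominated
point has a meaningless negative ICER). The weight and LY01008-price
lower limits reproduce the two published threshold-crossing ICERs
(31,698 vs 32,124/32,115). One known divergence: at the OS hazard
ratio's lower CI limit (0.302) this reconstruction yields an ICER of
about 26,200 — below the threshold — whereas the source narrative
reports only weight and price crossing; no admissible structural setting
removes this, since the required PD-state cost would break the base
case. The corresponding test states the published claim and fails.

**Probabilistic (PSA).** Method-of-moments distributions from base value
and range (sd = range/3.92): Beta for probabilities and utilities, Gamma
for costs, Normal for anthropometrics. Hazard ratios are sampled
log-normally (CI-derived sd on the log scale) although the source labels
them "Normal", because a plain normal puts mass below zero; the
plain-normal option (truncated at machine epsilon) is a switch and the
choice is recorded in run metadata. One master seed spawns an
independent substream per draw. Draws violating joint validity
(essentially `u_pd > u_pfs`, about a quarter of draws given the
overlapping utility CIs) are redrawn, up to 100 attempts, and counted;
this conditioning biases the *accepted* utility means away from their
marginal means, which matters only under the QALY effectiveness switch.
At 1,000 draws the probability of cost-effectiveness at WTP US$ 33,438
is 20–24% depending on the seed (22.4% at n = 10,000), against 23.5%
published. The Monte-Carlo mean incremental effectiveness exceeds the
deterministic value by ≈0.06 — effectiveness is convex in the hazard
ratios, so log-normal sampling adds a Jensen gap; this is a property of
the design, not an estimator defect, and the mean incremental *cost*
does track the deterministic value when only linearly-entering
parameters are sampled.

## Synthetic data

The generator emulates the individual-patient time-to-event data behind
the survival inputs: inverse-CDF Weibull draws per patient for OS and
PFS, progression-free time taken as the minimum of the two independent
draws, administrative censoring at a configurable horizon, and the
arm effect applied through the hazard ratios. It reproduces the marginal
curves the model needs; it does not model recruitment, dropout, or the
PFS–OS dependence of real trials, so passing recovery tests demonstrate
estimator correctness, not trial realism. The Weibull fitter maximises
the right-censored log-likelihood on log-parameters (scipy L-BFGS-B,
gradient tolerance 1e-8), with asymptotic SEs from the observed
information via the delta method; it rejects inputs with fewer than two
events or non-positive times. An AE aggregation operator implements the
frequency-weighted lump construction (weighted-average disutility by
default, plain sum as an option — the published wording is ambiguous;
the published lump values are used directly by the model either way).

## Numerical and testing notes

* Mass conservation holds to 1e-12 per cycle; the death column is
  monotone; a brute-force matrix-product oracle reproduces the engine
  exactly on short horizons.
* The analytic Weibull medians from the printed parameters are 25.879
  (OS) and 9.223 (PFS) cycles; tests pin these to 0.01.
* The 1,000-draw PSA and the full DSA run in a few seconds on one CPU;
  problem sizes in the tests (cohort horizons, draw counts, synthetic
  cohort sizes) match the analysis defaults rather than scaled-down
  stand-ins, except where consistency checks deliberately contrast small
  and large samples.
* lifelines' Weibull fitter serves as an independent cross-check of the
  in-package MLE in the test suite (reparametrised; agreement to 0.1%).
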