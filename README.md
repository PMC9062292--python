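# bevcea

Cost-effectiveness analysis of first-line **LY01008** — a Chinese
bevacizumab biosimilar — combined with carboplatin/paclitaxel versus
chemotherapy alone for advanced or recurrent **nonsquamous non-small
cell lung cancer (NSCLC)**, from the perspective of the Chinese
healthcare system, implemented as a reusable, tested Python package.

It is written for health-economics and HTA practitioners who want to
inspect, reproduce or perturb every assumption of the published-style
analysis: the cohort model, the survival extrapolation, the costing
chain, and both sensitivity analyses are plain, documented Python.

## The model

A deterministic Markov cohort model tracks the proportion of patients in
four states over 3-week cycles for a 30-year horizon (521 cycles):
progression-free on first-line treatment (PFS-on), progression-free with
treatment discontinued after a grade III/IV adverse event (PFS-off),
progressive disease (PD), and death.

Survival of the reference (chemotherapy) arm follows Weibull curves
fitted to trial data, `S(t) = exp(−λt^γ)` with `t` in cycles:

| curve | scale λ | shape γ | median |
|---|---|---|---|
| overall survival | 0.004716 | 1.533854 | 25.9 cycles ≈ 17.9 months |
| progression-free survival | 0.003867 | 2.335407 | 9.2 cycles ≈ 6.4 months |

Per-cycle transition probabilities are conditional exit probabilities
`P(t) = 1 − S(t)/S(t−1)`; the death hazard (from the OS curve) applies
from every alive state, and PFS exits in excess of it move to PD. The
combination arm multiplies each scale by its hazard ratio (OS 0.654,
PFS 0.405), keeping the shape. A constant per-cycle probability moves
on-treatment patients to PFS-off.

Costs (2020 US$, also reported in CNY at 6.8974) cover
anthropometry-dependent drug acquisition (15 mg/kg LY01008; paclitaxel
175 mg/m²; carboplatin by the Calvert formula, AUC × (CrCl + 25)),
routine follow-up, PD management, one terminal palliative cycle per
death, and lump adverse-event costs. Costs and effectiveness are
discounted at 5%/year and compared as

```
ICER = Δcost / Δeffectiveness,   NMB = WTP × Δeffectiveness − Δcost
```

against a willingness-to-pay of US$ 33,438 (3× China's 2020 per-capita
GDP). One-way sensitivity analysis sweeps every parameter across its
range; probabilistic sensitivity analysis samples all non-fixed
parameters (Beta for probabilities/utilities, Gamma for costs, log-normal
for hazard ratios, Normal for anthropometrics) for 1,000 Monte-Carlo
draws. See `docs/methods.md` for assumptions, calibration and the
choice of effectiveness measure.

## Worked example

```python
from bevcea import default_inputs, evaluate

inputs, specs = default_inputs()      # packaged base-case configuration
out = evaluate(inputs)
print(round(out.reference.cost), round(out.comparator.cost),
      round(out.ce.delta_qalys, 3), round(out.ce.icer))
```

prints `20790 46966 0.474 55278`: the chemotherapy arm costs US$ 20,790
and the combination arm US$ 46,966 discounted over 30 years; the
combination adds 0.474 discounted effectiveness units at an ICER of
US$ 55,278 — above the US$ 33,438 threshold, so full-dose LY01008 is not
cost-effective. Halving the dose to the real-world 7.5 mg/kg
(`evaluate(inputs, {"ly01008_dose_multiplier": 0.5})`) drops the
combination arm to US$ 35,800 and the ICER to US$ 31,698, below the
threshold. The `examples/` directory walks through each capability
(base case, dosage scenario, tornado DSA, PSA/CEAC, survival-fitting
round trip); a thin CLI mirrors them (`bevcea base-case`,
`bevcea scenario`, `bevcea dsa`, `bevcea psa`, `bevcea simulate-ipd`,
`bevcea fit-weibull`).

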