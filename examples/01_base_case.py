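"""Base-case cost-effectiveness: LY01008 (15 mg/kg) + chemo vs chemo alone.

Runs both treatment arms through the 30-year Markov cohort model at the
packaged base-case inputs and prints per-arm discounted costs and
effectiveness, the incremental comparison, and the decision at the
willingness-to-pay threshold (3x China's 2020 per-capita GDP).
"""

from bevcea import default_inputs, evaluate

inputs, _ = default_inputs()
out = evaluate(inputs)

for arm in (out.reference, out.comparator):
    print(f"{arm.name:24s} cost US$ {arm.cost:10,.0f}   "
          f"effectiveness {arm.effectiveness(inputs.effectiveness_measure):.2f}")

ce = out.ce
print(f"\nincremental cost  US$ {ce.delta_cost:,.0f}")
print(f"incremental gain      {ce.delta_qalys:.3f}")
print(f"ICER              US$ {ce.icer:,.0f} per unit gained")
print(f"NMB at WTP {out.wtp:,.0f}: US$ {out.nmb_at_wtp:,.0f} "
      f"-> {'cost-effective' if out.cost_effective else 'NOT cost-effective'}")
# A negative net monetary benefit means the extra survival bought by the
# biosimilar costs more per unit than the threshold allows at full dosage.
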