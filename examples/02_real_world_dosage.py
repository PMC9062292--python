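"""Scenario analysis: real-world LY01008 dosage (7.5 mg/kg, half dose).

Efficacy inputs are unchanged — only the biosimilar acquisition cost
falls — so the incremental effectiveness is identical to the base case
while the ICER drops below the willingness-to-pay threshold.
"""

from bevcea import default_inputs, evaluate

inputs, _ = default_inputs()
base = evaluate(inputs)
scenario = evaluate(inputs, {"ly01008_dose_multiplier": 0.5})

print(f"combination arm cost, full dose: US$ {base.comparator.cost:,.0f}")
print(f"combination arm cost, half dose: US$ {scenario.comparator.cost:,.0f}")
print(f"incremental gain (both analyses): {scenario.ce.delta_qalys:.3f}")
print(f"scenario ICER: US$ {scenario.ce.icer:,.0f} vs WTP US$ {scenario.wtp:,.0f}")
print("cost-effective at half dose:", scenario.cost_effective)
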