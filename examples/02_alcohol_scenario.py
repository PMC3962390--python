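"""Simulate acute alcohol exposure, chronic adaptation and withdrawal.

Acute exposure raises GABA production and lowers Glu production (fold 1.3);
adaptation adds the compensatory degradation changes; withdrawal removes the
alcohol effect but keeps the compensation.  The mobile translates the
resulting intensity changes into rod tilt angles.
"""

import neuromobile as nm

model = nm.MatrixModel.default()
tree = nm.calibrate_lever_lengths(nm.default_tree(), model.baseline)
schedule = nm.build_alcohol_timeline(alpha=1.3, gamma=1.3)
result = nm.run_scenario(model, tree, schedule, k_res=500.0)

for phase in ("acute", "adaptation", "withdrawal"):
    profile = result.phase_end_profile(phase)
    theta = result.phase_end_angle("Glu_GABA", phase)
    side = nm.descending_side(tree, "Glu_GABA", theta)
    print(f"end of {phase:>10}: Glu = {profile['Glu']:7.2f}  "
          f"GABA = {profile['GABA']:7.2f}  "
          f"Glu-GABA rod angle = {theta:+.4f} rad (tilts toward {side[0]})")

print("\ndirection of change at withdrawal end (±5% band):")
for name, label in nm.direction_of_change_report(result, at="withdrawal").items():
    print(f"  {name:>4}  {label}")

print(
    "\nReading: alcohol tips the Glu-GABA rod toward GABA; adaptation brings"
    "\nit most of the way back; withdrawal overshoots, tipping it toward Glu"
    "\n(hyperexcitability), with DA and NA over-active and 5-HT/ACh unchanged."
)
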