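"""Treat withdrawal symptoms with diazepam and compare mobile imbalance.

Diazepam enhances GABA signalling (modelled as a 1.2-fold step on GABA
production from t = 275, mid-withdrawal).  The imbalance index — the sum of
absolute rod angles — quantifies how far the whole mobile is from level.
"""

import neuromobile as nm

model = nm.MatrixModel.default()
tree = nm.calibrate_lever_lengths(nm.default_tree(), model.baseline)

untreated = nm.run_scenario(model, tree, nm.build_alcohol_timeline())
treated = nm.run_scenario(
    model, tree, nm.apply_treatment(nm.build_alcohol_timeline(), preset="diazepam")
)

print("imbalance index (sum of |rod angles|, radians):")
print(f"{'time':>6} {'untreated':>10} {'diazepam':>10}")
for t in (275.0, 300.0, 325.0, 350.0):
    print(f"{t:6.0f} {untreated.mobile.imbalance_at(t):10.4f} "
          f"{treated.mobile.imbalance_at(t):10.4f}")

print(
    "\nReading: from the moment of application the treated mobile is strictly"
    "\ncloser to level at every time point — the GABA boost propagates through"
    "\nthe interaction matrix and also pulls Glu, DA and NA back toward baseline."
)
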