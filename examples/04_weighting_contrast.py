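"""Compare the categorized and raw-concentration weighting schemes.

Under the categorized scheme every transmitter gets a comparable functional
weight (100/150/200).  Under the raw scheme glutamate outweighs the
monoamines a thousandfold, so rods involving low-concentration transmitters
barely move and the mobile under-reports their imbalance.
"""

import neuromobile as nm

schedule = nm.build_alcohol_timeline()
for mode in ("categorized", "raw"):
    weights = nm.assign_weights(nm.WeightingScheme(mode=mode))
    model = nm.MatrixModel.from_baseline(weights)
    tree = nm.calibrate_lever_lengths(nm.default_tree(), weights)
    result = nm.run_scenario(model, tree, schedule, k_res=500.0)
    print(f"{mode:>11} weights: withdrawal-end imbalance index = "
          f"{result.mobile.imbalance_at(350.0):.4f} rad")

print(
    "\nReading: the categorized mobile shows a clearly larger overall"
    "\nimbalance. With raw weights the glutamate signal dominates every"
    "\ntorque budget, hiding the dopamine- and noradrenaline-side imbalances"
    "\nthat the categorized scheme makes visible."
)
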