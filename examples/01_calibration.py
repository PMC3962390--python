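"""Calibrate the interaction matrix and the mobile from the reference profile.

The six degradation rate constants are fixed by requiring that the reference
signal intensities (HT = DA = NA = ACh = 100, Glu = 200, GABA = 150) are a
steady state of the power-law system; the lever arm lengths are fixed by
requiring that every rod of the mobile is perfectly balanced at those same
intensities.
"""

import neuromobile as nm

model = nm.MatrixModel.default()

print("degradation rate constants (1/time):")
for name, k in model.rates_dict().items():
    print(f"  {name:>4}  {k:.7g}")

tree = nm.calibrate_lever_lengths(nm.default_tree(), model.baseline)
print("\nlever arm lengths (left, right) per rod:")
for rod, (ra, rb) in tree.arm_lengths().items():
    print(f"  {rod:>13}  {ra:.4f}  {rb:.4f}")

print(
    "\nThe rate constants span ~5 orders of magnitude (ACh turns over ~60,000x"
    "\nslower than NA), which is why the scenario dynamics mix fast and very"
    "\nslow responses. The arm lengths are the ratios of baseline subtree"
    "\nweights, e.g. the NA arm is 2 because (HT+DA) = 200 balances NA = 100."
)
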