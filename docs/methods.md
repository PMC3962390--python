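# Methods

## The interaction matrix

The six transmitter signals follow generalized-mass-action kinetics: each
production rate is a product of powers of all other signals (kinetic order
matrix `g`, diagonal zero, entries in {−0.3, −0.2, 0.2, 0.5}), each loss is
first order. The production rate coefficient is 1 by construction; all scale
sits in the degradation constants, which are calibrated from the steady-state
condition k_i = ∏_j X_j^{g_ij} / X_i at the reference profile
(100, 100, 100, 100, 200, 150 for HT, DA, NA, ACh, Glu, GABA). This
reproduces the published constants (e.g. k_DA = 7.901101,
k_ACh = 0.0004985258) to better than 1e-6 relative; the package stores the
published values only as a reference table and uses its own calibrated rates,
so the baseline is a machine-precision fixed point rather than one rounded to
seven digits.

The calibrated constants span almost five orders of magnitude
(k_NA ≈ 31.5 down to k_ACh ≈ 5e-4), making the system stiff. Integration
uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8, atol 1e-10, storing
output on a uniform grid (default spacing 0.1 time units). Perturbations are
piecewise-constant multiplicative modifiers on production (p_i) and
degradation (d_i); the solver restarts at every phase boundary from the
previous end state, with no ramping — regime changes are modelled as
instantaneous. Time is dimensionless model time; no mapping to physiological
hours is attempted.

`find_steady_state` solves p_i·flux_i = d_i·k_i·X_i by damped Newton
iteration on log-intensities seeded at baseline (for a pure power-law system
the log-space residual is nearly linear, so convergence is immediate);
non-convergence raises rather than returning an unconverged state, and the
result is verified against the tolerance max_i |dX_i/dt|/X_i < 1e-9.

## The mobile

The mobile is a binary tree: five massless rods, six transmitter weights,
default topology [[HT–DA]–NA] vs [ACh–[Glu–GABA]]. One arm per rod is a
reference of length 1; the other arm is calibrated from perfect balance at
baseline (w_left·r_left = w_right·r_right), giving the arm profile
NA = 2, GABA = 4/3, ACh = 3.5 and 2/3 for the top rod's right arm.

Rod rotation under imbalance is quasi-static. Weights A, B act at the arm
ends; at each arm end a resistant force proportional to that end's vertical
displacement (coefficient k_res) opposes rotation. Net torque about the
pivot is

τ(θ) = (A·r_a − B·r_b)·cos θ − k_res·(r_a² + r_b²)·sin θ·cos θ,

whose root in (−π/2, π/2) satisfies sin θ = (A·r_a − B·r_b)/(k_res·(r_a²+r_b²));
the cos θ factor cancels because both the weight torques and the resistant
torques act through the horizontal lever r·cos θ. The closed form is verified
in the test suite against brute-force root-finding of τ on 1000 randomized
rods to 1e-10. Sign convention: counterclockwise positive, so θ > 0 means the
left side hangs lower; `descending_side` converts the sign into a
"tilts toward X" statement so downstream code never depends on the
convention. When |A·r_a − B·r_b| ≥ k_res·(r_a²+r_b²) no equilibrium angle
exists inside ±90° and the package raises a "resistance too weak" error
instead of saturating.

Angles are computed per rod in local frames: a rod's tilt changes neither the
total weight it transmits to its parent nor the parent's balance reference.
The imbalance index is Σ|θ| over the five rods.

**Choice of k_res.** The default is k_res = 500 (weight units per length
unit). The coefficient exists to keep angles strictly inside ±90°; under the
default scenario sweep (fold changes up to 1.5) the largest torque imbalance
reaches ≈ 350 weight·length on the top rod, so any k_res below ≈ 250 has no
admissible angle there, while k_res = 500 keeps all scenario angles below
≈ 28°. Only angle magnitudes depend on this choice; every sign, ordering and
ratio reported by the scenario suite is monotone in the torque imbalance and
therefore unaffected.

## Scenarios

The alcohol timeline has four phases (default boundaries 0, 50, 100, 200,
end 350 — arbitrary model-time units; only the ordering is meaningful):

| phase      | production modifiers        | degradation modifiers       |
|------------|-----------------------------|-----------------------------|
| baseline   | —                           | —                           |
| acute      | GABA ×α, Glu ×1/α           | —                           |
| adaptation | GABA ×α, Glu ×1/α           | GABA ×γ, Glu ×1/γ           |
| withdrawal | —                           | GABA ×γ, Glu ×1/γ           |

α > 1 is the acute insult, γ > 1 the compensation; both default to 1.3. The
Glu folds default to the reciprocal of the GABA folds (one fewer free
parameter) but can be overridden independently. Treatments split the
withdrawal phase at a configurable start (default 275): diazepam = GABA
production ×1.2, clonidine = NA production ×0.8, plus a generic
single-target intervention (used for the hypothesised ACh target). The
direction-of-change report labels each transmitter elevated/reduced/unchanged
at a phase end, with "unchanged" meaning within ±5% of baseline by default.

**Matched versus mismatched compensation.** During adaptation the net effect
on GABA is the fold α/γ (production up, degradation up). With matched
compensation (γ = α) adaptation asymptotically restores baseline, and the
residual tilt at the end of the phase comes from GABA's slow kinetics
(timescale 1/k_GABA ≈ 67 against a 100-unit phase) — exactly the picture of
partial compensation, and the regime in which the package asserts its
adaptation, withdrawal and treatment properties. Strongly mismatched folds
leave that regime: γ > α over-compensates (net GABA fold < 1, the Glu–GABA
rod swings past level during adaptation), while γ ≪ α under-compensates
(GABA is still elevated entering withdrawal, decays too slowly to register
as "reduced" within the phase, and a GABA-enhancing drug can transiently
worsen the imbalance). These are genuine properties of piecewise-constant
modifiers on a stiff system, not numerical artifacts; the scenario machinery
permits such configurations but the directional claims are only guaranteed
for commensurate compensation. The acute-phase claims are independent of γ
and hold across the whole fold range tested (1.1–1.5).

A side observation the simulations reproduce: DA and NA trajectories overlap
(within 1% relative throughout the default scenario). Their equations share
the same kinetic-order signs for all regulators that change appreciably, and
both start at 100, so their relative responses coincide even though their
rate constants differ fourfold.

## Weighting schemes

The categorized scheme bins concentrations into low/medium/high and assigns
100/150/200; thresholds (100 and 5000 concentration units) are only exercised
when users supply their own concentration tables and default so that the
package's synthetic concentration table (Glu 10 000, GABA 1 000, monoamines
and ACh 10 — respecting the three-orders-of-magnitude Glu–DA spread reported
for the synaptic cleft, but not literature values) maps exactly onto the
reference profile. The raw scheme uses concentrations directly as weights.
Either scheme's output doubles as the matrix baseline, with degradation
constants recalibrated, so the mobile is level at baseline under both. Under
raw weights the withdrawal imbalance index is several-fold smaller than under
categorized weights (0.083 vs 0.545 rad at the default scenario's end):
glutamate dominates every torque budget, and larger calibrated arms also
enlarge the restoring lever (r_a²+r_b²), so imbalances of the
low-concentration transmitters become nearly invisible — the quantitative
form of the argument that relative, not absolute, magnitudes carry the
physiological signal.

## Problem sizes and determinism

A full default scenario integrates 6 stiff ODEs over 350 time units with
3 501 stored points in ~30 ms; the test suite's fold sweep runs the scenario
at nine (α, γ) combinations plus treated variants. There are no stochastic
elements anywhere in the model: identical configurations produce
byte-identical output files (TSV, UTF-8, LF, full `repr` precision).

## Known limitations

* The model is heuristic and mesoscopic: signal "intensities" are relative,
  time is unitless, and no receptor subtypes or brain regions are resolved.
* The mobile is quasi-static; no inertial dynamics.
* Treatments are step functions — no pharmacokinetics.
* Published figure angle magnitudes are not reproducible targets: they depend
  on the unpublished perturbation folds and resistance coefficient, so the
  scenario suite checks directions, orderings and ratios, not magnitudes.
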