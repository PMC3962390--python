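"""Functional-weight schemes for the mobile.

Synaptic concentrations of the six transmitters differ by orders of magnitude
(glutamate exceeds dopamine by a factor of thousands), yet low-concentration
transmitters are correspondingly more potent.  Two weighting schemes capture
the two readings:

* ``categorized`` (the default): concentrations are binned into low / medium /
  high classes and assigned the relative intensities 100 / 150 / 200.  With
  the default concentration table this reproduces the reference profile
  HT = DA = NA = ACh = 100, GABA = 150, Glu = 200.
* ``raw``: concentrations are used directly as functional weights.

Either scheme's output serves both as the mobile's weights and as the
baseline intensities of the interaction matrix (whose degradation constants
are then recalibrated to keep that baseline a steady state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .transmitters import TRANSMITTERS, TransmitterProfile

__all__ = ["WeightingScheme", "DEFAULT_RAW_CONCENTRATIONS", "assign_weights"]

#: Synthetic stand-in for literature synaptic concentrations (arbitrary
#: units): glutamate three orders of magnitude above the monoamines, GABA
#: one order below glutamate.  Used for the categorized defaults and for the
#: raw-versus-categorized contrast analysis; not literature values.
DEFAULT_RAW_CONCENTRATIONS: dict[str, float] = {
    "HT": 10.0,
    "DA": 10.0,
    "NA": 10.0,
    "ACh": 10.0,
    "Glu": 10_000.0,
    "GABA": 1_000.0,
}


@dataclass(frozen=True)
class WeightingScheme:
    """How transmitter concentrations become mobile weights.

    ``thresholds`` are the two concentration cut-points separating low /
    medium / high; ``category_values`` the intensities assigned to the three
    classes.  ``concentrations`` default to the synthetic table above.
    """

    mode: str = "categorized"
    thresholds: tuple[float, float] = (100.0, 5000.0)
    category_values: tuple[float, float, float] = (100.0, 150.0, 200.0)
    concentrations: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("categorized", "raw"):
            raise ValueError("mode must be 'categorized' or 'raw'")
        lo, hi = self.thresholds
        if not (0 < lo < hi):
            raise ValueError("thresholds must be positive and strictly increasing")
        a, b, c = self.category_values
        if not (0 < a < b < c):
            raise ValueError("category values must be strictly increasing and positive")

    def table(self) -> dict[str, float]:
        conc = dict(DEFAULT_RAW_CONCENTRATIONS if self.concentrations is None
                    else self.concentrations)
        missing = [t for t in TRANSMITTERS if t not in conc]
        if missing:
            raise KeyError(f"missing concentrations for {missing}")
        return {t: float(conc[t]) for t in TRANSMITTERS}


def assign_weights(scheme: WeightingScheme) -> TransmitterProfile:
    """Turn a weighting scheme into the profile of functional weights.

    Categorized mode maps each concentration through the thresholds to the
    three category values; raw mode returns the concentrations unchanged.
    """
    table = scheme.table()
    if scheme.mode == "raw":
        return TransmitterProfile.from_dict(table)
    lo, hi = scheme.thresholds
    low, mid, high = scheme.category_values

    def categorize(c: float) -> float:
        if c < lo:
            return low
        if c < hi:
            return mid
        return high

    return TransmitterProfile.from_dict({t: categorize(c) for t, c in table.items()})
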