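"""Transmitter identifiers and the signal-intensity state vector.

Six neurotransmitter systems are modelled: serotonin (HT, i.e. 5-HT),
dopamine (DA), noradrenaline (NA), acetylcholine (ACh), glutamate (Glu)
and gamma-aminobutyric acid (GABA).  Their ordering is fixed so that every
array, matrix row/column and output file column refers to the same
transmitter deterministically.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterator

import numpy as np

__all__ = ["TRANSMITTERS", "TRANSMITTER_INDEX", "TransmitterProfile"]

#: Canonical transmitter ordering used everywhere in the package.
TRANSMITTERS: tuple[str, ...] = ("HT", "DA", "NA", "ACh", "Glu", "GABA")

TRANSMITTER_INDEX: dict[str, int] = {name: i for i, name in enumerate(TRANSMITTERS)}

N_TRANSMITTERS = len(TRANSMITTERS)


def _check_transmitter(name: str) -> int:
    try:
        return TRANSMITTER_INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown transmitter {name!r}; expected one of {TRANSMITTERS}"
        ) from None


class TransmitterProfile(Mapping):
    """Relative signal intensities of the six transmitters at one time point.

    Intensities are dimensionless, on the scale where 100 corresponds to a
    "low" signal.  All intensities must be strictly positive: the production
    terms of the interaction matrix are products of powers with negative
    exponents, which are undefined at zero.

    The profile behaves as an immutable mapping ``name -> intensity`` and also
    exposes the underlying :class:`numpy.ndarray` (in canonical transmitter
    order) as :attr:`values`.
    """

    __slots__ = ("_values",)

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_TRANSMITTERS,):
            raise ValueError(
                f"expected {N_TRANSMITTERS} intensities in order {TRANSMITTERS}, "
                f"got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        for name, x in zip(TRANSMITTERS, arr):
            if x <= 0:
                raise ValueError(
                    f"intensity of {name} must be strictly positive, got {x}"
                )
        arr.flags.writeable = False
        self._values = arr

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "TransmitterProfile":
        missing = [t for t in TRANSMITTERS if t not in mapping]
        if missing:
            raise KeyError(f"missing intensities for {missing}")
        extra = [k for k in mapping if k not in TRANSMITTER_INDEX]
        if extra:
            raise KeyError(f"unknown transmitters {extra}")
        return cls([float(mapping[t]) for t in TRANSMITTERS])

    @property
    def values(self) -> np.ndarray:
        """Intensities as a read-only array in canonical order."""
        return self._values

    def to_dict(self) -> dict[str, float]:
        return {t: float(x) for t, x in zip(TRANSMITTERS, self._values)}

    def __getitem__(self, name: str) -> float:
        return float(self._values[_check_transmitter(name)])

    def __iter__(self) -> Iterator[str]:
        return iter(TRANSMITTERS)

    def __len__(self) -> int:
        return N_TRANSMITTERS

    def __repr__(self) -> str:
        inner = ", ".join(f"{t}={x:g}" for t, x in self.to_dict().items())
        return f"TransmitterProfile({inner})"

    def __eq__(self, other) -> bool:
        if isinstance(other, TransmitterProfile):
            return bool(np.array_equal(self._values, other._values))
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._values.tobytes())
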