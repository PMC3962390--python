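"""The neurochemical mobile: hierarchical torque balances between transmitters.

The mobile is a binary tree of massless rods.  Each leaf carries one
transmitter whose weight is its current signal intensity; each rod balances
its two subtrees on arms of lengths ``r_a`` (left) and ``r_b`` (right).  Arm
lengths are calibrated once, under perfect balance at the reference profile,
so that in health every rod is level.  Away from baseline each rod rotates.

A restoring ("resistant") force at each arm end, proportional to the vertical
displacement of that end and with coefficient ``k_res``, keeps rotation angles
strictly inside ±90°.  Static torque balance about the pivot reads

    (A*r_a - B*r_b) * cos(theta) = k_res * (r_a**2 + r_b**2) * sin(theta) * cos(theta)

(weights A, B act at the arm ends; each resistant force k_res * r * sin(theta)
acts at horizontal distance r * cos(theta)), so cos(theta) cancels and

    sin(theta) = (A*r_a - B*r_b) / (k_res * (r_a**2 + r_b**2)).

Sign convention: counterclockwise rotation is positive, which makes a
positive angle mean "left side down".  Angles are computed per rod in its own
local frame: a rod's internal tilt does not change the total weight it hands
to its parent, so ancestor rotations do not enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .matrix import Trajectory
from .transmitters import (
    N_TRANSMITTERS,
    TRANSMITTER_INDEX,
    TRANSMITTERS,
    TransmitterProfile,
)

__all__ = [
    "Leaf",
    "Rod",
    "MobileTree",
    "ROD_NAMES",
    "MobileSeries",
    "ResistanceTooWeakError",
    "default_tree",
    "subtree_weight",
    "calibrate_lever_lengths",
    "rotation_angle",
    "evaluate_mobile",
    "descending_side",
]

#: Output order of the five rods in angle tables.
ROD_NAMES: tuple[str, ...] = ("HT_DA", "HT_DA_NA", "Glu_GABA", "ACh_Glu_GABA", "TOP")


class ResistanceTooWeakError(ValueError):
    """The torque imbalance exceeds what the resistant force can hold."""


@dataclass(frozen=True)
class Leaf:
    transmitter: str

    def __post_init__(self) -> None:
        if self.transmitter not in TRANSMITTER_INDEX:
            raise ValueError(f"unknown transmitter {self.transmitter!r}")


@dataclass(frozen=True)
class Rod:
    """An internal mobile node: two subtrees on arms of given lengths.

    One arm per rod is flagged as the reference: its length is fixed by the
    user (default 1) and the other arm's length is solved for during
    calibration.
    """

    name: str
    left: Union["Rod", Leaf]
    right: Union["Rod", Leaf]
    left_arm: float = 1.0
    right_arm: float = 1.0
    reference: str = "left"  # which arm keeps its length during calibration

    def __post_init__(self) -> None:
        if self.left_arm <= 0 or self.right_arm <= 0:
            raise ValueError(f"rod {self.name!r}: arm lengths must be positive")
        if self.reference not in ("left", "right"):
            raise ValueError(f"rod {self.name!r}: reference must be 'left' or 'right'")


MobileNode = Union[Rod, Leaf]


@dataclass(frozen=True)
class MobileTree:
    """The full mobile: 5 rods over 6 transmitter leaves."""

    root: Rod

    def __post_init__(self) -> None:
        leaves = [l.transmitter for l in _leaves(self.root)]
        if sorted(leaves) != sorted(TRANSMITTERS):
            raise ValueError(
                f"mobile must contain each of {TRANSMITTERS} exactly once, "
                f"got {leaves}"
            )
        if len(list(_rods(self.root))) != N_TRANSMITTERS - 1:
            raise ValueError("mobile must contain exactly 5 rods")

    def rods(self) -> dict[str, Rod]:
        return {rod.name: rod for rod in _rods(self.root)}

    def arm_lengths(self) -> dict[str, tuple[float, float]]:
        """Per-rod ``(left_arm, right_arm)``."""
        return {rod.name: (rod.left_arm, rod.right_arm) for rod in _rods(self.root)}


def _leaves(node: MobileNode):
    if isinstance(node, Leaf):
        yield node
    else:
        yield from _leaves(node.left)
        yield from _leaves(node.right)


def _rods(node: MobileNode):
    if isinstance(node, Rod):
        yield from _rods(node.left)
        yield from _rods(node.right)
        yield node


def default_tree() -> MobileTree:
    """The default topology: [[HT-DA]-NA] against [ACh-[Glu-GABA]].

    Reference arms (length 1) match the published lever profile; calling
    :func:`calibrate_lever_lengths` with the default baseline then yields
    arm lengths NA = 2, GABA = 4/3, ACh = 3.5 and 2/3 for the right arm of
    the top rod.
    """
    ht_da = Rod("HT_DA", Leaf("HT"), Leaf("DA"), reference="left")
    ht_da_na = Rod("HT_DA_NA", ht_da, Leaf("NA"), reference="left")
    glu_gaba = Rod("Glu_GABA", Leaf("Glu"), Leaf("GABA"), reference="left")
    ach_glu_gaba = Rod("ACh_Glu_GABA", Leaf("ACh"), glu_gaba, reference="right")
    top = Rod("TOP", ht_da_na, ach_glu_gaba, reference="left")
    return MobileTree(top)


def subtree_weight(node: MobileNode, profile: TransmitterProfile) -> float:
    """Total weight hanging below ``node``: the sum of its leaf intensities.

    Rods and strings are massless, so a rod's weight is simply the sum over
    its leaves regardless of its internal tilt.
    """
    return float(sum(profile[l.transmitter] for l in _leaves(node)))


def _calibrate_node(node: MobileNode, profile: TransmitterProfile) -> MobileNode:
    if isinstance(node, Leaf):
        return node
    left = _calibrate_node(node.left, profile)
    right = _calibrate_node(node.right, profile)
    w_left = subtree_weight(left, profile)
    w_right = subtree_weight(right, profile)
    if w_left <= 0 or w_right <= 0:
        raise ValueError(f"rod {node.name!r}: zero weight on one side")
    if node.reference == "left":
        left_arm = node.left_arm
        right_arm = w_left * left_arm / w_right
    else:
        right_arm = node.right_arm
        left_arm = w_right * right_arm / w_left
    return replace(node, left=left, right=right, left_arm=left_arm, right_arm=right_arm)


def calibrate_lever_lengths(
    tree: MobileTree, baseline: TransmitterProfile
) -> MobileTree:
    """Solve all non-reference arm lengths under perfect balance at baseline.

    For each rod the balance condition ``w_left * r_left = w_right * r_right``
    fixes the non-reference arm given the reference arm's length.
    """
    return MobileTree(_calibrate_node(tree.root, baseline))


def rotation_angle(
    weight_a: float,
    weight_b: float,
    r_a: float,
    r_b: float,
    k_res: float,
) -> float:
    """Static rotation angle (radians) of a rod under the resistant force.

    ``weight_a`` hangs on the arm whose descent is counted positive
    (counterclockwise); in this package that is the left arm.  Raises
    :class:`ResistanceTooWeakError` instead of silently saturating when the
    torque imbalance cannot be held inside ±90°.
    """
    if weight_a < 0 or weight_b < 0:
        raise ValueError("weights must be non-negative")
    if r_a <= 0 or r_b <= 0:
        raise ValueError("arm lengths must be positive")
    if k_res <= 0:
        raise ValueError("resistance coefficient must be positive")
    s = (weight_a * r_a - weight_b * r_b) / (k_res * (r_a**2 + r_b**2))
    if abs(s) >= 1.0:
        raise ResistanceTooWeakError(
            f"torque imbalance {weight_a * r_a - weight_b * r_b:g} exceeds the "
            f"restoring capacity k_res*(r_a^2+r_b^2) = {k_res * (r_a**2 + r_b**2):g}; "
            "increase k_res"
        )
    return math.asin(s)


@dataclass(frozen=True)
class MobileSeries:
    """Per-rod rotation angles and the imbalance index along a trajectory.

    The imbalance index at a time point is the sum over the five rods of the
    absolute rotation angles — zero exactly when every rod is level.
    """

    times: np.ndarray
    angles: np.ndarray  # shape (n_times, 5), columns in ROD_NAMES order
    imbalance: np.ndarray  # shape (n_times,)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.angles, columns=list(ROD_NAMES))
        frame.insert(0, "time", self.times)
        frame["imbalance_index"] = self.imbalance
        return frame

    def angle_at(self, rod: str, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.angles[i, ROD_NAMES.index(rod)])

    def imbalance_at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.imbalance[i])


def _weight_matrices(tree: MobileTree) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Left/right leaf-aggregation matrices and arm-length vectors, ROD_NAMES order."""
    rods = tree.rods()
    missing = set(ROD_NAMES) - set(rods)
    if missing:
        raise ValueError(f"tree lacks expected rods {sorted(missing)}")
    L = np.zeros((len(ROD_NAMES), N_TRANSMITTERS))
    R = np.zeros((len(ROD_NAMES), N_TRANSMITTERS))
    ra = np.zeros(len(ROD_NAMES))
    rb = np.zeros(len(ROD_NAMES))
    for i, name in enumerate(ROD_NAMES):
        rod = rods[name]
        for leaf in _leaves(rod.left):
            L[i, TRANSMITTER_INDEX[leaf.transmitter]] = 1.0
        for leaf in _leaves(rod.right):
            R[i, TRANSMITTER_INDEX[leaf.transmitter]] = 1.0
        ra[i], rb[i] = rod.left_arm, rod.right_arm
    return L, R, ra, rb


def evaluate_mobile(
    tree: MobileTree,
    trajectory: Trajectory,
    k_res: float,
) -> MobileSeries:
    """Rotation angles of all rods and the imbalance index along a trajectory.

    Each rod's angle is computed independently in its local frame from the
    current subtree weights.
    """
    if k_res <= 0:
        raise ValueError("resistance coefficient must be positive")
    L, R, ra, rb = _weight_matrices(tree)
    X = trajectory.values  # (n, 6)
    diff = (X @ L.T) * ra - (X @ R.T) * rb  # (n, 5)
    denom = k_res * (ra**2 + rb**2)
    s = diff / denom
    if np.any(np.abs(s) >= 1.0):
        bad = np.argwhere(np.abs(s) >= 1.0)[0]
        t_bad, rod_bad = trajectory.times[bad[0]], ROD_NAMES[bad[1]]
        raise ResistanceTooWeakError(
            f"rod {rod_bad!r} at t={t_bad:g}: torque imbalance exceeds the "
            "restoring capacity; increase k_res"
        )
    angles = np.arcsin(s)
    return MobileSeries(
        times=trajectory.times,
        angles=angles,
        imbalance=np.sum(np.abs(angles), axis=1),
    )


def descending_side(tree: MobileTree, rod_name: str, theta: float) -> Optional[tuple[str, ...]]:
    """Transmitters on the side that hangs lower, or ``None`` if level.

    This converts the sign convention (positive = counterclockwise = left
    side down) into a convention-independent "tilts toward ..." statement.
    """
    rod = tree.rods()[rod_name]
    if theta == 0:
        return None
    side = rod.left if theta > 0 else rod.right
    return tuple(l.transmitter for l in _leaves(side))
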