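"""Alcohol-phase and treatment scenarios over the interaction matrix + mobile.

The alcohol timeline encodes the standard clinical picture as piecewise
multiplicative modifiers on production and degradation:

* acute exposure — inhibitory transmission up, excitatory down: GABA
  production x alpha, Glu production x 1/alpha (alpha > 1);
* adaptation (chronic use) — the brain compensates: on top of the acute
  modifiers, GABA degradation x gamma and Glu degradation x 1/gamma
  (gamma > 1);
* withdrawal — the direct alcohol effects disappear but the compensation
  persists: degradation modifiers only.

Pharmacological treatments are additional multiplicative steps applied during
withdrawal: diazepam enhances GABA signalling (GABA production fold > 1),
clonidine suppresses noradrenaline release (NA production fold < 1), and a
generic acetylcholine intervention is exposed with a configurable fold.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .matrix import MatrixModel, Trajectory, integrate
from .mobile import MobileSeries, MobileTree, evaluate_mobile
from .transmitters import N_TRANSMITTERS, TRANSMITTER_INDEX, TRANSMITTERS

__all__ = [
    "ModifierSet",
    "Phase",
    "ModifierSchedule",
    "ScenarioResult",
    "TREATMENT_PRESETS",
    "build_alcohol_timeline",
    "apply_treatment",
    "run_scenario",
    "direction_of_change_report",
]


@dataclass(frozen=True)
class ModifierSet:
    """Multiplicative production/degradation modifiers per transmitter.

    Both arrays follow the canonical transmitter order; 1 everywhere means no
    perturbation.
    """

    production: np.ndarray
    degradation: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.production, dtype=float)
        d = np.asarray(self.degradation, dtype=float)
        for label, arr in (("production", p), ("degradation", d)):
            if arr.shape != (N_TRANSMITTERS,):
                raise ValueError(f"{label} modifiers must have 6 entries")
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{label} modifiers must be strictly positive")
        p.flags.writeable = False
        d.flags.writeable = False
        object.__setattr__(self, "production", p)
        object.__setattr__(self, "degradation", d)

    @classmethod
    def unit(cls) -> "ModifierSet":
        return cls(np.ones(N_TRANSMITTERS), np.ones(N_TRANSMITTERS))

    @classmethod
    def from_dict(
        cls,
        production: Optional[Mapping[str, float]] = None,
        degradation: Optional[Mapping[str, float]] = None,
    ) -> "ModifierSet":
        p = np.ones(N_TRANSMITTERS)
        d = np.ones(N_TRANSMITTERS)
        for mapping, arr in ((production, p), (degradation, d)):
            if mapping:
                for name, fold in mapping.items():
                    arr[TRANSMITTER_INDEX[name]] = float(fold)
        return cls(p, d)

    def scaled(
        self, transmitter: str, channel: str, fold: float
    ) -> "ModifierSet":
        """New set with one channel of one transmitter multiplied by ``fold``."""
        if channel not in ("production", "degradation"):
            raise ValueError("channel must be 'production' or 'degradation'")
        if fold <= 0:
            raise ValueError("fold must be strictly positive")
        i = TRANSMITTER_INDEX[transmitter]
        p = self.production.copy()
        d = self.degradation.copy()
        (p if channel == "production" else d)[i] *= fold
        return ModifierSet(p, d)

    def is_unit(self) -> bool:
        return bool(np.all(self.production == 1) and np.all(self.degradation == 1))


@dataclass(frozen=True)
class Phase:
    name: str
    start: float
    end: float
    modifiers: ModifierSet

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"phase {self.name!r}: end must exceed start")


@dataclass(frozen=True)
class ModifierSchedule:
    """Contiguous, non-overlapping, time-ordered phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        if not phases:
            raise ValueError("schedule needs at least one phase")
        for prev, nxt in zip(phases, phases[1:]):
            if nxt.start != prev.end:
                raise ValueError(
                    f"phases must be contiguous: {prev.name!r} ends at {prev.end} "
                    f"but {nxt.name!r} starts at {nxt.start}"
                )
        object.__setattr__(self, "phases", phases)

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def end(self) -> float:
        return self.phases[-1].end

    def phase_named(self, name: str) -> Phase:
        matches = [ph for ph in self.phases if ph.name == name]
        if not matches:
            raise KeyError(f"no phase named {name!r}; have {[p.name for p in self.phases]}")
        return matches[-1]

    def boundaries(self) -> dict[str, float]:
        return {ph.name: ph.start for ph in self.phases}

    @classmethod
    def unit(cls, start: float = 0.0, end: float = 100.0) -> "ModifierSchedule":
        return cls((Phase("baseline", start, end, ModifierSet.unit()),))


#: Default phase boundaries (dimensionless model time; only ordering matters).
DEFAULT_PHASE_TIMES: dict[str, float] = {
    "baseline": 0.0,
    "acute": 50.0,
    "adaptation": 100.0,
    "withdrawal": 200.0,
    "end": 350.0,
}


def build_alcohol_timeline(
    alpha: float = 1.3,
    gamma: float = 1.3,
    *,
    phase_times: Optional[Mapping[str, float]] = None,
    glu_production_fold: Optional[float] = None,
    glu_degradation_fold: Optional[float] = None,
) -> ModifierSchedule:
    """The four-phase alcohol schedule: baseline, acute, adaptation, withdrawal.

    ``alpha`` (> 1) scales GABA production during exposure while Glu
    production is scaled by ``1/alpha`` (override with ``glu_production_fold``);
    ``gamma`` (> 1) is the compensatory fold on GABA degradation, with Glu
    degradation scaled by ``1/gamma`` (override with ``glu_degradation_fold``).
    """
    if alpha <= 1:
        raise ValueError(
            f"acute fold alpha must exceed 1 (alcohol raises GABA synthesis), got {alpha}"
        )
    if gamma <= 1:
        raise ValueError(
            f"compensation fold gamma must exceed 1, got {gamma}"
        )
    times = dict(DEFAULT_PHASE_TIMES)
    if phase_times:
        unknown = set(phase_times) - set(times)
        if unknown:
            raise ValueError(f"unknown phase-time keys {sorted(unknown)}")
        times.update({k: float(v) for k, v in phase_times.items()})
    order = ["baseline", "acute", "adaptation", "withdrawal", "end"]
    ts = [times[k] for k in order]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"phase times must be strictly increasing, got {times}")

    glu_p = 1.0 / alpha if glu_production_fold is None else float(glu_production_fold)
    glu_d = 1.0 / gamma if glu_degradation_fold is None else float(glu_degradation_fold)
    acute_production = {"GABA": alpha, "Glu": glu_p}
    compensation_degradation = {"GABA": gamma, "Glu": glu_d}

    return ModifierSchedule(
        (
            Phase("baseline", ts[0], ts[1], ModifierSet.unit()),
            Phase("acute", ts[1], ts[2], ModifierSet.from_dict(production=acute_production)),
            Phase(
                "adaptation",
                ts[2],
                ts[3],
                ModifierSet.from_dict(
                    production=acute_production,
                    degradation=compensation_degradation,
                ),
            ),
            Phase(
                "withdrawal",
                ts[3],
                ts[4],
                ModifierSet.from_dict(degradation=compensation_degradation),
            ),
        )
    )


#: Treatment presets: (target transmitter, channel, default fold).
TREATMENT_PRESETS: dict[str, tuple[str, str, float]] = {
    # benzodiazepine: enhanced GABA signalling
    "diazepam": ("GABA", "production", 1.2),
    # alpha-2 agonist: inhibits noradrenaline release
    "clonidine": ("NA", "production", 0.8),
    # hypothesised acetylcholine intervention; fold is configurable
    "ach": ("ACh", "production", 1.2),
}


def apply_treatment(
    schedule: ModifierSchedule,
    *,
    target: Optional[str] = None,
    channel: Optional[str] = None,
    fold: Optional[float] = None,
    start: float = 275.0,
    preset: Optional[str] = None,
) -> ModifierSchedule:
    """Split the withdrawal phase at ``start`` and apply a treatment step.

    Either name a ``preset`` (``diazepam``, ``clonidine``, ``ach``) or give
    ``target``/``channel``/``fold`` explicitly; a preset's fold may still be
    overridden.  The treatment multiplies the chosen channel on top of the
    withdrawal modifiers for the remainder of the schedule.  ``start`` must
    lie strictly inside the withdrawal phase.
    """
    if preset is not None:
        if preset not in TREATMENT_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(TREATMENT_PRESETS)}"
            )
        p_target, p_channel, p_fold = TREATMENT_PRESETS[preset]
        target = target or p_target
        channel = channel or p_channel
        fold = p_fold if fold is None else fold
    if target is None or channel is None or fold is None:
        raise ValueError("a treatment needs target, channel and fold (or a preset)")
    if fold <= 0:
        raise ValueError("treatment fold must be strictly positive")

    withdrawal = schedule.phase_named("withdrawal")
    if not (withdrawal.start < start < withdrawal.end):
        raise ValueError(
            f"treatment start {start} must lie inside the withdrawal phase "
            f"({withdrawal.start}, {withdrawal.end})"
        )
    if fold == 1.0:
        return schedule

    treated = Phase(
        "treatment",
        start,
        withdrawal.end,
        withdrawal.modifiers.scaled(target, channel, fold),
    )
    shortened = replace(withdrawal, end=start)
    phases = []
    for ph in schedule.phases:
        if ph is withdrawal:
            phases.extend([shortened, treated])
        else:
            phases.append(ph)
    return ModifierSchedule(tuple(phases))


@dataclass(frozen=True)
class ScenarioResult:
    """Joined output of one simulation: intensities, angles, imbalance."""

    trajectory: Trajectory
    mobile: MobileSeries
    schedule: ModifierSchedule
    model: MatrixModel
    tree: MobileTree
    k_res: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.trajectory.times, self.mobile.times):
            raise ValueError("trajectory and mobile series must share one time grid")

    def phase_end_profile(self, phase: str):
        return self.trajectory.profile_at(self.schedule.phase_named(phase).end)

    def phase_end_angle(self, rod: str, phase: str) -> float:
        return self.mobile.angle_at(rod, self.schedule.phase_named(phase).end)

    def phase_boundaries(self) -> dict[str, float]:
        return self.schedule.boundaries()


def run_scenario(
    model: MatrixModel,
    tree: MobileTree,
    schedule: ModifierSchedule,
    k_res: float = 500.0,
    *,
    grid_dt: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> ScenarioResult:
    """Integrate the matrix over the schedule and evaluate the mobile.

    Fully deterministic: identical inputs give identical results.
    """
    trajectory = integrate(
        model, schedule, grid_dt=grid_dt, rtol=rtol, atol=atol, method=method
    )
    mobile = evaluate_mobile(tree, trajectory, k_res)
    return ScenarioResult(trajectory, mobile, schedule, model, tree, k_res)


def direction_of_change_report(
    result: ScenarioResult,
    at: str = "withdrawal",
    epsilon: float = 0.05,
) -> dict[str, str]:
    """Label each transmitter elevated / reduced / unchanged at a phase end.

    A transmitter is "unchanged" when its phase-end intensity lies within
    ``epsilon`` (relative, default ±5%) of its baseline.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    profile = result.phase_end_profile(at)
    baseline = result.model.baseline
    report = {}
    for t in TRANSMITTERS:
        rel = profile[t] / baseline[t] - 1.0
        if rel > epsilon:
            report[t] = "elevated"
        elif rel < -epsilon:
            report[t] = "reduced"
        else:
            report[t] = "unchanged"
    return report
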