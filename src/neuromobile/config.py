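"""Run configuration: a validated, fully-defaulted view of one simulation.

An empty configuration file reproduces the published system exactly: the
default kinetic orders, the categorized baseline (100/100/100/100/200/150),
reference arms of length 1 and the default alcohol timeline.  Every key is
validated before any computation happens and unknown keys are rejected, so a
typo cannot silently change a run.  The effective configuration (defaults
merged in) can be serialized back out and re-loaded without change.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .matrix import (
    DEFAULT_BASELINE,
    DEFAULT_KINETIC_ORDERS,
    MatrixModel,
    kinetic_orders_from_dict,
)
from .mobile import MobileTree, calibrate_lever_lengths, default_tree
from .scenarios import (
    DEFAULT_PHASE_TIMES,
    ModifierSchedule,
    apply_treatment,
    build_alcohol_timeline,
)
from .transmitters import TRANSMITTERS, TransmitterProfile
from .weighting import (
    DEFAULT_RAW_CONCENTRATIONS,
    WeightingScheme,
    assign_weights,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "effective_config_dict"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ModelSection(_StrictModel):
    """Overrides of the interaction matrix (kinetic orders, baseline)."""

    orders: Optional[dict[str, dict[str, float]]] = None
    baseline: Optional[dict[str, float]] = None


class WeightingSection(_StrictModel):
    mode: Literal["categorized", "raw"] = "categorized"
    thresholds: tuple[float, float] = (100.0, 5000.0)
    category_values: tuple[float, float, float] = (100.0, 150.0, 200.0)
    concentrations: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_RAW_CONCENTRATIONS)
    )

    def scheme(self) -> WeightingScheme:
        return WeightingScheme(
            mode=self.mode,
            thresholds=self.thresholds,
            category_values=self.category_values,
            concentrations=self.concentrations,
        )


class MobileSection(_StrictModel):
    k_res: float = Field(default=500.0, gt=0, description="resistant-force coefficient")
    reference_length: float = Field(default=1.0, gt=0)


class TreatmentSection(_StrictModel):
    preset: Optional[Literal["diazepam", "clonidine", "ach"]] = None
    target: Optional[Literal["HT", "DA", "NA", "ACh", "Glu", "GABA"]] = None
    channel: Optional[Literal["production", "degradation"]] = None
    fold: Optional[float] = Field(default=None, gt=0)
    start: float = 275.0

    def is_specified(self) -> bool:
        """Whether this section actually selects a treatment.

        A section giving only ``start`` is a valid placeholder (e.g. the
        preset is chosen on the command line).
        """
        return self.preset is not None or self.target is not None

    @model_validator(mode="after")
    def _needs_preset_or_full_spec(self) -> "TreatmentSection":
        partial = (self.target, self.channel, self.fold)
        if self.preset is None and any(v is not None for v in partial):
            if None in partial:
                raise ValueError(
                    "treatment needs either a preset or all of target+channel+fold"
                )
        return self


class ScheduleSection(_StrictModel):
    alpha: float = Field(
        default=1.3, gt=1,
        description="acute fold on GABA production (Glu production gets 1/alpha)",
    )
    gamma: float = Field(
        default=1.3, gt=1,
        description="compensatory fold on GABA degradation (Glu degradation gets 1/gamma)",
    )
    glu_production_fold: Optional[float] = Field(default=None, gt=0)
    glu_degradation_fold: Optional[float] = Field(default=None, gt=0)
    phase_times: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PHASE_TIMES)
    )
    treatment: Optional[TreatmentSection] = None

    @model_validator(mode="after")
    def _check_phase_times(self) -> "ScheduleSection":
        unknown = set(self.phase_times) - set(DEFAULT_PHASE_TIMES)
        if unknown:
            raise ValueError(f"unknown phase_times keys {sorted(unknown)}")
        return self


class IntegrationSection(_StrictModel):
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-10, gt=0)
    grid_dt: float = Field(default=0.1, gt=0)
    method: Literal["LSODA", "BDF", "Radau"] = "LSODA"


class RunConfig(_StrictModel):
    """The complete, validated configuration of one simulation run."""

    model: ModelSection = Field(default_factory=ModelSection)
    weighting: WeightingSection = Field(default_factory=WeightingSection)
    mobile: MobileSection = Field(default_factory=MobileSection)
    schedule: ScheduleSection = Field(default_factory=ScheduleSection)
    integration: IntegrationSection = Field(default_factory=IntegrationSection)

    # --- builders -------------------------------------------------------

    def baseline_profile(self) -> TransmitterProfile:
        """Baseline intensities: explicit override > weighting scheme output."""
        if self.model.baseline is not None:
            return TransmitterProfile.from_dict(self.model.baseline)
        return assign_weights(self.weighting.scheme())

    def matrix_model(self) -> MatrixModel:
        orders = (
            DEFAULT_KINETIC_ORDERS
            if self.model.orders is None
            else kinetic_orders_from_dict(self.model.orders)
        )
        return MatrixModel.from_baseline(self.baseline_profile(), orders)

    def mobile_tree(self) -> MobileTree:
        tree = default_tree()
        if self.mobile.reference_length != 1.0:
            # scale every reference arm; calibration then scales the others
            from dataclasses import replace

            def rescale(node):
                from .mobile import Leaf, Rod

                if isinstance(node, Leaf):
                    return node
                return replace(
                    node,
                    left=rescale(node.left),
                    right=rescale(node.right),
                    left_arm=self.mobile.reference_length,
                    right_arm=self.mobile.reference_length,
                )

            tree = MobileTree(rescale(tree.root))
        return calibrate_lever_lengths(tree, self.baseline_profile())

    def modifier_schedule(self) -> ModifierSchedule:
        s = self.schedule
        timeline = build_alcohol_timeline(
            alpha=s.alpha,
            gamma=s.gamma,
            phase_times=s.phase_times,
            glu_production_fold=s.glu_production_fold,
            glu_degradation_fold=s.glu_degradation_fold,
        )
        if s.treatment is not None and s.treatment.is_specified():
            t = s.treatment
            timeline = apply_treatment(
                timeline,
                preset=t.preset,
                target=t.target,
                channel=t.channel,
                fold=t.fold,
                start=t.start,
            )
        return timeline


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load and validate a YAML configuration; ``None``/empty file = defaults.

    Raises :class:`ConfigError` naming the offending key on any violation.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries key paths
        raise ConfigError(f"invalid configuration {path}: {exc}") from exc


def effective_config_dict(config: RunConfig) -> dict:
    """The fully-defaulted configuration as plain data (YAML-serializable)."""
    return config.model_dump(mode="json")
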