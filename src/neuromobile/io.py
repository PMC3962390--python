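"""Deterministic tabular output of scenario results.

All tables are tab-separated UTF-8 with LF line endings and full float
precision (``repr`` round-trip), so two runs of the same configuration
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .config import RunConfig, effective_config_dict
from .mobile import ROD_NAMES
from .scenarios import ScenarioResult, direction_of_change_report
from .transmitters import TRANSMITTERS

__all__ = [
    "write_trajectory",
    "write_angles",
    "write_direction_report",
    "write_result",
]


def _write_table(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    rows = zip(*columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_trajectory(result: ScenarioResult, path: str | Path) -> Path:
    """Trajectory TSV: ``time`` then one column per transmitter."""
    path = Path(path)
    traj = result.trajectory
    _write_table(
        path,
        ["time", *TRANSMITTERS],
        [traj.times, *[traj.values[:, i] for i in range(len(TRANSMITTERS))]],
    )
    return path


def write_angles(result: ScenarioResult, path: str | Path) -> Path:
    """Angles TSV: ``time``, one column per rod, then ``imbalance_index``."""
    path = Path(path)
    mob = result.mobile
    _write_table(
        path,
        ["time", *ROD_NAMES, "imbalance_index"],
        [mob.times, *[mob.angles[:, i] for i in range(len(ROD_NAMES))], mob.imbalance],
    )
    return path


def write_direction_report(
    result: ScenarioResult,
    path: str | Path,
    *,
    at: str = "withdrawal",
    epsilon: float = 0.05,
) -> Path:
    path = Path(path)
    report = direction_of_change_report(result, at=at, epsilon=epsilon)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# direction of change at end of phase '{at}' "
                 f"(unchanged band: +/-{epsilon:g} relative)\n")
        fh.write("transmitter\tdirection\n")
        for t in TRANSMITTERS:
            fh.write(f"{t}\t{report[t]}\n")
    return path


def write_result(
    result: ScenarioResult,
    directory: str | Path,
    *,
    config: Optional[RunConfig] = None,
    report_phase: str = "withdrawal",
    epsilon: float = 0.05,
) -> dict[str, Path]:
    """Write the full file set for one run into ``directory``.

    Produces ``trajectory.tsv``, ``angles.tsv``, ``directions.tsv`` and, when
    a configuration is supplied, ``effective_config.yaml`` with all defaults
    merged in.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "trajectory": write_trajectory(result, directory / "trajectory.tsv"),
        "angles": write_angles(result, directory / "angles.tsv"),
    }
    phase_names = [ph.name for ph in result.schedule.phases]
    if report_phase in phase_names:
        files["directions"] = write_direction_report(
            result, directory / "directions.tsv", at=report_phase, epsilon=epsilon
        )
    if config is not None:
        cfg_path = directory / "effective_config.yaml"
        with open(cfg_path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(effective_config_dict(config), fh, sort_keys=True)
        files["config"] = cfg_path
    return files
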