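"""Validated pipeline configuration.

One document gathers every tunable constant of the pipeline — filter
corners, artifact thresholds, epoch lengths, the log clipping floor, the
siesta slot, the Bayesian t-grid and seeds — with explicit defaults.
Unknown keys are rejected before any computation runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .epochs import LOG_FLOOR


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a configuration."""


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class FilterSettings:
    bandpass_lo: float = 0.1
    bandpass_hi: float = 55.0
    notches: Tuple[float, ...] = ()


@dataclass(frozen=True)
class ArtifactSettings:
    slew_max_uv: float = 50.0
    ptp_max_uv: float = 500.0
    flat_run_s: float = 0.5
    saturation_run: int = 10


@dataclass(frozen=True)
class SimSettings:
    """Session-grid and generator settings (see simstudy for semantics)."""

    max_duration: float = 40.0
    epoch_len_fine: float = 15.0
    epoch_len_stage: float = 30.0
    theta_n1: float = 0.5
    theta_n2: float = 0.9
    microsleep_base_rate: float = 1.0


@dataclass(frozen=True)
class StatsSettings:
    endpoints: Tuple[str, ...] = ("sleepiness_slope", "microsleep_rate")
    model: str = "lmm"  # 'lmm' | 'bayes'
    t: float = 3.0
    t_grid: Tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    chains: int = 2
    iters: int = 1000

    def __post_init__(self) -> None:
        if self.model not in ("lmm", "bayes"):
            raise ConfigError(f"model must be 'lmm' or 'bayes', got {self.model!r}")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "mwtbio_run"
    design: Optional[dict] = None  # None -> trial-mirroring default design
    include_qeeg: bool = True
    write_eeg: bool = False
    qeeg_fs: float = 256.0
    clip_floor: float = LOG_FLOOR
    siesta_time: str = "14:00"
    fit_window: str = "to_sol"
    filter: FilterSettings = field(default_factory=FilterSettings)
    artifact: ArtifactSettings = field(default_factory=ArtifactSettings)
    sim: SimSettings = field(default_factory=SimSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        nested = {
            "filter": FilterSettings,
            "artifact": ArtifactSettings,
            "sim": SimSettings,
            "stats": StatsSettings,
        }
        for key, sub in nested.items():
            if key in data and isinstance(data[key], dict):
                sub_data = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data[key].items()
                }
                data[key] = _from_mapping(sub, sub_data, key)
        return _from_mapping(cls, data, "pipeline config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration (for the run log)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def design_from_dict(data: dict):
    """Build a StudyDesign from a plain mapping (e.g. parsed YAML)."""
    from .simstudy import CohortSpec, SimSessionConfig, StudyDesign

    data = dict(data)
    cohort_rows = data.pop("cohorts", None)
    if not cohort_rows:
        raise ConfigError("design: 'cohorts' list is required")
    cohorts = tuple(
        _from_mapping(CohortSpec, dict(row), f"design cohort {i}")
        for i, row in enumerate(cohort_rows)
    )
    if "session_cfg" in data and isinstance(data["session_cfg"], dict):
        data["session_cfg"] = _from_mapping(
            SimSessionConfig, data["session_cfg"], "design session_cfg"
        )
    for key in ("days", "session_times"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return _from_mapping(StudyDesign, {"cohorts": cohorts, **data}, "design")
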