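"""Run configuration: every scalar threshold of the measurement methods
in one versioned, hashable object.

The defaults are the study conditions: 500-step / 12-h / 95% valid-day
rules, 90-min non-wear rule, 75 and 100 cpm cut-points, 10-h day rule,
10/30-min bout thresholds, 80% participation rule for the daytime
analysis, and cohort sizes of 38 (development) and 62 (comparison).
Configs round-trip through YAML; the hash of the canonical YAML is
recorded in every output manifest so results are traceable to their
exact settings.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    # reproducibility
    seed: int = 1
    # simulated cohorts
    n_development: int = 38
    n_comparison: int = 62
    n_days: int = 7
    # pre-processing thresholds
    min_steps: int = 500
    min_waking_hours: float = 12.0
    max_single_posture_fraction: float = 0.95
    nonwear_min_const_minutes: float = 90.0
    nonwear_movement_qualifies: bool = True
    lag_max_s: float = 60.0
    # cut-points (counts per minute, vertical axis)
    cutpoint_inactive_cpm: float = 75.0
    cutpoint_sedentary_cpm: float = 100.0
    cutpoint_axis: str = "axis1"
    # summarization
    min_wear_hours_per_day: float = 10.0
    bout_thresholds_min: tuple[float, float] = (10.0, 30.0)
    interval_min_participation: float = 0.80
    interval_bin_minutes: int = 30
    # training
    feature_set: int = 1
    feature_subset: tuple[str, ...] | None = None  # None = full registry
    n_keep: int = 100
    patience: int = 10
    search_budget: int = 30
    max_training_minutes_per_participant: int | None = None
    posture_rows_per_participant: int = 150
    # artifacts
    model_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_development < 2 or self.n_comparison < 3:
            raise ConfigurationError("cohorts too small")
        if self.cutpoint_inactive_cpm <= 0 or self.cutpoint_sedentary_cpm <= 0:
            raise ConfigurationError("cut-points must be positive")
        lo, hi = self.bout_thresholds_min
        if lo > hi:
            raise ConfigurationError("bout thresholds must be ordered")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["bout_thresholds_min"] = list(d["bout_thresholds_min"])
        if d["feature_subset"] is not None:
            d["feature_subset"] = list(d["feature_subset"])
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "bout_thresholds_min" in data:
        data["bout_thresholds_min"] = tuple(data["bout_thresholds_min"])
    if data.get("feature_subset") is not None:
        data["feature_subset"] = tuple(data["feature_subset"])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config.to_yaml())
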