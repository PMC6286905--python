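"""Run configuration: one file describing a full synth -> fit -> plan -> workload run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GeneratorConfig
from .decision import RiskPolicy
from .workload import CountingRules

__all__ = ["GridSpec", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class GridSpec:
    """D1/D2 ranges (Gy) and step for the exceedance-probability contour export."""

    d1_min: float = 0.1
    d1_max: float = 12.0
    d2_min: float = 0.1
    d2_max: float = 12.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.d1_max < self.d1_min or self.d2_max < self.d2_min:
            raise ValueError("grid ranges must be non-empty")


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    policy: RiskPolicy = field(default_factory=RiskPolicy)
    counting: CountingRules = field(default_factory=CountingRules)
    grid: GridSpec = field(default_factory=GridSpec)
    output_dir: str = "prrtplan-run"
    verbosity: str = "INFO"


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            coerced[f.name] = value
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration; unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run configuration must be a mapping at the top level")
    sections = {
        "generator": GeneratorConfig,
        "policy": RiskPolicy,
        "counting": CountingRules,
        "grid": GridSpec,
    }
    unknown = set(data) - set(sections) - {"output_dir", "verbosity"}
    if unknown:
        raise ValueError(f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, data[name], name) for name, cls in sections.items() if name in data
    }
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    if "verbosity" in data:
        kwargs["verbosity"] = str(data["verbosity"])
    return RunConfig(**kwargs)


def config_hash(obj) -> str:
    """Short stable hash of any dataclass tree, for run logging."""
    payload = json.dumps(dataclasses.asdict(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
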