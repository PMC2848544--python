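"""Run configuration: YAML round-trip, validation, defaults.

A RunConfig bundles everything a simulation run needs — scenario, parameter
overrides, lattice and gradient geometry, sweep/screen settings,
intervention, heterogeneity, seed and tolerances — and is fully serializable
so a run can be reproduced bit-for-bit from its config file and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .experiments import HeterogeneitySpec, Intervention
from .params import ParameterSet, ScenarioConfig
from .tissue import GradientSpec, LatticeSpec

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]


@dataclass
class RunConfig:
    scenario: str = "III"
    parameters: dict = field(default_factory=dict)   # overrides of ParameterSet fields
    lattice: dict = field(default_factory=lambda: {"n_axial": 50, "n_lateral": 1})
    gradient: dict = field(default_factory=dict)     # G_min/G_max/t_half/h overrides
    sweep: dict = field(default_factory=lambda: {
        "G_step": 10.0, "G_max_sweep": 2500.0, "settle": 250.0, "cap": 2000.0})
    screen: dict = field(default_factory=lambda: {"n": 500, "G_step": 100.0})
    intervention: dict = field(default_factory=lambda: {"kind": "none"})
    heterogeneity: dict = field(default_factory=lambda: {"level": 0.0, "seed": 0})
    settle: float = 500.0
    t_end: float = 400.0
    seed: int = 42
    rtol: float = 1e-6
    atol: float = 1e-9
    outdir: str = "results"

    def __post_init__(self) -> None:
        # constructing the domain objects validates every block
        self.scenario_config()
        self.parameter_set()
        self.lattice_spec()
        self.intervention_spec()
        self.heterogeneity_spec()
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")

    def scenario_config(self) -> ScenarioConfig:
        return ScenarioConfig.from_name(self.scenario)

    def parameter_set(self) -> ParameterSet:
        ps = ParameterSet(**self.parameters)
        return ps.with_scenario(self.scenario_config())

    def lattice_spec(self) -> LatticeSpec:
        return LatticeSpec(**self.lattice)

    def gradient_spec(self) -> GradientSpec:
        ps = self.parameter_set()
        g = {"G_min": ps.G_min, "G_max": ps.G_max, "t_half": ps.t_half,
             **self.gradient}
        return GradientSpec(**g)

    def intervention_spec(self) -> Intervention:
        return Intervention(**self.intervention)

    def heterogeneity_spec(self) -> HeterogeneitySpec:
        return HeterogeneitySpec(**self.heterogeneity)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path_or_none) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys are rejected."""
    data = {}
    if path_or_none is not None:
        text = Path(path_or_none).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in data:
            continue
        v = data[f.name]
        default = getattr(RunConfig(), f.name)
        if isinstance(default, dict) and isinstance(v, dict):
            merged[f.name] = {**default, **v}
        else:
            merged[f.name] = v
    return RunConfig(**merged)


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def result_metadata(cfg: RunConfig) -> dict:
    """Provenance block embedded in every result file."""
    return {"config_hash": config_hash(cfg), "seed": cfg.seed,
            "version": __version__}
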