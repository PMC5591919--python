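"""Structured run configuration (YAML) with provenance hashing.

A run configuration collects the seed and every module's parameters in one
nested document so that a whole analysis is reproducible from a single file.
Outputs written by the CLI carry ``config_hash`` so results produced under
different configurations are never silently compared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fieldmodel import CurrentWaveform, SolenoidSpec, default_bioreactor
from .kinematics import KinematicsParams
from .synthgen import BeatWaveformParams, ConditionParams, StudyDesign

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    n_repro_seeds: int = 20
    design: StudyDesign = field(default_factory=StudyDesign)
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    solenoids: tuple[SolenoidSpec, SolenoidSpec] = field(
        default_factory=lambda: default_bioreactor()[0])
    waveform: CurrentWaveform = field(default_factory=CurrentWaveform)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "alpha": self.alpha,
            "n_repro_seeds": self.n_repro_seeds,
            "design": asdict(self.design),
            "kinematics": asdict(self.kinematics),
            "solenoids": [asdict(s) for s in self.solenoids],
            "waveform": asdict(self.waveform),
        }
        d["design"]["arms"] = [asdict(a) for a in self.design.arms]
        d["design"]["base"] = asdict(self.design.base)
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _design_from_dict(d: dict) -> StudyDesign:
    d = dict(d)
    if "base" in d:
        d["base"] = BeatWaveformParams(**d["base"])
    if "arms" in d:
        d["arms"] = tuple(ConditionParams(**a) for a in d["arms"])
    for key in ("minutes", "frame_shape"):
        if key in d:
            d[key] = tuple(d[key])
    return StudyDesign(**d)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML run configuration; missing sections fall back to defaults.

    Unknown top-level keys raise, so a typo in a config file fails loudly
    rather than silently running with defaults.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    known = {"seed", "alpha", "n_repro_seeds", "design", "kinematics",
             "solenoids", "waveform"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "alpha", "n_repro_seeds"):
        if key in data:
            kwargs[key] = data[key]
    if "design" in data:
        kwargs["design"] = _design_from_dict(data["design"])
    if "kinematics" in data:
        kwargs["kinematics"] = KinematicsParams(**data["kinematics"])
    if "solenoids" in data:
        specs = tuple(SolenoidSpec(**s) for s in data["solenoids"])
        if len(specs) != 2:
            raise ValueError("solenoids must list exactly two coils")
        kwargs["solenoids"] = specs
    if "waveform" in data:
        kwargs["waveform"] = CurrentWaveform(**data["waveform"])
    return RunConfig(**kwargs)
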