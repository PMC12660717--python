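"""Structured run configuration: defaults, YAML round-trip, validation.

One YAML file configures every stage of the pipeline.  The defaults
reproduce the reference study settings: unit production/degradation
rates, Hill coefficient 2, the sequential N->H->O protocol over
[-15, 30] at step 0.05, a 20-point (K_H, K_TF) sweep over [0.01, 2],
significance level 0.05, and the 27-sample synthetic design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import CircuitSpec, IFFLParams
from .signals import Protocol, default_nho_protocol
from .synth import PlantedClass, SyntheticDesign, default_planted_classes

__all__ = ["RunConfig", "SweepConfig", "PatternsConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class SweepConfig:
    k_min: float = 0.01
    k_max: float = 2.0
    grid_points: int = 20
    rel_tol: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.k_min < self.k_max:
            raise ValueError("sweep range requires 0 < k_min < k_max")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")


@dataclass(frozen=True)
class PatternsConfig:
    alpha: float = 0.05
    kd_condition: str = "H"
    strict_kd_significance: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.kd_condition not in ("N", "H", "O"):
            raise ValueError("kd_condition must be one of N, H, O")


@dataclass(frozen=True)
class RunConfig:
    circuit: CircuitSpec = field(default_factory=CircuitSpec)
    protocol: Protocol = field(default_factory=default_nho_protocol)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    patterns: PatternsConfig = field(default_factory=PatternsConfig)
    synth: SyntheticDesign = field(default_factory=SyntheticDesign)
    seed: int = 0
    out_dir: str = "hiffl-out"

    def to_dict(self) -> dict:
        return {
            "circuit": {
                "iffl_type": self.circuit.iffl_type,
                "mode": self.circuit.mode,
                "params": dataclasses.asdict(self.circuit.params),
            },
            "protocol": self.protocol.to_dict(),
            "sweep": dataclasses.asdict(self.sweep),
            "patterns": dataclasses.asdict(self.patterns),
            "synth": {
                **{k: v for k, v in dataclasses.asdict(self.synth).items()
                   if k != "planted_classes"},
                "planted_classes": [dataclasses.asdict(c)
                                    for c in self.synth.planted_classes],
            },
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {"circuit", "protocol", "sweep", "patterns", "synth", "seed", "out_dir"}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {', '.join(bad)}")
        kwargs: dict = {}
        if "circuit" in d:
            c = dict(d["circuit"])
            params = IFFLParams(**c.pop("params", {}))
            kwargs["circuit"] = CircuitSpec(params=params, **c)
        if "protocol" in d:
            kwargs["protocol"] = Protocol.from_dict(d["protocol"])
        if "sweep" in d:
            kwargs["sweep"] = SweepConfig(**d["sweep"])
        if "patterns" in d:
            kwargs["patterns"] = PatternsConfig(**d["patterns"])
        if "synth" in d:
            s = dict(d["synth"])
            classes = s.pop("planted_classes", None)
            if classes is not None:
                s["planted_classes"] = tuple(
                    PlantedClass(
                        pattern=c["pattern"], effects=tuple(c["effects"]),
                        fraction=c["fraction"],
                        tf_dependent=c.get("tf_dependent", False),
                    )
                    for c in classes
                )
            kwargs["synth"] = SyntheticDesign(**s)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        if "out_dir" in d:
            kwargs["out_dir"] = str(d["out_dir"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, or the documented defaults when path is None."""
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(path)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the fully-resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
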