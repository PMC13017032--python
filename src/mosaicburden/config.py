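"""Run configuration: YAML-backed, strictly validated, round-trippable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calling import CallerConfig
from .cohort import SimConfig
from .sc import ScCallerConfig
from .sc_sim import CloneSpec, ScSimConfig, default_clones

__all__ = ["RunConfig", "load_config"]


def _from_dict(cls, data: dict, path: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {path!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    ``seed`` fans out to stage-specific child seeds; ``genes`` seeds the
    synthetic panel; stage sections mirror the stage config dataclasses.
    """

    seed: int = 0
    genes: list[str] = field(
        default_factory=lambda: ["VAPB", "MAPT", "FUS", "NEFH", "CCNF", "NEK1", "TBK1"]
    )
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    sc_sim: ScSimConfig = field(default_factory=ScSimConfig)
    sc_caller: ScCallerConfig = field(default_factory=ScCallerConfig)
    sc_clones: list[CloneSpec] = field(default_factory=default_clones)
    af_bins: list[float] = field(default_factory=lambda: [0.015, 0.05, 0.15, 0.35])
    n_signatures: int = 5
    n_boot: int = 200
    n_perm: int = 999
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, val in data.items():
            if key == "sim":
                kwargs[key] = _from_dict(SimConfig, val, "sim")
            elif key == "caller":
                kwargs[key] = _from_dict(CallerConfig, val, "caller")
            elif key == "sc_sim":
                kwargs[key] = _from_dict(ScSimConfig, val, "sc_sim")
            elif key == "sc_caller":
                kwargs[key] = _from_dict(ScCallerConfig, val, "sc_caller")
            elif key == "sc_clones":
                kwargs[key] = [
                    _from_dict(CloneSpec, v, f"sc_clones[{i}]")
                    for i, v in enumerate(val or [])
                ]
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        # the global seed governs both simulators unless set explicitly
        if "sim" not in data or "seed" not in (data.get("sim") or {}):
            cfg.sim.seed = cfg.seed
        if "sc_sim" not in data or "seed" not in (data.get("sc_sim") or {}):
            cfg.sc_sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(data)
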