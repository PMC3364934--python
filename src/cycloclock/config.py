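"""Run configuration: parsing, validation, digests.

Configs are TOML (or YAML) files with blocks mapping one-to-one onto the
parameter dataclasses: ``[clock]``, ``[cdk]``, ``[coupling]``, ``[ld]``,
``[gf]``, ``[simulation]``. Unknown keys are rejected with the offending
path; every run can emit a frozen copy plus a stable digest (invariant
under key reordering).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .cdk import CdkParams, GFSquareWave
from .clock import ClockParams, LDSchedule
from .core import SimulationConfig
from .coupling import CouplingParams

__all__ = ["RunConfig", "load_config", "config_digest"]

_BLOCKS = {
    "clock": ClockParams,
    "cdk": CdkParams,
    "coupling": CouplingParams,
    "ld": LDSchedule,
    "gf": GFSquareWave,
    "simulation": SimulationConfig,
}


@dataclass
class RunConfig:
    """Validated bundle of all parameter blocks for one run."""

    clock: ClockParams = field(default_factory=ClockParams)
    cdk: CdkParams = field(default_factory=CdkParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    ld: LDSchedule | None = field(default_factory=LDSchedule)
    gf: GFSquareWave | None = None
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(t_end=960.0, t_transient=240.0))
    output_dir: str = "."
    seed: int = 0

    def digest(self) -> str:
        return config_digest(self.to_dict())

    def to_dict(self) -> dict:
        out = {}
        for name in _BLOCKS:
            v = getattr(self, name)
            out[name] = None if v is None else dataclasses.asdict(v)
        out["output_dir"] = self.output_dir
        out["seed"] = self.seed
        return out

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _build_block(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown key '{path}.{key}'")
    if cls is CouplingParams and "modes" in data:
        data = dict(data, modes=tuple(data["modes"]))
    return cls(**data)


def load_config(path) -> RunConfig:
    """Parse and validate a TOML or YAML run configuration."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        data = tomllib.loads(text.decode())
    if not isinstance(data, dict):
        raise ValueError("config root must be a table/mapping")

    kwargs = {}
    for key, val in data.items():
        if key in _BLOCKS:
            if not isinstance(val, dict):
                raise ValueError(f"block '{key}' must be a table")
            kwargs[key] = _build_block(_BLOCKS[key], val, key)
        elif key == "output_dir":
            kwargs["output_dir"] = str(val)
        elif key == "seed":
            kwargs["seed"] = int(val)
        else:
            raise ValueError(f"unknown key '{key}'")
    return RunConfig(**kwargs)


def config_digest(obj) -> str:
    """Stable content hash: canonical JSON with sorted keys."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
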