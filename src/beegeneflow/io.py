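"""Config parsing, output writers and run manifests.

Configs are YAML or JSON mappings mirroring :class:`ScenarioParams` or
:class:`SimConfig`; unknown keys are rejected by name so typos fail loudly.
Trajectory tables are tab-separated with '.' decimals and a header row, so
outputs are byte-for-byte diffable across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .scenario import MatingSystem, ParameterError, ScenarioParams
from .simulator import SimConfig

__all__ = [
    "load_config",
    "scenario_from_dict",
    "sim_config_from_dict",
    "parse_scenario",
    "parse_sim_config",
    "write_json",
    "RunManifest",
]

_SCENARIO_KEYS = {
    "mating_system", "p", "q", "s1", "s2",
    "p_series", "q_series", "s1_series", "s2_series",
}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON mapping from disk."""
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a mapping")
    return data


def _check_keys(data: dict, allowed: set[str], what: str) -> None:
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ParameterError(
            f"unknown {what} key(s): {', '.join(unknown)}"
        )


def _int_keys(series: dict | None) -> dict[int, float] | None:
    if series is None:
        return None
    return {int(k): float(v) for k, v in series.items()}


def scenario_from_dict(data: dict) -> ScenarioParams:
    """Validated deterministic-model parameters from a plain mapping."""
    _check_keys(data, _SCENARIO_KEYS, "scenario")
    for key in ("mating_system", "p", "q", "s1"):
        if key not in data:
            raise ParameterError(f"scenario config is missing key: {key}")
    return ScenarioParams(
        mating_system=MatingSystem(data["mating_system"]),
        p=float(data["p"]),
        q=float(data["q"]),
        s1=float(data["s1"]),
        s2=float(data["s2"]) if data.get("s2") is not None else None,
        p_series=_int_keys(data.get("p_series")),
        q_series=_int_keys(data.get("q_series")),
        s1_series=_int_keys(data.get("s1_series")),
        s2_series=_int_keys(data.get("s2_series")),
    )


def sim_config_from_dict(data: dict) -> SimConfig:
    """Validated simulator configuration from a plain mapping."""
    _check_keys(data, _SIM_KEYS, "simulation")
    for key in ("n_b", "n_p"):
        if key not in data:
            raise ParameterError(f"simulation config is missing key: {key}")
    return SimConfig(**data)


def parse_scenario(path: str | Path) -> ScenarioParams:
    return scenario_from_dict(load_config(path))


def parse_sim_config(path: str | Path) -> SimConfig:
    return sim_config_from_dict(load_config(path))


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Inventory of a run: version, seed, config echo, output checksums.

    Re-running with the recorded seed and config reproduces files with
    identical checksums.
    """

    seed: int | None
    config: dict
    outputs: dict[str, str]
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        seed: int | None,
        config: dict,
        output_paths: list[Path],
    ) -> "RunManifest":
        return cls(
            seed=seed,
            config=config,
            outputs={p.name: _sha256(p) for p in output_paths},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path: str | Path) -> None:
        write_json(dataclasses.asdict(self), path)
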