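"""Configuration loading, presets, and provenance stamping.

A run is described by a small YAML file merged over package defaults
(defaults < file < explicit overrides).  The resolved configuration
validates into concrete :class:`ModelParameters` and
:class:`LifeHistoryParameters` before any computation, and every
pipeline run writes a provenance block (config echo, seed, package
version) next to its outputs so results are reproducible.
"""

from __future__ import annotations

import difflib
import importlib.resources
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .climate_response import LifeHistoryParameters
from .model_core import ModelParameters

__all__ = [
    "RunConfig",
    "load_presets",
    "load_config",
    "write_provenance",
]

_TOP_KEYS = {
    "model_preset",
    "life_history_preset",
    "model",
    "seed",
    "aggregation",
    "parameters",
    "life_history",
}
_PARAM_KEYS = {f.name for f in fields(ModelParameters)}
_LH_KEYS = {f.name for f in fields(LifeHistoryParameters)}


def load_presets() -> dict:
    """The packaged parameter presets (model and life-history)."""
    text = (
        importlib.resources.files("irmap").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


def _reject_unknown(given: dict, allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        msgs = []
        for key in sorted(unknown):
            hint = difflib.get_close_matches(key, sorted(allowed), n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            msgs.append(f"{key!r}{suffix}")
        raise ValueError(f"unknown {where} key(s): {', '.join(msgs)}")


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run configuration."""

    model_preset: str = "table1"
    life_history_preset: str = "parham2010"
    model: int = 1
    seed: int = 0
    aggregation: str = "mean"
    parameters: dict = field(default_factory=dict)  # overrides
    life_history: dict = field(default_factory=dict)  # overrides

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ValueError(f"model must be 1 or 2, got {self.model!r}")
        if self.aggregation not in ("mean", "median"):
            raise ValueError(
                f"aggregation must be mean|median, got {self.aggregation!r}"
            )
        _reject_unknown(self.parameters, _PARAM_KEYS, "parameters")
        _reject_unknown(self.life_history, _LH_KEYS, "life_history")
        # fail fast: resolution must succeed before any computation
        self.model_parameters()
        self.life_history_parameters()

    def model_parameters(self) -> ModelParameters:
        presets = load_presets()["model"]
        if self.model_preset not in presets:
            raise ValueError(
                f"unknown model preset {self.model_preset!r}; "
                f"available: {sorted(presets)}"
            )
        values = dict(presets[self.model_preset])
        values.update(self.parameters)
        if self.model == 2:
            values["alpha"] = 0.0
        return ModelParameters(**values)

    def life_history_parameters(self) -> LifeHistoryParameters:
        presets = load_presets()["life_history"]
        if self.life_history_preset not in presets:
            raise ValueError(
                f"unknown life-history preset {self.life_history_preset!r}; "
                f"available: {sorted(presets)}"
            )
        values = dict(presets[self.life_history_preset])
        values.update(self.life_history)
        return LifeHistoryParameters(**values)

    def echo(self) -> dict:
        """JSON-serialisable echo of the resolved configuration."""
        d = asdict(self)
        d["resolved_parameters"] = asdict(self.model_parameters())
        d["resolved_life_history"] = asdict(self.life_history_parameters())
        return d


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and overrides.

    Precedence: package defaults < file contents < keyword overrides.
    Unknown keys at any level raise with a closest-match suggestion.
    """
    merged: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a YAML mapping")
        _reject_unknown(raw, _TOP_KEYS, "config")
        merged.update(raw)
    _reject_unknown(overrides, _TOP_KEYS, "config")
    for key, value in overrides.items():
        if key in ("parameters", "life_history") and key in merged:
            merged[key] = {**merged[key], **value}
        else:
            merged[key] = value
    return RunConfig(**merged)


def write_provenance(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a provenance JSON (config echo, seed, version) next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "package": "irmap",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
    }
    if extra:
        block.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
    return path
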