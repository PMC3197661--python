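"""Run configuration: YAML/JSON round-tripping with field-level validation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .params import ModelParameters, ParameterError

__all__ = ["RunConfig", "load_config", "save_config"]

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run: model parameters + plumbing."""

    params: ModelParameters = dataclasses.field(default_factory=ModelParameters)
    seed: int = 0
    n_sets: int = 20
    scale: str = "desk"          # desk: S=20, n_sets=20; full: S=40, n_sets=1000
    out: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(seed=self.seed, n_sets=self.n_sets, scale=self.scale,
                 out=self.out, log_level=self.log_level)
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a config file (YAML or JSON; empty = all defaults).

    Unknown keys are rejected; invalid values are reported field-by-field
    through :class:`ParameterError`.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config root must be a mapping, got {type(data).__name__}")
    plumbing_fields = {"seed", "n_sets", "scale", "out", "log_level"}
    unknown = set(data) - _MODEL_FIELDS - plumbing_fields
    if unknown:
        raise ParameterError(f"unknown config keys: {', '.join(sorted(unknown))}")
    model_kwargs = {k: v for k, v in data.items() if k in _MODEL_FIELDS}
    plumbing = {k: v for k, v in data.items() if k in plumbing_fields}
    if plumbing.get("scale", "desk") not in ("desk", "full"):
        raise ParameterError(f"scale must be 'desk' or 'full', got {plumbing['scale']!r}")
    params = ModelParameters(**model_kwargs)
    return RunConfig(params=params, **plumbing)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config so that load_config reads back an identical one."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
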