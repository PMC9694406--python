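"""Model-parameter config files (flat YAML keyed like PopulationModel)."""

from __future__ import annotations

import dataclasses

import yaml

from .errors import ConfigError
from .pk import PopulationModel

__all__ = ["load_model_config", "dump_model_config"]

_FIELDS = {f.name for f in dataclasses.fields(PopulationModel)}


def load_model_config(path) -> PopulationModel:
    """Read a PopulationModel from YAML; keys must match field names exactly."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"model config must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _FIELDS)
    if unknown:
        raise ConfigError(f"unknown model config keys: {unknown}")
    if "cl_pop" not in raw:
        raise ConfigError("model config must set cl_pop (L/h per 12 kg FFM)")
    if "omega" in raw:
        raw["omega"] = tuple(tuple(float(x) for x in row) for row in raw["omega"])
    return PopulationModel(**raw)


def dump_model_config(model: PopulationModel, path) -> None:
    d = dataclasses.asdict(model)
    d["omega"] = [list(row) for row in model.omega]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
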