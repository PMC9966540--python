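"""YAML/JSON configuration loading for filter and simulation parameters.

Config blocks mirror the dataclass field names exactly; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping, Optional

import yaml

from .errors import ConfigError
from .reading import FilterConfig
from .synthetic import CohortParams, TraceParams

__all__ = [
    "load_yaml",
    "filter_config_from_mapping",
    "trace_params_from_mapping",
    "cohort_params_from_mapping",
]


def load_yaml(path) -> dict:
    """Parse a YAML (or JSON) config file into a mapping."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return dict(data)


def _from_mapping(cls, mapping: Optional[Mapping[str, Any]], what: str):
    mapping = dict(mapping or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ConfigError(f"unknown {what} key(s): {', '.join(unknown)}")
    # YAML lists become tuples where the dataclass expects tuples
    for f in dataclasses.fields(cls):
        if f.name in mapping and isinstance(mapping[f.name], list):
            mapping[f.name] = tuple(mapping[f.name])
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise ConfigError(f"invalid {what}: {exc}") from exc


def filter_config_from_mapping(mapping: Optional[Mapping[str, Any]] = None) -> FilterConfig:
    return _from_mapping(FilterConfig, mapping, "filter config")


def trace_params_from_mapping(mapping: Optional[Mapping[str, Any]] = None) -> TraceParams:
    return _from_mapping(TraceParams, mapping, "trace parameter")


def cohort_params_from_mapping(mapping: Optional[Mapping[str, Any]] = None) -> CohortParams:
    return _from_mapping(CohortParams, mapping, "cohort parameter")
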