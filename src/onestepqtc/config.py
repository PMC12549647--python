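"""Run configuration: YAML loading with strict (unknown-key) validation."""

from __future__ import annotations

import dataclasses
from typing import Any, TypeVar, get_args, get_origin, get_type_hints

import yaml

T = TypeVar("T")


class ConfigError(ValueError):
    pass


def _is_dataclass_type(tp) -> bool:
    return isinstance(tp, type) and dataclasses.is_dataclass(tp)


def _unwrap_optional(tp):
    if get_origin(tp) is not None:
        args = [a for a in get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


def from_dict(cls: type[T], data: dict[str, Any], path: str = "") -> T:
    """Build a (possibly nested) dataclass from a mapping.

    Unknown keys are rejected with the full dotted path, so a typo in a
    run config fails loudly instead of silently using a default.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    hints = get_type_hints(cls)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"{path or cls.__name__}: unknown keys {sorted(unknown)} "
            f"(allowed: {sorted(fields)})")
    kwargs = {}
    for name, value in data.items():
        target = _unwrap_optional(hints[name])
        if _is_dataclass_type(target) and isinstance(value, dict):
            kwargs[name] = from_dict(target, value,
                                     f"{path + '.' if path else ''}{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def load_yaml(path: str, cls: type[T]) -> T:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return from_dict(cls, raw or {})
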