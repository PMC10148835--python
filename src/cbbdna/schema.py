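"""Relational table schema carried in pool metadata."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

TYPES = ("integer", "text")


@dataclass(frozen=True)
class TableSchema:
    """Ordered attributes with declared types, a primary key, and the
    subset of attributes that filter queries may target."""

    attributes: tuple  # ((name, "integer"|"text"), ...)
    primary_key: str
    filterable: tuple = ()

    def __post_init__(self):
        names = [n for n, _ in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate attribute names in schema")
        for n, t in self.attributes:
            if t not in TYPES:
                raise ConfigError(f"unknown type {t!r} for attribute {n!r}")
        if self.primary_key not in names:
            raise ConfigError(f"primary key {self.primary_key!r} not in schema")
        for f in self.filterable:
            if f not in names:
                raise ConfigError(f"filterable attribute {f!r} not in schema")

    @property
    def names(self):
        return tuple(n for n, _ in self.attributes)

    def type_of(self, name: str) -> str:
        for n, t in self.attributes:
            if n == name:
                return t
        raise KeyError(name)

    def coerce(self, name: str, text: str):
        return int(text) if self.type_of(name) == "integer" else text

    def to_dict(self) -> dict:
        return {
            "attributes": [list(a) for a in self.attributes],
            "primary_key": self.primary_key,
            "filterable": list(self.filterable),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TableSchema":
        return cls(
            attributes=tuple((n, t) for n, t in d["attributes"]),
            primary_key=d["primary_key"],
            filterable=tuple(d.get("filterable", ())),
        )
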