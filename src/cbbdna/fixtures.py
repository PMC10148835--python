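"""Synthetic table generators used throughout the tests and examples.

``toy_table`` is the canonical four-record flight-tracking miniature
(attributes Id, Time, Velocity) used in every worked example: Ids 100-103
with Velocity values 512, 280, 280, 512, so Velocity posting lists are
[100, 103] and [101, 102]. The Time values of Ids 100 and 101 are fixed
(1015430211 and 332012549); the remaining two are synthetic fill chosen
once.

``random_table`` produces deterministic random tables with configurable
row count, non-unique cardinality and value length, so posting lists of
controllable expected length (rows / cardinality) exist.
"""

from __future__ import annotations

import string

import pandas as pd

from ._prng import SplitMix64, mix64
from .schema import TableSchema

_FIG_ROWS = [
    {"Id": 100, "Time": 1015430211, "Velocity": 512},
    {"Id": 101, "Time": 332012549, "Velocity": 280},
    {"Id": 102, "Time": 1015430400, "Velocity": 280},  # synthetic fill
    {"Id": 103, "Time": 332012777, "Velocity": 512},  # synthetic fill
]

TOY_SCHEMA = TableSchema(
    attributes=(("Id", "integer"), ("Time", "integer"), ("Velocity", "integer")),
    primary_key="Id",
    filterable=("Id", "Velocity"),
)


def toy_table():
    """The four-record worked-example table; returns (DataFrame, schema)."""
    return pd.DataFrame(_FIG_ROWS), TOY_SCHEMA


_ALPHABET = string.ascii_lowercase + string.digits


def random_table(
    rows: int,
    n_value_attrs: int = 2,
    cardinality: int = 10,
    value_length: int = 6,
    seed: int = 0,
):
    """Deterministic random table with integer keys 0..rows-1.

    Each of the *n_value_attrs* text attributes draws uniformly from its
    own pool of *cardinality* random strings, so the expected posting-list
    length is rows / cardinality. Returns (DataFrame, schema).
    """
    if rows < 0 or n_value_attrs < 1 or cardinality < 1 or value_length < 1:
        raise ValueError("fixture parameters must be positive")
    rng = SplitMix64(mix64(seed ^ 0x746162666978))  # "tabfix"
    attrs = [f"a{i + 1}" for i in range(n_value_attrs)]
    pools = {
        a: [
            "".join(_ALPHABET[rng.randbelow(len(_ALPHABET))]
                    for _ in range(value_length))
            for _ in range(cardinality)
        ]
        for a in attrs
    }
    data = {"Id": list(range(rows))}
    for a in attrs:
        data[a] = [pools[a][rng.randbelow(cardinality)] for _ in range(rows)]
    schema = TableSchema(
        attributes=(("Id", "integer"),) + tuple((a, "text") for a in attrs),
        primary_key="Id",
        filterable=("Id",) + tuple(attrs),
    )
    return pd.DataFrame(data), schema


def make_fixture(kind: str, seed: int = 0, **params):
    """Dispatch: ``kind`` is 'toy' or 'random' (with row/cardinality params)."""
    if kind == "toy":
        return toy_table()
    if kind == "random":
        return random_table(seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
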