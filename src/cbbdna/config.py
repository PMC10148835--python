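"""Codec configuration: every tunable in one serializable object."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

from .constraints import ConstraintThresholds, ErrorWeights
from .errors import ConfigError


@dataclass(frozen=True)
class LshParams:
    """MinHash/LSH shape: k-shingle length, number of hash functions r,
    and band count b (rows per band = r / b)."""

    shingle_k: int = 4
    num_hashes_r: int = 200
    bands_b: int = 20
    hash_seed: int = 0

    def __post_init__(self):
        if self.num_hashes_r % self.bands_b != 0:
            raise ConfigError("num_hashes_r must be divisible by bands_b")
        if self.shingle_k < 1:
            raise ConfigError("shingle_k must be >= 1")

    @property
    def rows_per_band(self) -> int:
        return self.num_hashes_r // self.bands_b


@dataclass(frozen=True)
class CodecConfig:
    """All codec tunables.

    Lengths are in bases.  ``l_info`` is derived (L_Oligo - L_CBB), and the
    permutation-offset reserve ``r_off`` is ceil(log4(max(n, 1))) so the
    quaternary prefix can name every candidate offset.
    """

    l_oligo: int = 250
    l_cbb: int = 60
    n_permutations: int = 8
    c_pad_reserve: int = 10  # bases reserved per Info-DNA segment for framing+pad
    epsilon: int = 2  # fountain redundancy beyond k packets
    converter: str = "RotatingQuattro"
    thresholds: ConstraintThresholds = field(default_factory=ConstraintThresholds)
    weights: ErrorWeights = field(default_factory=ErrorWeights)
    lsh: LshParams = field(default_factory=LshParams)
    master_seed: int = 0
    min_symbol_size: int = 4  # bytes per fountain symbol, lower bound
    max_source_symbols: int = 64  # symbol size grows to keep k at or below this

    def __post_init__(self):
        if self.l_cbb >= self.l_oligo:
            raise ConfigError("L_CBB must be smaller than L_Oligo")
        if self.n_permutations < 0 or self.epsilon < 0:
            raise ConfigError("n and epsilon must be non-negative")
        if self.c_pad_reserve < 3:
            raise ConfigError(
                "c must be >= 3 (marker + delimiter alone occupy 3 bases)"
            )
        if self.l_info - self.c_pad_reserve - self.r_off < 1:
            raise ConfigError("L_Info - c - r_off must be at least 1")
        if self.min_symbol_size < 1 or self.max_source_symbols < 1:
            raise ConfigError("fountain sizing parameters must be positive")

    @property
    def l_info(self) -> int:
        return self.l_oligo - self.l_cbb

    @property
    def r_off(self) -> int:
        # smallest r with 4^r >= n (integer arithmetic; no float log)
        n = max(self.n_permutations, 1)
        r = 0
        while 4**r < n:
            r += 1
        return r

    def with_seed(self, master_seed: int) -> "CodecConfig":
        return replace(self, master_seed=master_seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["weights"] = asdict(self.weights)
        d["lsh"] = asdict(self.lsh)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CodecConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = ConstraintThresholds(**d["thresholds"])
        if "weights" in d:
            d["weights"] = ErrorWeights(**d["weights"])
        if "lsh" in d:
            d["lsh"] = LshParams(**d["lsh"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "CodecConfig":
        """Load from a JSON or YAML configuration file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
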