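import pytest

from cbbdna import CodecConfig, encode_table, toy_table
from cbbdna.codec import Codec
from cbbdna._prng import SplitMix64

BASES = "ACGT"


def random_dna(rng: SplitMix64, length: int) -> str:
    return "".join(BASES[rng.randbelow(4)] for _ in range(length))


@pytest.fixture(scope="session")
def default_config():
    return CodecConfig(master_seed=1)


@pytest.fixture(scope="session")
def codec(default_config):
    return Codec(default_config)


@pytest.fixture(scope="session")
def toy_pool(default_config):
    table, schema = toy_table()
    return encode_table(
        table, schema, default_config, nonunique_attrs=["Velocity"]
    )
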