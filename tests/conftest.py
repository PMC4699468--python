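import numpy as np
import pytest

from brackmag.synthetic_community import CommunityConfig, make_community_fixture


@pytest.fixture(scope="session")
def small_config() -> CommunityConfig:
    """A runtime-scaled community: same stated world, smaller genomes."""
    return CommunityConfig(
        n_genomes=5,
        genome_length_range=(40_000, 60_000),
        contig_target_len=8_000,
        marker_length=300,
        n_replicated=1,
        reads_per_sample=200,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return make_community_fixture(small_config, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
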