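"""Shared fixtures: tiny constructed genomes and a small mock scenario."""

import numpy as np
import pytest

from twobrad.enzyme import BCGI
from twobrad.simulate import SimGenomeSpec, mock_scenario, synth_genome


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def plant_tag(rng: np.random.Generator, flank_left: int = 10,
              flank_right: int = 10) -> str:
    """A concrete 32 nt BcgI tag: flank + CGA + 6 random + TGC + flank."""
    return (random_dna(rng, flank_left) + "CGA" + random_dna(rng, 6)
            + "TGC" + random_dna(rng, flank_right))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_mock():
    """A 5-species mock with 50% host spike, reused across tests."""
    return mock_scenario(n_species=5, host_pct=0.5, n_reads=5000, seed=11,
                         genome_length=30_000, host_genome_length=60_000)


@pytest.fixture(scope="session")
def toy_genomes():
    """Three deterministic synthetic genomes keyed by species."""
    out = {}
    for i, sp in enumerate(["alpha", "beta", "gamma"]):
        _, seq = synth_genome(
            SimGenomeSpec(sp, length=20_000, seed=100 + i), BCGI)
        out[sp] = seq
    return out
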