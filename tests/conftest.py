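import numpy as np
import pandas as pd
import pytest

from rerepkit import simcore


@pytest.fixture(scope="session")
def genome():
    """10 Mb genome: 1000 x 10 kb bins, Mb-scale timing domains."""
    return simcore.build_genome(1000, 10_000, seed=1)


@pytest.fixture(scope="session")
def origins(genome):
    """Licensed origins with early-skewed CDT1-like weights and dormant subset."""
    return simcore.place_origins(genome, 30, skew=2.0, dormant_fraction=0.15, seed=2)


@pytest.fixture(scope="session")
def uniform_origins(genome):
    """Uniformly placed origins (no licensing skew, no dormant subset)."""
    return simcore.place_origins(genome, 30, skew=0.0, seed=2)


@pytest.fixture(scope="session")
def params():
    return simcore.SimParams(seed=3)


@pytest.fixture(scope="session")
def normal_pop(genome, origins, params):
    return simcore.simulate_population(genome, origins, params, "normal")


@pytest.fixture(scope="session")
def rerep_pop(genome, origins, params):
    return simcore.simulate_population(genome, origins, params.with_(seed=4),
                                       "rereplication")


@pytest.fixture(scope="session")
def stress_pop(genome, origins, params):
    return simcore.simulate_population(genome, origins, params.with_(seed=7), "stress")


@pytest.fixture()
def origin_intervals(genome, origins):
    return pd.DataFrame({"chrom": genome.chrom_name,
                         "start": origins.positions - 500,
                         "end": origins.positions + 500})


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1_000_000, max_len=5000):
    starts = rng.integers(0, span, n)
    lengths = rng.integers(1, max_len, n)
    return pd.DataFrame({"chrom": rng.choice(chroms, n),
                         "start": starts, "end": starts + lengths})
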