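import random

import pytest

from transannot.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A 60-gene synthetic study shared by the integration-style tests."""
    return simulate(SimConfig(n_genes=60, seed=7))


@pytest.fixture(scope="session")
def small_sim_result(small_sim):
    from transannot.pipeline import run_pipeline

    return run_pipeline(
        small_sim.transcriptome,
        genome=small_sim.genome,
        database=small_sim.database,
    )


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_nt(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_aa(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))
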