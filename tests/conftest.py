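import numpy as np
import pytest

from structmut import simulate
from structmut.catalog import MutationalSignature


@pytest.fixture(scope="session")
def uniform_signature():
    return MutationalSignature.uniform()


@pytest.fixture(scope="session")
def random_gene():
    return simulate.random_coding_gene(30, seed_or_rng=42, gene="TESTG")


@pytest.fixture(scope="session")
def two_domain():
    structure, truth = simulate.make_two_domain_structure(seed=7)
    return structure, truth


@pytest.fixture(scope="session")
def skewed_signature():
    """A C>T-dominant signature resembling endogenous deamination spectra."""
    rng = np.random.default_rng(11)
    probs = rng.dirichlet(np.full(96, 0.5))
    probs[32:48] += 3.0 / 16.0  # boost all C>T channels
    probs /= probs.sum()
    return MutationalSignature(probs)
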