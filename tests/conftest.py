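import numpy as np
import pytest

from ecotraitmap.abundance_io import AbundanceTable
from ecotraitmap.diffusion_map import TraitSpace, TrustedNetwork
from ecotraitmap.metacommunity_sim import (SimParams, build_metacommunity,
                                           collect_samples, sample_traits,
                                           simulate)

import scipy.sparse as sparse


@pytest.fixture
def toy_table():
    """3 species × 4 samples with simple values."""
    return AbundanceTable(
        ["spA", "spB", "spC"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 2.5, 0.0, 1.0],
                  [0.0, 1.0, 2.0, 0.5],
                  [2.5, 0.0, 1.0, 2.0]]),
    )


@pytest.fixture
def path3_network():
    """Unweighted path a–b–c as a trusted network."""
    W = np.array([[0.0, 1.0, 0.0],
                  [1.0, 0.0, 1.0],
                  [0.0, 1.0, 0.0]])
    return TrustedNetwork(["a", "b", "c"], sparse.csr_matrix(W), k=1)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated metacommunity dataset with known traits.

    60 species on a 4×5 grid, 8 pooled runs — enough samples for a
    spanning trusted network in a couple of seconds.
    """
    rng_traits = np.random.default_rng(101)
    traits = sample_traits(60, seed=rng_traits)
    params = SimParams(horizon=120.0)
    outs = [simulate(traits, build_metacommunity((4, 5), seed=np.random.default_rng(200 + i)),
                     params)
            for i in range(8)]
    table = collect_samples(outs, traits)
    return traits, outs, table
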