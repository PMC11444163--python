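import numpy as np
import pytest

from pairscan.genome import GenomeDef, Region, make_bins
from pairscan.simulate import CohortConfig, ExpressionSpec, simulate_cohort


@pytest.fixture
def toy_genome():
    return GenomeDef.from_lengths({"chrT": 10_000, "chrU": 5_500})


@pytest.fixture
def toy_grid(toy_genome):
    return make_bins(toy_genome, 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort with all default effects, reused across tests."""
    cfg = CohortConfig(n_patients=12,
                       expression=ExpressionSpec(n_genes=120))
    return simulate_cohort(cfg, seed=11)
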