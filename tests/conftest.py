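import warnings

import numpy as np
import pytest

from mito_orfan.simulate import SimConfig, simulate_study

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def study():
    """One small seeded F/M study shared across tests (2 species)."""
    genomes, truth = simulate_study(SimConfig(seed=11, n_species=2))
    return genomes, truth


@pytest.fixture(scope="session")
def fm_pair(study):
    genomes, truth = study
    f_id, m_id = truth.fm_pairs[0]
    by_id = {g.id: g for g in genomes}
    return by_id[f_id], by_id[m_id]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
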