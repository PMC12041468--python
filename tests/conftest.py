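import numpy as np
import pandas as pd
import pytest

import stromamatrix as sm


@pytest.fixture(scope="session")
def tmt_experiment():
    """1000-protein TMT simulation at low noise with a fixed seed."""
    table, design, truth = sm.gen_tmt_experiment(
        n_proteins=1000, noise_sd=0.1, seed=7
    )
    return table, design, truth


@pytest.fixture(scope="session")
def sc_dataset():
    """Default single-cell simulation (5 planted states)."""
    return sm.gen_sc_counts(seed=0)


@pytest.fixture(scope="session")
def sc_discovery(sc_dataset):
    """State discovery on the default single-cell simulation (shared because
    the NMF sweep is the slow step)."""
    adata, truth = sc_dataset
    disc = sm.discover_cell_states(adata, seed=0, max_iter=300)
    return disc, truth


@pytest.fixture(scope="session")
def sc_lognorm(sc_dataset):
    adata, truth = sc_dataset
    lognorm = sm.log_normalize(np.asarray(adata.X))
    labels = pd.Series(truth.state_of_cell).loc[adata.obs_names].to_numpy()
    return adata, truth, lognorm, labels


@pytest.fixture
def rng():
    return np.random.default_rng(42)
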