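import numpy as np
import pandas as pd
import pytest

from phytoarray import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_experiment():
    """Noiseless 30-gene experiment with two planted effects."""
    cfg = sd.ExperimentConfig(
        n_genes=30,
        noise_sigma=0.0,
        seed=7,
        treatments=("LPS", "shikonin+LPS", "cytopiloyne+LPS"),
        times=(0.5, 2.0, 4.0),
        effects={
            ("G001", "shikonin+LPS", 0.5): 4.0,
            ("G002", "cytopiloyne+LPS", 4.0): 0.25,
        },
    )
    return sd.simulate_experiment(cfg)


def random_ratio_matrix(rng, n_genes=20, treatments=("a", "b", "c"), low=0.05, high=8.0):
    vals = np.exp(rng.uniform(np.log(low), np.log(high), size=(n_genes, len(treatments))))
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=list(treatments))
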