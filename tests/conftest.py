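import numpy as np
import pandas as pd
import pytest

from dosagenet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 genotypes x 3 reps, 400 genes, 4 planted modules of 40 genes."""
    config = SimulationConfig(
        n_genes=400,
        n_genotypes=20,
        reps_per_genotype=3,
        module_sizes=(40, 40, 40, 40),
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {
            "chromosome": ["Chr01", "Chr01", "Chr02"],
            "start": [100, 5000, 100],
            "end": [1099, 5999, 1099],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
    )
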