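import warnings

import numpy as np
import pandas as pd
import pytest

from paraclines import SimConfig
from paraclines.containers import CountMatrix
from paraclines.simulate import simulate_experiment

warnings.filterwarnings("ignore", category=UserWarning)


SMALL_ARMS = {"2L": 300, "2R": 300, "3R": 300, "X": 200}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes_per_species=800,
        n_orthologs=600,
        arms=dict(SMALL_ARMS),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


def build_count_matrix(counts: np.ndarray, populations=None, temperatures=None):
    """CountMatrix from a gene x sample array with a default 2x2x(r) design."""
    n_genes, n_samples = counts.shape
    samples = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        populations = ["low"] * (n_samples // 2) + ["high"] * (n_samples - n_samples // 2)
    if temperatures is None:
        temperatures = [21] * n_samples
    design = pd.DataFrame(
        {
            "species": "spA",
            "population": populations,
            "temperature": temperatures,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=samples,
    )
    frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    return CountMatrix(frame, design)


@pytest.fixture
def cm_builder():
    return build_count_matrix
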