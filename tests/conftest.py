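import numpy as np
import pandas as pd
import pytest

from spliceclip.synthetic import (
    SimulationConfig, simulate_annotation, simulate_timecourse_counts,
)


@pytest.fixture(scope="session")
def annotation_small():
    return simulate_annotation(SimulationConfig(n_genes=14, seed=3))


@pytest.fixture(scope="session")
def counts_small(annotation_small):
    splice, genes, order = simulate_timecourse_counts(annotation_small)
    return splice, genes, order


def make_comparisons(rows):
    """Comparison table from (sample_a, sample_b, delta_psi, bayes_factor) rows."""
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "delta_psi",
                                       "bayes_factor"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
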