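import numpy as np
import pytest

from gwgen.identification import identify_gwgen
from gwgen.netio import apply_degree_cap
from gwgen.synthetic import generate_candidate_gwgen, simulate_expression

SMALL_SIZES = dict(n_proteins=12, n_genes=20, n_mirnas=6, n_lncrnas=3)


@pytest.fixture(scope="session")
def small_instance():
    """Seed-fixed noiseless planted instance shared across test modules."""
    candidate, truth = generate_candidate_gwgen(seed=11, **SMALL_SIZES)
    data = simulate_expression(truth, n_samples=40, seed=12)
    return candidate, truth, data


@pytest.fixture(scope="session")
def small_identified(small_instance):
    candidate, truth, data = small_instance
    capped = apply_degree_cap(candidate, data)
    return identify_gwgen(capped, data)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
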