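import numpy as np
import pytest

from thymod import CONDITIONS, SimConfig, filter_cells, generate_counts, normalise


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 400 genes, 5 x 80 cells, 5 small modules."""
    return SimConfig(
        n_genes=400,
        n_cells_per_condition={c: 80 for c in CONDITIONS},
        n_modules=5,
        module_size_range=(30, 40),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_counts(small_config)


@pytest.fixture(scope="session")
def small_normalised(small_data):
    counts, _ = small_data
    filtered, _ = filter_cells(counts)
    return normalise(filtered)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
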