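import numpy as np
import pytest

from drydiv import synthetic as syn


@pytest.fixture(scope="session")
def small_scaffold():
    """A compact single-site experiment (4 species, ~200 focal trees)."""
    return syn.build_experiment(seed=11, n_species=4, richness_levels=(1, 2, 4), plot_rows=6)


@pytest.fixture(scope="session")
def default_scaffold():
    """The default study conditions (~300 focal trees, 1-6 richness gradient)."""
    return syn.build_experiment(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
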