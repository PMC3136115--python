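import numpy as np
import pytest

import ermimap as em


@pytest.fixture(scope="session")
def panel():
    return em.load_panel()


@pytest.fixture(scope="session")
def table1(panel):
    return em.load_table1(panel)


@pytest.fixture(scope="session")
def table2(panel):
    return em.load_table2(panel)


@pytest.fixture(scope="session")
def small_homes():
    """A quick 150-home synthetic dataset shared across tests."""
    return em.generate(em.SynthConfig(n_homes=150, n_locales=12, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
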