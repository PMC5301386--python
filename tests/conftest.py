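import numpy as np
import pytest

import episeq as eq


@pytest.fixture(scope="session")
def toy():
    return eq.worked_toy()


@pytest.fixture(scope="session")
def planted_small():
    """Small planted-signal corpus shared by pipeline-level tests."""
    cfg = eq.planted_config(n_records=14, length_range=(70, 110))
    return eq.generate_corpus(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
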