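import numpy as np
import pytest

import immunosig as im


@pytest.fixture(scope="session")
def default_cohort():
    """One study-calibrated 150-subject cohort, shared across tests."""
    return im.generate_cohort(im.default_config(), seed=0)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with only the 3-marker Profile-2 signature planted (1.5 SD)."""
    return im.generate_cohort(im.planted_signature_config(1.5), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
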