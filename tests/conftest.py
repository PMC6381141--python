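import numpy as np
import pytest

from mciprog import default_adni_like_spec, generate_cohort


@pytest.fixture(scope="session")
def adni_table():
    """Default ADNI-like synthetic cohort (seed 0), shared read-only."""
    return generate_cohort(default_adni_like_spec(seed=0)).as_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
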