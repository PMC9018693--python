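import numpy as np
import pytest

from epiamplicon import MixtureSpec, make_amplicon_spec

DEMO7_LABELS = [-118, -91, -47, -3, 92, 112, 131]
DEMO8_LABELS = [-227, -183, -137, -71, -51, 26, 85, 144]


@pytest.fixture(scope="session")
def spec7():
    """7-CpG amplicon of 388 bp spanning a promoter TSS."""
    return make_amplicon_spec(7, 388, DEMO7_LABELS, seed=1)


@pytest.fixture(scope="session")
def spec8():
    """8-CpG amplicon of 403 bp."""
    return make_amplicon_spec(8, 403, DEMO8_LABELS, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def clean_mixture(probs, n, seed=0):
    """Error-free, fully converted mixture spec."""
    return MixtureSpec(
        epiallele_probs=probs,
        n_molecules=n,
        conversion_rate=1.0,
        inappropriate_conversion_rate=0.0,
        seq_error_rate=0.0,
        seed=seed,
    )
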