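import warnings

import pytest

from vlpdetect.config import RunConfig
from vlpdetect.synth_ecg import NoiseSpec, VlpSpec, generate_record

# the 5-level DWT on a 700-sample beat window triggers a benign pywt
# boundary-effect warning on every call; silence it suite-wide
warnings.filterwarnings("ignore", message="Level value .* too high")


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 20-beat record with ground truth."""
    return generate_record(20, vlp=None, noise=None, seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    """20-beat record with default acquisition noise."""
    return generate_record(20, vlp=None, noise=NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def paired_records():
    """Same-seed record pair without / with a 10 uV artificial VLP."""
    neg = generate_record(60, vlp=None, noise=NoiseSpec(), seed=7)
    pos = generate_record(60, vlp=VlpSpec.uniform(10.0), noise=NoiseSpec(), seed=7)
    return neg, pos

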