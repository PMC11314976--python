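import numpy as np
import pytest

from sleepmat import synthdata as sd
from sleepmat.decompose import BandpassDecomposer


@pytest.fixture(scope="session")
def decomposer():
    return BandpassDecomposer()


@pytest.fixture(scope="session")
def default_profile():
    return sd.SubjectProfile()


@pytest.fixture(scope="session")
def supine_template():
    return sd.make_template("supine")


@pytest.fixture(scope="session")
def clean_minute(default_profile, supine_template):
    return sd.synth_minute(default_profile, supine_template, movement=False,
                           rng_seed=123)


@pytest.fixture(scope="session")
def clean_decomposed(clean_minute, decomposer):
    return decomposer.transform([clean_minute])[0]


@pytest.fixture(scope="session")
def contaminated_minute(default_profile, supine_template):
    return sd.synth_minute(default_profile, supine_template, movement=True,
                           rng_seed=321)
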