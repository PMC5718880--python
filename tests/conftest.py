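import numpy as np
import pytest

from strucval.refdata import default_bundle
from strucval.synth import make_helix_peptide, make_synthetic_archive, make_xray_entry


@pytest.fixture(scope="session")
def bundle():
    return default_bundle()


@pytest.fixture(scope="session")
def helix10(bundle):
    return make_helix_peptide(10, bundle=bundle)


@pytest.fixture(scope="session")
def helix25(bundle):
    return make_helix_peptide(25, bundle=bundle)


@pytest.fixture(scope="session")
def xray_entry():
    return make_xray_entry(12)


@pytest.fixture(scope="session")
def archive400():
    return make_synthetic_archive(400, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
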