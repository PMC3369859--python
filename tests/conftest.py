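import pytest

from bovmito.classifier import default_hierarchy
from bovmito.reference_variants import HaplotypeProfile, Region
from bovmito.synthetic_data import generate_reference


@pytest.fixture(scope="session")
def reference():
    return generate_reference(seed=1)


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def make_profile():
    def _make(*labels, sample_id="x", covered=Region(1, 16338)):
        return HaplotypeProfile.from_labels(sample_id, labels, covered_region=covered)

    return _make
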