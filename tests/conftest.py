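import pytest

from duohit import datasets
from duohit.synthetic_data import SyntheticConfig, simulate_duo


@pytest.fixture(scope="session")
def candidates():
    """The fifteen published shared candidates (1 LoF, 14 missense)."""
    return datasets.candidate_variants()


@pytest.fixture(scope="session")
def p1_segments():
    return datasets.tumour_segments("P1")


@pytest.fixture(scope="session")
def p2_segments():
    return datasets.tumour_segments("P2")


@pytest.fixture(scope="session")
def study_shape_bundle(tmp_path_factory):
    """One study-shaped synthetic duo, generated once per session."""
    out = tmp_path_factory.mktemp("sim")
    bundle, truth = simulate_duo(SyntheticConfig(seed=20_240_101), out)
    return bundle, truth
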