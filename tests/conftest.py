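import pytest

from agetech import datasets


@pytest.fixture(scope="session")
def dist():
    """National disease-count pools (thousands)."""
    return datasets.load_disease_distribution()


@pytest.fixture(scope="session")
def singles():
    """Single-disease column (thousands)."""
    return datasets.load_single_counts()


@pytest.fixture(scope="session")
def matrix():
    """National 8x8 pairwise co-occurrence matrix."""
    return datasets.load_comorbidity_matrix()


@pytest.fixture(scope="session")
def profile():
    return datasets.load_assistance_profile()


@pytest.fixture(scope="session")
def population():
    return datasets.load_population()


@pytest.fixture(scope="session")
def mortality():
    return datasets.load_mortality()
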