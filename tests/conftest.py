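import numpy as np
import pytest

from fucotype.features import ExtractionParams, extract_feature_table, feature_matrix
from fucotype.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-noise synthetic set: spectra, GSMs."""
    return generate_dataset(n_per_class=10, seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    spectra, gsms = small_dataset
    fvs = extract_feature_table(spectra, gsms, ExtractionParams())
    return feature_matrix(fvs), [g.manual_label for g in gsms]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
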