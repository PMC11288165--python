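import pytest

from gramclass.ngram_features import build_feature_matrix
from gramclass.synthetic import SyntheticSpec, fourteen_class_spec, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The small four-class planted-motif benchmark at its default settings."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_fm(default_dataset):
    sset, _ = default_dataset
    return build_feature_matrix(sset)


@pytest.fixture(scope="session")
def strong14_dataset():
    """The 14-class strong-signal benchmark (50 sequences per class)."""
    return generate_dataset(fourteen_class_spec(seed=0))


@pytest.fixture(scope="session")
def strong14_fm(strong14_dataset):
    sset, _ = strong14_dataset
    return build_feature_matrix(sset)
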