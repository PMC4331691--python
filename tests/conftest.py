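import pytest

from chemtag.postprocess import FilterSet
from chemtag.resources import load_resources
from chemtag.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def resources():
    return load_resources()


@pytest.fixture(scope="session")
def filters(resources):
    return FilterSet.from_yaml(resources.filters_path)


@pytest.fixture(scope="session")
def small_corpus(resources):
    """40 fully annotated synthetic documents (deterministic)."""
    return generate(SynthConfig(n_documents=40, random_seed=11), resources)
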