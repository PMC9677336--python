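import pytest

from c2m2.fixtures import GeneratorConfig, generate_references
from c2m2.schema import build_registry


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def ontology():
    """Shared mini-ontologies: (refs, provisional, dags, slims)."""
    return generate_references(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def refs(ontology):
    return ontology[0]


@pytest.fixture(scope="session")
def provisional(ontology):
    return ontology[1]


@pytest.fixture(scope="session")
def dags(ontology):
    return ontology[2]


@pytest.fixture(scope="session")
def slims(ontology):
    return ontology[3]
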