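import pytest
from hypothesis import settings

from sepsiskg import (
    DictionaryMockBackend,
    PromptTemplate,
    extract_corpus,
    load_schema,
)
from sepsiskg.simulate import SimConfig, generate_corpus

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def gold50(schema):
    """The bundled study conditions: 50 synthetic documents, seed 42."""
    return generate_corpus(SimConfig(n_docs=50, seed=42), schema)


@pytest.fixture(scope="session")
def perfect_extraction(schema, gold50):
    """Extraction over gold50 with the perfect (no-noise) mock backend."""
    backend = DictionaryMockBackend(gold50.sentences)
    results, failures = extract_corpus(
        gold50.documents, PromptTemplate(), backend, schema
    )
    assert not failures
    return results
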