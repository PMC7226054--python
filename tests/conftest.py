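import pytest

from deidkit import GeneratorConfig, generate_corpus, tokenize
from deidkit.corpus_io import AnnotatedDocument, PHIEntity


@pytest.fixture(scope="session")
def example_sentence():
    """The canonical worked example: an 8-token sentence with a two-token
    name and a single-token age."""
    text = "Harlan Oneil is a 43 years old gentleman"
    tokens = tokenize(text)
    entities = [PHIEntity(0, 12, "NAME"), PHIEntity(18, 20, "AGE")]
    return text, tokens, entities


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_docs=12, seed=3))


@pytest.fixture(scope="session")
def small_hard_corpus():
    return generate_corpus(GeneratorConfig(n_docs=12, seed=3, hard=True))


@pytest.fixture()
def tiny_doc():
    text = "Edwin 43"
    return AnnotatedDocument("tiny", text, [])
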