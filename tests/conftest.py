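import pytest

from perturbkit.fixtures import FixtureConfig, generate_classification_corpus, generate_qa_corpus
from perturbkit.homophones import DictionaryProvider
from perturbkit.tagging import load_medical_lexicon

# the discharge-summary question used as the running worked example
EXAMPLE_TEXT = (
    "How did voxelotor affect the patient’s scleral icterus and overall "
    "quality of life in the given discharge summary?"
)
EXAMPLE_REDACTED = (
    "How did voxelotor affect the patient’s scleral and overall quality of "
    "in the given discharge summary?"
)
EXAMPLE_HOMOPHONE = (
    "How deed voxelotor affect the patient’s scleral icterus and overall "
    "quality of life inn the given discharge summary?"
)


@pytest.fixture(scope="session")
def provider():
    return DictionaryProvider()


@pytest.fixture(scope="session")
def lexicon():
    return load_medical_lexicon()


@pytest.fixture(scope="session")
def sentiment_records():
    return generate_classification_corpus(FixtureConfig(n_records=60, seed=11))


@pytest.fixture(scope="session")
def condition_records():
    return generate_classification_corpus(
        FixtureConfig(n_records=60, seed=12), task="condition_ternary"
    )


@pytest.fixture(scope="session")
def qa_records():
    return generate_qa_corpus(FixtureConfig(n_records=40, seed=13))
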