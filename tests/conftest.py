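import pytest

from fgie import SynthConfig, TrainedVocabTokenizer, generate_corpus, lnc_epic1_example
from fgie.segment import segment_words
from fgie.synthetic import generate_corpus_detailed


@pytest.fixture(scope="session")
def example_doc():
    """The nine-mention, four-group single-sentence worked example."""
    return lnc_epic1_example()


@pytest.fixture(scope="session")
def small_corpus():
    """Fifty synthetic documents at default study conditions."""
    return generate_corpus(SynthConfig(n_docs=50, seed=7))


@pytest.fixture(scope="session")
def small_corpus_detailed():
    return generate_corpus_detailed(SynthConfig(n_docs=50, seed=7))


@pytest.fixture(scope="session")
def tiny_tagger(small_corpus):
    """A quickly trained tagger for pipeline-shape tests (not accuracy)."""
    from fgie.tagging import TrainConfig, train_tagger

    model, _ = train_tagger(
        small_corpus[:25],
        TrainConfig(epochs=3, seed=0, encoder_dim=32, encoder_ff=64),
    )
    return model


@pytest.fixture(scope="session")
def tiny_linker(small_corpus):
    from fgie.linking import LinkTrainConfig, train_linker

    model, _ = train_linker(
        small_corpus[:25],
        LinkTrainConfig(epochs=3, seed=0, encoder_dim=32, encoder_ff=64),
    )
    return model


@pytest.fixture(scope="session")
def tokenizer(small_corpus):
    words = [w.surface for d in small_corpus for w in segment_words(d.text)]
    return TrainedVocabTokenizer.train(words)
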