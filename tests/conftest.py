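import numpy as np
import pytest

from textnetsum import Corpus, Document, ThemeSpec, generate_corpus


def make_random_corpus(rng: np.random.Generator, n_docs: int, vocab_size: int,
                       max_sentences: int = 4, max_sentence_len: int = 8,
                       source: str = "random") -> Corpus:
    """Arbitrary corpus with no planted structure, for oracle comparisons."""
    vocab = [f"w{i:03d}" for i in range(vocab_size)]
    docs = []
    for d in range(n_docs):
        sentences = []
        for _ in range(int(rng.integers(1, max_sentences + 1))):
            length = int(rng.integers(2, max_sentence_len + 1))
            words = [vocab[int(i)] for i in rng.integers(0, vocab_size, size=length)]
            sentences.append(" ".join(words) + ".")
        docs.append(Document(entity_id=f"D{d:03d}", raw_text=" ".join(sentences), source=source))
    return Corpus(documents=docs, source=source)


@pytest.fixture
def random_corpus_factory():
    return make_random_corpus


@pytest.fixture(scope="session")
def theme_corpus():
    """The standard desk-scale planted-theme benchmark: 3 themes x 15 words
    x 10 entities, 20% background noise, seed 7."""
    spec = ThemeSpec(n_themes=3, words_per_theme=15, entities_per_theme=10,
                     noise_fraction=0.2, seed=7)
    corpus, entity_theme, theme_terms = generate_corpus(spec)
    return corpus, entity_theme, theme_terms


@pytest.fixture
def tiny_corpus():
    docs = [
        Document(entity_id="GENE1", raw_text="Kinase binds substrate. It regulates transport."),
        Document(entity_id="GENE2", raw_text="Membrane transport protein."),
        Document(entity_id="GENE3", raw_text="Kinase substrate phosphorylation signal."),
    ]
    return Corpus(documents=docs, source="tiny")
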