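import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from textnetsum import (
    Corpus,
    Document,
    FilterConfig,
    background_from_corpus,
    build_tdm,
    compute_tfidf,
    default_stopwords,
    extract_ngrams,
    filter_vocabulary,
    tokenize,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Kinase binds substrate. It regulates transport.",
             [["kinase", "binds", "substrate"], ["it", "regulates", "transport"]]),
            ("", []),
            ("E3 ubiquitin-protein ligase (HECT-type).",
             [["e3", "ubiquitin-protein", "ligase", "hect-type"]]),
            ("Activated by 42 and 3.5 units!", [["activated", "by", "and", "units"]]),
            ("No terminal punctuation", [["no", "terminal", "punctuation"]]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=200))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_tokens_are_normalized(self, text):
        for sentence in tokenize(text):
            assert sentence  # no empty sentences
            for token in sentence:
                assert token and token == token.lower()
                assert not any(c.isspace() for c in token)
                assert any(c.isalpha() for c in token)

    @given(st.text(max_size=200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_deterministic(self, text):
        assert tokenize(text) == tokenize(text)


class TestTfidf:
    def test_term_in_every_document_weighs_zero(self, tiny_corpus):
        tdm = compute_tfidf(tiny_corpus)
        # "kinase" appears in docs 1 and 3 only; "transport" in 1 and 2.
        # Construct a term in all docs:
        docs = [Document(entity_id=f"D{i}", raw_text="protein stuff here.") for i in range(3)]
        tdm = compute_tfidf(Corpus(documents=docs))
        assert np.all(tdm.weights[tdm.terms.index("protein")] == 0.0)

    def test_single_document_corpus_all_zero(self):
        corpus = Corpus(documents=[Document(entity_id="D0", raw_text="kinase binds substrate.")])
        tdm = compute_tfidf(corpus)
        assert np.all(tdm.weights == 0.0)

    def test_hand_evaluated_weight(self):
        docs = [
            Document(entity_id="D0", raw_text="kinase kinase other."),
            Document(entity_id="D1", raw_text="membrane other."),
            Document(entity_id="D2", raw_text="transport other."),
        ]
        tdm = compute_tfidf(Corpus(documents=docs))
        w = tdm.weights[tdm.terms.index("kinase"), 0]
        assert w == pytest.approx(2 * math.log(3), abs=1e-12)

    def test_matches_closed_form_on_random_corpus(self, random_corpus_factory):
        rng = np.random.default_rng(42)
        corpus = random_corpus_factory(rng, n_docs=12, vocab_size=25)
        tdm = compute_tfidf(corpus)
        df = oracles.document_frequencies(corpus)
        for i, term in enumerate(tdm.terms):
            for j, doc in enumerate(corpus):
                count = doc.token_counts().get(term, 0)
                expected = oracles.tfidf_weight(count, len(corpus), df.get(term, 0))
                assert tdm.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_document_reordering(self, random_corpus_factory):
        rng = np.random.default_rng(3)
        corpus = random_corpus_factory(rng, n_docs=8, vocab_size=15)
        reordered = Corpus(documents=list(reversed(corpus.documents)), source=corpus.source)
        a, b = compute_tfidf(corpus), compute_tfidf(reordered)
        assert a.terms == b.terms
        perm = [a.doc_ids.index(d) for d in b.doc_ids]
        np.testing.assert_allclose(a.weights[:, perm], b.weights, atol=1e-15)


class TestFilterVocabulary:
    def test_stopword_removed(self, tiny_corpus):
        vocab = filter_vocabulary(tiny_corpus, FilterConfig(stopwords=frozenset({"it"})))
        assert "it" not in vocab
        assert "kinase" in vocab

    def test_max_doc_freq_fraction_boundary(self):
        docs = [Document(entity_id=f"D{i}", raw_text=f"protein specific{i}.") for i in range(4)]
        corpus = Corpus(documents=docs)
        vocab = filter_vocabulary(corpus, FilterConfig(max_doc_freq_fraction=0.99))
        assert "protein" not in vocab  # occurs in all documents
        assert "specific0" in vocab

    def test_min_doc_freq_matches_brute_force(self, random_corpus_factory):
        rng = np.random.default_rng(11)
        corpus = random_corpus_factory(rng, n_docs=20, vocab_size=30)
        vocab = filter_vocabulary(corpus, FilterConfig(min_doc_freq=3))
        df = oracles.document_frequencies(corpus)
        assert set(vocab) == {t for t, v in df.items() if v >= 3}

    def test_empty_whitelist_is_error(self, tiny_corpus):
        with pytest.raises(ValueError, match="whitelist"):
            filter_vocabulary(tiny_corpus, FilterConfig(whitelist=frozenset()))

    def test_whitelist_bounds_vocabulary(self, tiny_corpus):
        vocab = filter_vocabulary(
            tiny_corpus, FilterConfig(whitelist=frozenset({"kinase", "transport", "absent"}))
        )
        assert set(vocab) <= {"kinase", "transport"}

    def test_ordering_and_top_k(self):
        docs = [Document(entity_id="D0", raw_text="beta beta alpha alpha gamma.")]
        corpus = Corpus(documents=docs)
        vocab = filter_vocabulary(corpus, FilterConfig())
        assert vocab == ["alpha", "beta", "gamma"]  # ties lexicographic
        assert filter_vocabulary(corpus, FilterConfig(top_k_terms=2)) == ["alpha", "beta"]

    def test_filters_compose_conjunctively(self, random_corpus_factory):
        rng = np.random.default_rng(5)
        corpus = random_corpus_factory(rng, n_docs=15, vocab_size=20)
        combined = FilterConfig(min_doc_freq=2, max_doc_freq_fraction=0.8,
                                stopwords=frozenset({"w000", "w001"}))
        survivors = set(filter_vocabulary(corpus, combined))
        for single in (FilterConfig(min_doc_freq=2),
                       FilterConfig(max_doc_freq_fraction=0.8),
                       FilterConfig(stopwords=frozenset({"w000", "w001"}))):
            assert survivors <= set(filter_vocabulary(corpus, single))

    def test_background_stats_override_corpus_df(self, tiny_corpus):
        bg = background_from_corpus(tiny_corpus)
        with_bg = filter_vocabulary(tiny_corpus, FilterConfig(min_doc_freq=2, background=bg))
        without = filter_vocabulary(tiny_corpus, FilterConfig(min_doc_freq=2))
        assert with_bg == without  # background computed from the same corpus

    def test_min_token_length(self, tiny_corpus):
        vocab = filter_vocabulary(tiny_corpus, FilterConfig(min_token_length=3))
        assert "it" not in vocab


class TestBuildTdm:
    def test_direct_count(self):
        docs = [
            Document(entity_id="D0", raw_text="kinase binds kinase."),
            Document(entity_id="D1", raw_text="membrane transport."),
        ]
        corpus = Corpus(documents=docs)
        tdm = build_tdm(corpus, ["kinase"], scheme="freq")
        np.testing.assert_array_equal(tdm.weights, [[2, 0]])

    def test_tfidf_scheme_consistent_with_compute_tfidf(self, tiny_corpus):
        full = compute_tfidf(tiny_corpus)
        sub = build_tdm(tiny_corpus, ["kinase", "transport"], scheme="tfidf")
        for term in sub.terms:
            np.testing.assert_allclose(sub.row(term), full.row(term), atol=1e-15)

    def test_column_sums_equal_token_recount(self, random_corpus_factory):
        rng = np.random.default_rng(8)
        corpus = random_corpus_factory(rng, n_docs=10, vocab_size=20)
        vocab = sorted(oracles.term_counts(corpus))
        tdm = build_tdm(corpus, vocab, scheme="freq")
        for j, doc in enumerate(corpus):
            assert tdm.weights[:, j].sum() == len(doc.tokens())

    def test_absent_term_gives_zero_row(self, tiny_corpus):
        tdm = build_tdm(tiny_corpus, ["kinase", "nonexistent"], scheme="freq")
        assert np.all(tdm.row("nonexistent") == 0)

    def test_empty_vocabulary_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            build_tdm(tiny_corpus, [], scheme="freq")


class TestNgrams:
    def test_bigram_enumeration(self):
        corpus = Corpus(documents=[
            Document(entity_id="D0", raw_text="signal transduction pathway.")
        ])
        assert extract_ngrams(corpus, 2) == {
            "signal transduction": 1,
            "transduction pathway": 1,
        }

    def test_sentence_shorter_than_n_contributes_nothing(self):
        corpus = Corpus(documents=[Document(entity_id="D0", raw_text="kinase. binds substrate.")])
        grams = extract_ngrams(corpus, 3)
        assert grams == {}

    def test_never_crosses_sentence_boundaries(self):
        corpus = Corpus(documents=[Document(entity_id="D0", raw_text="alpha beta. gamma delta.")])
        assert set(extract_ngrams(corpus, 2)) == {"alpha beta", "gamma delta"}

    def test_n_below_two_rejected(self, tiny_corpus):
        with pytest.raises(ValueError):
            extract_ngrams(tiny_corpus, 1)

    def test_matches_sliding_window_oracle(self, random_corpus_factory):
        rng = np.random.default_rng(21)
        corpus = random_corpus_factory(rng, n_docs=5, vocab_size=12)
        for n in (2, 3):
            assert extract_ngrams(corpus, n) == oracles.ngram_counts(corpus, n)


def test_default_stopwords_asset_loads():
    stopwords = default_stopwords()
    assert {"the", "and", "of"} <= stopwords
    assert "kinase" not in stopwords
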