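"""Text processing: tokenization, the combinable filter stack, term-document
matrices, TF-IDF, and n-gram extraction.

The pipeline view is: free text -> sentences of normalized tokens ->
filtered vocabulary -> term-document matrix (raw counts or TF-IDF), which
downstream modules turn into word networks.

TF-IDF here is the plain unnormalized form

    w(t, d) = tf(t, d) * ln(N / df(t))

with ``tf`` the raw within-document count, ``N`` the number of documents and
``df`` the number of documents containing the term.  Terms present in every
document therefore weigh exactly zero.  The formula is deliberately the
simplest standard one so that background tables shipped alongside a corpus
can be regenerated from it.
"""

from __future__ import annotations

import math
import re
import string
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .corpus import BackgroundStats, Corpus

__all__ = [
    "FilterConfig",
    "TermDocumentMatrix",
    "tokenize",
    "default_stopwords",
    "corpus_term_counts",
    "corpus_doc_frequencies",
    "compute_tfidf",
    "filter_vocabulary",
    "build_tdm",
    "extract_ngrams",
    "background_from_corpus",
]

# Sentences end at . ! or ? followed by whitespace (or end of text).
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
_EDGE_PUNCT = string.punctuation


def tokenize(raw_text: str) -> list[list[str]]:
    """Segment text into sentences of normalized tokens.

    Sentences split on terminal punctuation ([.!?]) followed by whitespace.
    Tokens are lowercased, punctuation is stripped from token edges (internal
    hyphens survive, so biomedical compounds like "ubiquitin-protein" stay
    whole), and tokens without any alphabetic character (bare numerals,
    stranded punctuation) are dropped.  Deterministic and idempotent on its
    own output.
    """
    sentences: list[list[str]] = []
    for chunk in _SENTENCE_SPLIT.split(raw_text):
        tokens: list[str] = []
        for word in chunk.split():
            token = word.strip(_EDGE_PUNCT).lower()
            if not token or not any(c.isalpha() for c in token):
                continue
            tokens.append(token)
        if tokens:
            sentences.append(tokens)
    return sentences


def default_stopwords() -> frozenset[str]:
    """The packaged English stopword list (plain text asset, one term/line)."""
    text = resources.files("textnetsum").joinpath("data/stopwords_en.txt").read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class FilterConfig:
    """A conjunctive stack of vocabulary filters.

    A term survives only if it passes *every* enabled filter; order of
    application is immaterial.  Document-frequency and TF-IDF thresholds are
    evaluated against ``background`` when one is supplied (pre-computed
    corpus-wide statistics, e.g. over all RefSeq summaries), otherwise
    against the query corpus itself.
    """

    stopwords: frozenset[str] = frozenset()
    min_doc_freq: int = 0
    max_doc_freq_fraction: float = 1.0
    min_tfidf: float | None = None
    whitelist: frozenset[str] | None = None
    min_token_length: int = 1
    background: "BackgroundStats | None" = None
    top_k_terms: int | None = None

    def __post_init__(self) -> None:
        if self.min_doc_freq < 0:
            raise ValueError("min_doc_freq must be >= 0")
        if not (0.0 < self.max_doc_freq_fraction <= 1.0):
            raise ValueError("max_doc_freq_fraction must be in (0, 1]")
        if self.min_tfidf is not None and self.min_tfidf < 0:
            raise ValueError("min_tfidf must be non-negative")
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass
class TermDocumentMatrix:
    """Terms x documents weight matrix with a declared weighting scheme.

    ``scheme="freq"`` holds raw within-document counts (integral values);
    ``scheme="tfidf"`` holds tf*ln(N/df) weights.  Rows follow ``terms``,
    columns follow ``doc_ids`` in corpus order.
    """

    terms: list[str]
    doc_ids: list[str]
    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        if self.scheme not in ("freq", "tfidf"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.terms), len(self.doc_ids)):
            raise ValueError("weights shape does not match terms x doc_ids")
        if (self.weights < 0).any():
            raise ValueError("term-document weights must be non-negative")
        if self.scheme == "freq" and not np.allclose(self.weights, np.round(self.weights)):
            raise ValueError("freq scheme requires integral counts")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def n_documents(self) -> int:
        return len(self.doc_ids)

    def row(self, term: str) -> np.ndarray:
        return self.weights[self.terms.index(term)]


def corpus_term_counts(corpus: "Corpus") -> Counter:
    """Total occurrence count of every term across the corpus."""
    counts: Counter = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            counts.update(sentence)
    return counts


def corpus_doc_frequencies(corpus: "Corpus") -> Counter:
    """Number of documents containing each term at least once."""
    df: Counter = Counter()
    for doc in corpus:
        df.update(set(doc.tokens()))
    return df


def _ordered_terms(term_counts: Counter) -> list[str]:
    # Descending corpus frequency, lexicographic tie-break: the one ordering
    # used everywhere so top-k truncation is deterministic.
    return sorted(term_counts, key=lambda t: (-term_counts[t], t))


def build_tdm(corpus: "Corpus", vocabulary: Sequence[str], scheme: str = "freq") -> TermDocumentMatrix:
    """Build the term-document matrix restricted to ``vocabulary`` rows.

    Vocabulary terms absent from the corpus are kept as all-zero rows so
    callers can align matrices across corpora.  Under ``scheme="tfidf"`` the
    document frequencies are computed over the full corpus (not the
    restricted vocabulary), so the result equals :func:`compute_tfidf`
    restricted to the requested rows.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("vocabulary contains duplicate terms")
    n_docs = len(corpus)
    index = {t: i for i, t in enumerate(vocabulary)}
    weights = np.zeros((len(vocabulary), n_docs))
    for j, doc in enumerate(corpus):
        for term, count in doc.token_counts().items():
            i = index.get(term)
            if i is not None:
                weights[i, j] = count
    if scheme == "tfidf":
        df = corpus_doc_frequencies(corpus)
        idf = np.array([math.log(n_docs / df[t]) if df[t] else 0.0 for t in vocabulary])
        weights = weights * idf[:, None]
    return TermDocumentMatrix(list(vocabulary), list(corpus.entity_ids), weights, scheme)


def compute_tfidf(corpus: "Corpus") -> TermDocumentMatrix:
    """TF-IDF matrix over the corpus's full vocabulary (see module docstring)."""
    if len(corpus) == 0:
        raise ValueError("corpus must contain at least one document")
    counts = corpus_term_counts(corpus)
    if not counts:
        raise ValueError("corpus contains no tokens")
    return build_tdm(corpus, _ordered_terms(counts), scheme="tfidf")


def filter_vocabulary(corpus: "Corpus", config: FilterConfig) -> list[str]:
    """Apply the conjunctive filter stack; return the surviving vocabulary.

    Ordering is descending corpus frequency with lexicographic tie-break;
    ``top_k_terms`` truncates after ordering.
    """
    if config.whitelist is not None and len(config.whitelist) == 0:
        raise ValueError("whitelist is set but empty: vocabulary would always be empty")

    term_counts = corpus_term_counts(corpus)
    corpus_df = corpus_doc_frequencies(corpus)
    n_docs = len(corpus)

    bg = config.background
    use_bg_df = bg is not None and bg.doc_freq
    use_bg_tfidf = bg is not None and bg.tfidf

    corpus_max_tfidf: dict[str, float] = {}
    if config.min_tfidf is not None and not use_bg_tfidf:
        tdm = compute_tfidf(corpus)
        maxima = tdm.weights.max(axis=1)
        corpus_max_tfidf = dict(zip(tdm.terms, maxima))

    whitelist = config.whitelist
    survivors = []
    for term in term_counts:
        if len(term) < config.min_token_length:
            continue
        if term in config.stopwords:
            continue
        if whitelist is not None and term not in whitelist:
            continue
        if use_bg_df:
            df, denom = bg.doc_freq.get(term, 0), bg.n_documents
        else:
            df, denom = corpus_df[term], n_docs
        if df < config.min_doc_freq:
            continue
        if denom and df / denom > config.max_doc_freq_fraction:
            continue
        if config.min_tfidf is not None:
            score = bg.tfidf.get(term, 0.0) if use_bg_tfidf else corpus_max_tfidf.get(term, 0.0)
            if score < config.min_tfidf:
                continue
        survivors.append(term)

    survivors.sort(key=lambda t: (-term_counts[t], t))
    if config.top_k_terms is not None:
        survivors = survivors[: config.top_k_terms]
    return survivors


def extract_ngrams(corpus: "Corpus", n: int) -> dict[str, int]:
    """Count n-grams (n >= 2) within sentences, never across boundaries.

    Keys are the n tokens joined by a single space.
    """
    if n < 2:
        raise ValueError("n-gram order must be >= 2")
    counts: Counter = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            for i in range(len(sentence) - n + 1):
                counts[" ".join(sentence[i : i + n])] += 1
    return dict(counts)


def background_from_corpus(corpus: "Corpus") -> "BackgroundStats":
    """Summarize a (large, reference) corpus into reusable background stats.

    The TF-IDF score recorded per term is its maximum weight over documents,
    matching how ``filter_vocabulary`` thresholds corpus-internal TF-IDF.
    """
    from .corpus import BackgroundStats

    df = corpus_doc_frequencies(corpus)
    tdm = compute_tfidf(corpus)
    tfidf = dict(zip(tdm.terms, tdm.weights.max(axis=1)))
    return BackgroundStats(doc_freq=dict(df), tfidf=tfidf, n_documents=len(corpus))
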