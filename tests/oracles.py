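"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, explicit formulas,
exhaustive scans) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def cooccurrence_counts(corpus, vocabulary):
    """Exhaustive sentence scan: pair -> number of sentences containing both."""
    vocab = set(vocabulary)
    counts: Counter = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            present = sorted({t for t in sentence if t in vocab})
            for t, u in combinations(present, 2):
                counts[(t, u)] += 1
    return dict(counts)


def pearson(x, y):
    """Textbook Pearson correlation; None when either side has no variance."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def tfidf_weight(count, n_docs, doc_freq):
    """tf * ln(N / df) evaluated directly."""
    if doc_freq == 0:
        return 0.0
    return count * math.log(n_docs / doc_freq)


def document_frequencies(corpus):
    df: Counter = Counter()
    for doc in corpus:
        seen = set()
        for sentence in doc.sentences:
            seen.update(sentence)
        df.update(seen)
    return dict(df)


def term_counts(corpus):
    counts: Counter = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            counts.update(sentence)
    return dict(counts)


def ngram_counts(corpus, n):
    """Sliding-window enumeration within sentences."""
    counts: Counter = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            for i in range(len(sentence)):
                window = sentence[i : i + n]
                if len(window) == n:
                    counts[" ".join(window)] += 1
    return dict(counts)


def adjusted_rand_index(labels_a, labels_b):
    """ARI from the contingency table, by the closed-form comb2 formula.

    Accepts two item->label dicts over the same item set, or two aligned
    label sequences.
    """
    if isinstance(labels_a, dict):
        items = sorted(labels_a)
        assert sorted(labels_b) == items
        a = [labels_a[i] for i in items]
        b = [labels_b[i] for i in items]
    else:
        a, b = list(labels_a), list(labels_b)
    n = len(a)

    def comb2(m):
        return m * (m - 1) // 2

    contingency: Counter = Counter(zip(a, b))
    sum_cells = sum(comb2(v) for v in contingency.values())
    sum_rows = sum(comb2(v) for v in Counter(a).values())
    sum_cols = sum(comb2(v) for v in Counter(b).values())
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)
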