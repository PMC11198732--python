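"""Word networks: correlation and sentence co-occurrence graphs over terms.

Two network kinds are supported, mirroring the two standard ways of relating
words in a set of functional descriptions:

* **correlation** — edge weight is the Pearson (optionally Spearman)
  correlation between two terms' weight profiles across documents of a
  term-document matrix;
* **cooccurrence** — edge weight is the number of sentences, summed over the
  whole corpus, in which both terms appear at least once (within-sentence
  multiplicity is ignored).

In both cases pairs whose metric falls below the user threshold are dropped:
the "set weak relations to zero" rule is realized as edge *absence*, which
keeps the graph sparse with identical downstream semantics.  Terms with zero
variance across documents have undefined correlation and become isolated
nodes rather than errors, so frequency-based displays still show them.

Node clustering (community detection) delegates to networkx's
greedy-modularity or label-propagation algorithms; every node ends up with
exactly one cluster label, isolated nodes as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import TYPE_CHECKING, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .textproc import TermDocumentMatrix, corpus_term_counts

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Corpus

__all__ = ["WordNetwork", "correlation_network", "cooccurrence_network", "community_detect"]

METRICS = ("correlation", "cooccurrence")
COMMUNITY_METHODS = ("greedy_modularity", "label_propagation")


@dataclass
class WordNetwork:
    """Weighted undirected graph over terms.

    Node attributes: ``frequency`` (corpus occurrence count, or row weight
    sum for TF-IDF matrices) and ``cluster`` (label, absent until
    :func:`community_detect` runs).  Edge attribute: ``weight``.  ``meta``
    carries free-form provenance (correlation flavour, clustering seed,
    per-source thresholds after a merge ...).
    """

    graph: nx.Graph
    metric: str
    threshold: float
    sources: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    def frequency(self, term: str) -> float:
        return self.graph.nodes[term]["frequency"]

    def clusters(self) -> dict[str, int]:
        """term -> cluster label; raises if community_detect has not run."""
        labels = nx.get_node_attributes(self.graph, "cluster")
        if len(labels) != self.n_nodes:
            raise ValueError("network has no complete cluster labelling")
        return labels

    def copy(self) -> "WordNetwork":
        return WordNetwork(
            graph=self.graph.copy(),
            metric=self.metric,
            threshold=self.threshold,
            sources=list(self.sources),
            meta=dict(self.meta),
        )


def _correlation_matrix(weights: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        weights = rankdata(weights, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(weights)


def correlation_network(
    tdm: TermDocumentMatrix,
    threshold: float,
    method: str = "pearson",
) -> WordNetwork:
    """Correlation network over the rows of a term-document matrix.

    Edges keep pairs with correlation >= ``threshold``; zero-variance terms
    are isolated nodes.  Requires at least 2 documents and 2 terms.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if tdm.n_documents < 2:
        raise ValueError("correlation requires at least 2 documents")
    if tdm.n_terms < 2:
        raise ValueError("correlation network requires at least 2 terms")
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("correlation threshold must lie in [-1, 1]")

    corr = _correlation_matrix(tdm.weights, method)
    row_sums = tdm.weights.sum(axis=1)

    graph = nx.Graph()
    for i, term in enumerate(tdm.terms):
        freq = row_sums[i]
        graph.add_node(term, frequency=int(freq) if tdm.scheme == "freq" else float(freq))
    for i, j in combinations(range(tdm.n_terms), 2):
        w = corr[i, j]
        if np.isfinite(w) and w >= threshold:
            graph.add_edge(tdm.terms[i], tdm.terms[j], weight=float(np.clip(w, -1.0, 1.0)))
    return WordNetwork(
        graph=graph,
        metric="correlation",
        threshold=float(threshold),
        sources=["tdm"],
        meta={"correlation": method, "scheme": tdm.scheme},
    )


def cooccurrence_network(
    corpus: "Corpus",
    vocabulary: Sequence[str],
    threshold: int = 1,
    unit: str = "sentence",
) -> WordNetwork:
    """Sentence co-occurrence network over ``vocabulary``.

    weight(t, u) = number of sentences across the corpus containing both
    terms at least once; pairs with weight < ``threshold`` are omitted.
    ``unit="document"`` counts each document at most once per pair instead
    of each sentence, for corpora whose descriptions repeat phrases.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if threshold < 1:
        raise ValueError("co-occurrence threshold must be >= 1")
    if unit not in ("sentence", "document"):
        raise ValueError(f"unknown co-occurrence unit {unit!r}")

    vocab = set(vocabulary)
    pair_counts: dict[tuple[str, str], int] = {}
    for doc in corpus:
        doc_pairs: set[tuple[str, str]] = set()
        for sentence in doc.sentences:
            present = sorted(vocab.intersection(sentence))
            for pair in combinations(present, 2):
                if unit == "sentence":
                    pair_counts[pair] = pair_counts.get(pair, 0) + 1
                else:
                    doc_pairs.add(pair)
        for pair in doc_pairs:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1

    counts = corpus_term_counts(corpus)
    graph = nx.Graph()
    for term in vocabulary:
        graph.add_node(term, frequency=int(counts.get(term, 0)))
    for (t, u), w in pair_counts.items():
        if w >= threshold:
            graph.add_edge(t, u, weight=int(w))
    return WordNetwork(
        graph=graph,
        metric="cooccurrence",
        threshold=int(threshold),
        sources=[corpus.source],
        meta={"unit": unit},
    )


def community_detect(
    network: WordNetwork,
    method: str = "greedy_modularity",
    seed: int = 0,
) -> WordNetwork:
    """Assign one cluster label per node; returns a labelled copy.

    Negative-weight edges (possible in correlation networks with a negative
    threshold) are excluded from the modularity computation.  Labels are
    integers, numbered by decreasing community size (ties by smallest
    member), so the labelling is deterministic for a deterministic method.
    """
    if method not in COMMUNITY_METHODS:
        raise ValueError(f"unknown community detection method {method!r}")
    if network.n_nodes == 0:
        raise ValueError("cannot cluster an empty network")

    graph = network.graph
    positive = nx.Graph()
    positive.add_nodes_from(graph.nodes)
    positive.add_weighted_edges_from(
        (u, v, d["weight"]) for u, v, d in graph.edges(data=True) if d["weight"] > 0
    )

    # Cluster only the part that has edges; everything else is singletons.
    connected = [n for n in positive.nodes if positive.degree(n) > 0]
    communities: list[set[str]] = []
    if connected:
        sub = positive.subgraph(connected)
        if method == "greedy_modularity":
            communities = [set(c) for c in nx.community.greedy_modularity_communities(sub, weight="weight")]
        else:
            communities = [set(c) for c in nx.community.asyn_lpa_communities(sub, weight="weight", seed=seed)]
    communities.extend({n} for n in positive.nodes if positive.degree(n) == 0)

    communities.sort(key=lambda c: (-len(c), min(c)))
    labelled = network.copy()
    for label, members in enumerate(communities):
        for node in members:
            labelled.graph.nodes[node]["cluster"] = label
    labelled.meta.update({"cluster_method": method, "cluster_seed": seed})
    return labelled
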