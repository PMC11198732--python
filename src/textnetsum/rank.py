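"""Entity prioritization from important-word content.

Given a word network built from the descriptions of a list of biological
entities, the "important" words are the top terms by corpus frequency or by
weighted degree in the network.  Each queried entity is then scored by how
much of that important vocabulary its own description contains:

    score(e) = sum over important words w of count(w in e's tokens) * weight(w)

optionally divided by the entity's total token count (length normalization).
Every queried entity receives a score — an empty description scores 0 — so
the ranking always covers the full input list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

from .network import WordNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Corpus

__all__ = ["EntityRanking", "important_words", "score_entities"]

NORMALIZATIONS = ("none", "by_length")


@dataclass
class EntityRanking:
    """Per-entity scores plus the important-word list that produced them."""

    scores: dict[str, float]
    important_words: list[tuple[str, float]]
    normalization: str
    contributions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def ranked(self) -> list[tuple[str, float]]:
        """Entities by descending score, lexicographic tie-break."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_tsv(self, path: str | Path, top_words: int = 3) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("entity_id\tscore\ttop_words\n")
            for entity, score in self.ranked():
                contrib = self.contributions.get(entity, [])[:top_words]
                words = ",".join(w for w, _ in contrib)
                fh.write(f"{entity}\t{score:.10g}\t{words}\n")


def important_words(
    network: WordNetwork,
    k: int,
    criterion: str = "frequency",
) -> list[tuple[str, float]]:
    """Top-k terms of the network by ``frequency`` (corpus occurrence count)
    or ``degree`` (weighted degree); descending, ties lexicographic.

    The attached weight is the criterion value itself, so it can feed
    directly into :func:`score_entities`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if criterion not in ("frequency", "degree"):
        raise ValueError(f"unknown importance criterion {criterion!r}")
    if network.n_nodes == 0:
        raise ValueError("network has no nodes")

    if criterion == "frequency":
        values = {t: float(network.graph.nodes[t]["frequency"]) for t in network.graph.nodes}
    else:
        values = {t: float(network.graph.degree(t, weight="weight")) for t in network.graph.nodes}
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


def score_entities(
    corpus: "Corpus",
    important: Sequence[tuple[str, float]] | Mapping[str, float],
    normalization: str = "none",
) -> EntityRanking:
    """Score every entity by its weighted important-word content.

    ``important`` maps term -> weight (or is a (term, weight) sequence).
    ``normalization="by_length"`` divides by the entity's token count;
    entities with no tokens score 0 under either normalization.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    weights = dict(important.items()) if isinstance(important, Mapping) else dict(important)
    if not weights:
        raise ValueError("important word list must be non-empty")

    scores: dict[str, float] = {}
    contributions: dict[str, list[tuple[str, int]]] = {}
    importance = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    for doc in corpus:
        counts = doc.token_counts()
        total = sum(w * counts.get(term, 0) for term, w in weights.items())
        n_tokens = sum(counts.values())
        if normalization == "by_length":
            total = total / n_tokens if n_tokens else 0.0
        scores[doc.entity_id] = float(total)
        contributions[doc.entity_id] = [
            (term, counts[term]) for term, _ in importance if counts.get(term, 0) > 0
        ]
    return EntityRanking(
        scores=scores,
        important_words=importance,
        normalization=normalization,
        contributions=contributions,
    )
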