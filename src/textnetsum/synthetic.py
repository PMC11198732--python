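"""Synthetic entity-description corpora with planted theme structure.

Real inputs to this package are free-text functional descriptions of genes
or microbial taxa.  For testing and benchmarking without database access,
this module generates corpora in which the ground truth is known by
construction: entities belong to *themes* (stand-ins for biological
functions), each theme owns a vocabulary of marker words, and every entity's
sentences mix its theme's words with words from a shared background
vocabulary (stand-ins for generic biomedical boilerplate such as "protein"
or "encodes").

Specifically, each token of each sentence is drawn independently: with
probability ``noise_fraction`` uniformly from the background vocabulary,
otherwise uniformly from the entity's theme vocabulary.  Themes' vocabularies
are pairwise disjoint unless ``shared_theme_overlap > 0``, in which case that
fraction of every theme's vocabulary is replaced by words from a common
shared pool (emulating functions with overlapping terminology).  Sampling is
uniform — no Zipf tail — by default; a Zipf option exists for stress tests.

Generation is fully deterministic given the seed, and generated raw text
survives the package tokenizer unchanged (tokens are lowercase alphanumeric,
sentences end in "."), so every pipeline stage can be tested against the
returned ground-truth maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, Document

__all__ = ["ThemeSpec", "generate_corpus"]


@dataclass(frozen=True)
class ThemeSpec:
    """Parameters of a planted-theme corpus.

    Defaults describe a small desk-scale corpus: 3 themes of 15 marker words,
    10 entities per theme, 5 sentences of 8 words each per entity, and a 20%
    admixture of shared background words.
    """

    n_themes: int = 3
    words_per_theme: int = 15
    entities_per_theme: int = 10
    words_per_sentence: int = 8
    sentences_per_entity: int = 5
    noise_fraction: float = 0.2
    shared_theme_overlap: float = 0.0
    background_vocab_size: int = 20
    zipf_exponent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_themes < 1:
            raise ValueError("n_themes must be >= 1")
        for name in ("words_per_theme", "entities_per_theme", "words_per_sentence",
                     "sentences_per_entity", "background_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise_fraction must lie in [0, 1)")
        if not (0.0 <= self.shared_theme_overlap <= 1.0):
            raise ValueError("shared_theme_overlap must lie in [0, 1]")
        if self.words_per_theme < self.words_per_sentence * (1.0 - self.noise_fraction):
            raise ValueError(
                "infeasible spec: words_per_theme must cover the expected "
                "theme-word content of a sentence "
                f"({self.words_per_theme} < {self.words_per_sentence} * {1 - self.noise_fraction:.2f})"
            )


def _theme_vocabularies(spec: ThemeSpec) -> dict[int, list[str]]:
    n_shared = int(round(spec.shared_theme_overlap * spec.words_per_theme))
    shared = [f"shared{j:02d}" for j in range(n_shared)]
    vocabs: dict[int, list[str]] = {}
    for theme in range(spec.n_themes):
        own = [
            f"theme{theme}word{j:02d}" for j in range(n_shared, spec.words_per_theme)
        ]
        vocabs[theme] = shared + own
    return vocabs


def _sampler(rng: np.random.Generator, size: int, zipf_exponent: float | None):
    if zipf_exponent is None:
        probs = None
    else:
        ranks = np.arange(1, size + 1, dtype=float)
        probs = ranks ** (-zipf_exponent)
        probs /= probs.sum()
    def draw() -> int:
        return int(rng.choice(size, p=probs))
    return draw


def generate_corpus(spec: ThemeSpec) -> tuple[Corpus, dict[str, int], dict[int, set[str]]]:
    """Generate a planted-theme corpus.

    Returns ``(corpus, entity_theme, theme_terms)`` where ``entity_theme``
    maps each entity id to its planted theme index and ``theme_terms`` maps
    each theme to its marker-word set (ground truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    vocabs = _theme_vocabularies(spec)
    background = [f"common{j:02d}" for j in range(spec.background_vocab_size)]

    documents: list[Document] = []
    entity_theme: dict[str, int] = {}
    for theme in range(spec.n_themes):
        theme_vocab = vocabs[theme]
        draw_theme = _sampler(rng, len(theme_vocab), spec.zipf_exponent)
        draw_bg = _sampler(rng, len(background), spec.zipf_exponent)
        for e in range(spec.entities_per_theme):
            entity_id = f"ENT{theme:02d}_{e:02d}"
            sentences = []
            for _ in range(spec.sentences_per_entity):
                tokens = []
                for _ in range(spec.words_per_sentence):
                    if rng.random() < spec.noise_fraction:
                        tokens.append(background[draw_bg()])
                    else:
                        tokens.append(theme_vocab[draw_theme()])
                sentences.append(" ".join(tokens) + ".")
            documents.append(
                Document(entity_id=entity_id, raw_text=" ".join(sentences), source="synthetic")
            )
            entity_theme[entity_id] = theme

    corpus = Corpus(documents=documents, source="synthetic")
    theme_terms = {theme: set(vocab) for theme, vocab in vocabs.items()}
    return corpus, entity_theme, theme_terms
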