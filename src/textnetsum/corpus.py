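"""Entity-description corpora: the document model and its file formats.

A :class:`Corpus` is an ordered collection of :class:`Document` objects, one
per queried biological entity (gene symbol, bacterial taxon, pathway id ...),
each carrying the free-text functional description fetched for it and its
sentence-segmented, normalized tokens.  This module owns reading and writing
the on-disk formats:

* corpora as TSV (header row required) or JSON (array of objects), with
  configurable id/text column names — the seam where database fetchers
  (RefSeq summaries, curated signature databases) would plug in;
* background word-frequency / TF-IDF tables (TSV with an
  ``# n_documents=<N>`` header comment);
* vocabulary whitelists and stopword lists (one term per line, ``#``
  comments).

Files are UTF-8; undecodable bytes are an error, never silently replaced.
The corpus timestamp is provenance metadata only and never affects any
computation.
"""

from __future__ import annotations

import datetime
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .textproc import tokenize

__all__ = [
    "Document",
    "Corpus",
    "BackgroundStats",
    "read_corpus",
    "write_corpus",
    "read_background",
    "write_background",
    "read_vocabulary",
]


@dataclass(frozen=True)
class Document:
    """One entity's textual description.

    ``sentences`` is always derived from ``raw_text`` by
    :func:`textnetsum.textproc.tokenize`, so re-tokenizing reproduces it.
    """

    entity_id: str
    raw_text: str
    source: str = "manual"
    sentences: tuple[tuple[str, ...], ...] = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        sentences = tuple(tuple(s) for s in tokenize(self.raw_text))
        object.__setattr__(self, "sentences", sentences)

    def tokens(self) -> list[str]:
        """All tokens of the document in reading order."""
        return [t for sentence in self.sentences for t in sentence]

    def token_counts(self) -> Counter:
        return Counter(self.tokens())


@dataclass
class Corpus:
    """Ordered, uniquely-keyed collection of documents from one source."""

    documents: list[Document]
    source: str = "manual"
    created_at: datetime.datetime = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc),
        compare=False,
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.entity_id in seen:
                raise ValueError(f"duplicate entity_id {doc.entity_id!r} in corpus")
            seen.add(doc.entity_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def entity_ids(self) -> list[str]:
        return [doc.entity_id for doc in self.documents]

    def get(self, entity_id: str) -> Document:
        for doc in self.documents:
            if doc.entity_id == entity_id:
                return doc
        raise KeyError(entity_id)


@dataclass
class BackgroundStats:
    """Pre-computed corpus-wide term statistics used for filtering.

    Holds term -> document-frequency counts and term -> TF-IDF scores
    (either map may be empty) plus the number of documents they were
    computed over.
    """

    doc_freq: dict[str, int]
    tfidf: dict[str, float]
    n_documents: int

    def __post_init__(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be >= 0")
        for term, count in self.doc_freq.items():
            if count < 0:
                raise ValueError(f"negative document frequency for {term!r}")
            if count > self.n_documents:
                raise ValueError(
                    f"document frequency {count} of {term!r} exceeds n_documents={self.n_documents}"
                )
        for term, score in self.tfidf.items():
            if score < 0:
                raise ValueError(f"negative TF-IDF score for {term!r}")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "tsv"


def read_corpus(
    path: str | Path,
    format: str | None = None,
    id_column: str = "entity_id",
    text_column: str = "text",
    source: str | None = None,
) -> Corpus:
    """Read a corpus from TSV (header required) or JSON (array of objects).

    One document per row/record, tokenized on construction; row order is
    preserved and duplicate entity ids are rejected.  ``format`` defaults to
    the file suffix (".json" -> json, else tsv).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
        for col in (id_column, text_column):
            if col not in table.columns:
                raise ValueError(f"corpus file {path} is missing required column {col!r}")
        records = table.to_dict("records")
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise ValueError(f"corpus JSON {path} must be an array of objects")
        for i, rec in enumerate(data):
            for col in (id_column, text_column):
                if col not in rec:
                    raise ValueError(f"record {i} of {path} is missing required key {col!r}")
        records = data
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    src = source if source is not None else path.stem
    documents = [
        Document(entity_id=str(rec[id_column]), raw_text=str(rec[text_column]), source=src)
        for rec in records
    ]
    return Corpus(documents=documents, source=src)


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    format: str | None = None,
    id_column: str = "entity_id",
    text_column: str = "text",
) -> None:
    """Write a corpus; ``read_corpus`` round-trips ids, text and order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        frame = pd.DataFrame(
            {id_column: corpus.entity_ids, text_column: [d.raw_text for d in corpus]}
        )
        frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
    elif fmt == "json":
        records = [
            {id_column: d.entity_id, text_column: d.raw_text} for d in corpus
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, ensure_ascii=False, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")


def read_background(path: str | Path) -> BackgroundStats:
    """Read a background-statistics table.

    Format: TSV rows ``term<TAB>doc_freq[<TAB>tfidf]`` with a comment line
    ``# n_documents=<N>``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc_freq: dict[str, int] = {}
    tfidf: dict[str, float] = {}
    n_documents = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("n_documents="):
                    try:
                        n_documents = int(stripped.split("=", 1)[1])
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: bad n_documents header") from exc
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
            term = fields[0]
            try:
                count = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: doc frequency is not an integer") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative doc frequency for {term!r}")
            doc_freq[term] = count
            if len(fields) == 3:
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: TF-IDF score is not a number") from exc
                tfidf[term] = score
    return BackgroundStats(doc_freq=doc_freq, tfidf=tfidf, n_documents=n_documents)


def write_background(stats: BackgroundStats, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_documents={stats.n_documents}\n")
        for term in sorted(stats.doc_freq):
            if term in stats.tfidf:
                fh.write(f"{term}\t{stats.doc_freq[term]}\t{stats.tfidf[term]:.10g}\n")
            else:
                fh.write(f"{term}\t{stats.doc_freq[term]}\n")


def read_vocabulary(path: str | Path) -> set[str]:
    """Read a term list (whitelist or stopwords): one term per line,
    lowercased, ``#`` comment lines and blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    terms: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            terms.add(line.lower())
    return terms
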