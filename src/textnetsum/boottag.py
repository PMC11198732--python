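"""Bootstrap-supported hierarchical tagging of word sets.

Words are clustered hierarchically on the distance d(t, u) = 1 - r(t, u),
where r is the Pearson correlation of the two terms' profiles across
documents of a term-document matrix (average linkage by default).  The
stability of every internal node of that base dendrogram is then assessed by
a nonparametric bootstrap: documents (matrix columns) are resampled with
replacement ``n_boot`` times, the tree is rebuilt on each resample, and the
**bootstrap probability** (BP) of a cluster is the fraction of resampled
trees in which its exact leaf set reappears as a subtree.  Clusters with
BP >= ``support_threshold`` are reported as tagged word sets.

Plain BP is computed; no multiscale approximately-unbiased correction is
applied (see docs/methods.md for the rationale and consequences).  Under a
degenerate resample a term can lose all variance; its pairwise distances are
then set to the maximum (2.0) so clustering stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .textproc import TermDocumentMatrix

__all__ = ["ClusterSupport", "ClusterTagging", "bootstrap_cluster"]


@dataclass(frozen=True)
class ClusterSupport:
    """One internal node of the base dendrogram: its leaf set, merge height,
    and bootstrap probability."""

    terms: frozenset[str]
    height: float
    bootstrap_probability: float


@dataclass
class ClusterTagging:
    """Hierarchical word clusters with bootstrap support.

    ``clusters`` has one entry per internal node, in linkage-row order
    (so ``clusters[-1]`` is the root, whose BP is 1 by construction).
    """

    terms: list[str]
    linkage_matrix: np.ndarray
    clusters: list[ClusterSupport]
    n_boot: int
    seed: int
    support_threshold: float
    distance: str = "1-pearson"
    method: str = "average"

    @property
    def tagged(self) -> list[ClusterSupport]:
        """Clusters whose support reaches the threshold, largest first."""
        hits = [c for c in self.clusters if c.bootstrap_probability >= self.support_threshold]
        return sorted(hits, key=lambda c: (-len(c.terms), sorted(c.terms)))

    def support_of(self, terms: frozenset[str] | set[str]) -> float | None:
        """BP of the dendrogram node with exactly this leaf set, if any."""
        wanted = frozenset(terms)
        for c in self.clusters:
            if c.terms == wanted:
                return c.bootstrap_probability
        return None


def _correlation_distance(weights: np.ndarray) -> np.ndarray:
    """1 - Pearson distance matrix; undefined pairs (zero variance) -> 2.0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(weights)
    dist = 1.0 - corr
    dist[~np.isfinite(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, 2.0, out=dist)
    return (dist + dist.T) / 2.0


def _subtree_leafsets(Z: np.ndarray, n_leaves: int) -> list[frozenset[int]]:
    """Leaf-index set of every internal node, in linkage-row order."""
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    out: list[frozenset[int]] = []
    for k, row in enumerate(Z):
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets[n_leaves + k] = merged
        out.append(merged)
    return out


def bootstrap_cluster(
    tdm: TermDocumentMatrix,
    n_boot: int = 100,
    support_threshold: float = 0.9,
    seed: int = 0,
    method: str = "average",
) -> ClusterTagging:
    """Cluster terms hierarchically and attach bootstrap probabilities.

    Parameters
    ----------
    tdm
        Term-document matrix (>= 3 terms, >= 2 documents).
    n_boot
        Number of bootstrap resamples of the document columns (>= 1).
    support_threshold
        Minimum BP for a cluster to be reported as tagged, in [0, 1].
    seed
        Seed for the resampling RNG; identical inputs and seed give an
        identical tagging.
    method
        Linkage method passed to scipy (``average`` default, as is
        conventional for correlation-distance word clustering).
    """
    if tdm.n_terms < 3:
        raise ValueError("bootstrap clustering requires at least 3 terms")
    if tdm.n_documents < 2:
        raise ValueError("bootstrap clustering requires at least 2 documents")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0.0 <= support_threshold <= 1.0):
        raise ValueError("support_threshold must lie in [0, 1]")

    weights = tdm.weights
    n_terms, n_docs = weights.shape

    base_Z = linkage(squareform(_correlation_distance(weights), checks=False), method=method)
    base_sets = _subtree_leafsets(base_Z, n_terms)

    counts = np.zeros(len(base_sets), dtype=int)
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, n_docs, size=n_docs)
        boot_Z = linkage(
            squareform(_correlation_distance(weights[:, cols]), checks=False), method=method
        )
        boot_sets = set(_subtree_leafsets(boot_Z, n_terms))
        for i, leafset in enumerate(base_sets):
            if leafset in boot_sets:
                counts[i] += 1

    clusters = [
        ClusterSupport(
            terms=frozenset(tdm.terms[i] for i in leafset),
            height=float(base_Z[k, 2]),
            bootstrap_probability=counts[k] / n_boot,
        )
        for k, leafset in enumerate(base_sets)
    ]
    return ClusterTagging(
        terms=list(tdm.terms),
        linkage_matrix=base_Z,
        clusters=clusters,
        n_boot=n_boot,
        seed=seed,
        support_threshold=support_threshold,
        method=method,
    )
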