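"""Serialization of networks, dendrograms and word-metric data.

Supported formats:

* **GraphML** — lossless persistence of a word network (node frequency and
  cluster labels, edge weights, network-level metric/threshold/sources);
* **Cytoscape.js JSON** — the ``elements`` nodes/edges structure consumed by
  interactive browser graph viewers, with styling fields (node ``size``
  proportional to frequency, edge ``width`` proportional to weight);
* **Newick** — dendrograms from bootstrap tagging, with bootstrap
  probabilities as internal node labels (2 decimals) and branch lengths as
  merge-height differences;
* **TSV** — (term, size) wordcloud / bar-plot data and entity rankings.

All exports are deterministic byte-for-byte for fixed inputs: JSON keys are
sorted and nodes/edges are written in sorted order.  No images are rendered
here; plotting is downstream of the exported data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Union

import networkx as nx

from .boottag import ClusterTagging
from .network import WordNetwork
from .textproc import TermDocumentMatrix, corpus_term_counts

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Corpus

__all__ = [
    "to_graphml",
    "from_graphml",
    "to_cyjs",
    "to_newick",
    "wordcloud_data",
    "write_wordcloud_tsv",
    "annotate_cluster_graph",
]


def _ordered_graph(network: WordNetwork) -> nx.Graph:
    """Copy with nodes and edges in sorted order, for stable serialization."""
    out = nx.Graph()
    for node in sorted(network.graph.nodes):
        out.add_node(node, **network.graph.nodes[node])
    for u, v, data in sorted(
        ((min(u, v), max(u, v), d) for u, v, d in network.graph.edges(data=True))
    ):
        out.add_edge(u, v, **data)
    return out


def to_graphml(network: WordNetwork, path: str | Path) -> None:
    """Write a network as GraphML; :func:`from_graphml` round-trips it."""
    graph = _ordered_graph(network)
    graph.graph["metric"] = network.metric
    graph.graph["threshold"] = float(network.threshold)
    graph.graph["sources"] = ";".join(network.sources)
    if network.meta:
        graph.graph["meta"] = json.dumps(network.meta, sort_keys=True)
    nx.write_graphml(graph, str(path))


def from_graphml(path: str | Path) -> WordNetwork:
    """Read a network previously written by :func:`to_graphml`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    graph = nx.read_graphml(str(path))
    graph = nx.Graph(graph)  # drop graphml id bookkeeping, keep attributes
    metric = graph.graph.pop("metric", "correlation")
    threshold = graph.graph.pop("threshold", 0.0)
    sources = [s for s in graph.graph.pop("sources", "").split(";") if s]
    meta = json.loads(graph.graph.pop("meta", "{}"))
    for _, data in graph.nodes(data=True):
        if "frequency" in data:
            freq = data["frequency"]
            data["frequency"] = int(freq) if float(freq).is_integer() else float(freq)
        if "cluster" in data:
            data["cluster"] = int(data["cluster"])
    if metric == "cooccurrence":
        for _, _, data in graph.edges(data=True):
            w = data.get("weight")
            if w is not None and float(w).is_integer():
                data["weight"] = int(w)
        if float(threshold).is_integer():
            threshold = int(threshold)
    return WordNetwork(graph=graph, metric=metric, threshold=threshold, sources=sources, meta=meta)


def _dump_json(obj: dict, path: str | Path | None) -> dict:
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, sort_keys=True, indent=1)
            fh.write("\n")
    return obj


def to_cyjs(network: WordNetwork, path: str | Path | None = None) -> dict:
    """Cytoscape.js ``elements`` JSON with size/width styling fields.

    Node ``size`` scales linearly with frequency into [10, 50] px; edge
    ``width`` scales with |weight| into [1, 10] px.
    """
    graph = _ordered_graph(network)
    freqs = [float(d.get("frequency", 0)) for _, d in graph.nodes(data=True)]
    max_freq = max(freqs, default=0.0) or 1.0
    weights = [abs(float(d["weight"])) for _, _, d in graph.edges(data=True)]
    max_w = max(weights, default=0.0) or 1.0

    nodes = []
    for term, data in graph.nodes(data=True):
        freq = float(data.get("frequency", 0))
        node_data = {
            "id": term,
            "frequency": data.get("frequency", 0),
            "size": round(10 + 40 * freq / max_freq, 3),
        }
        if "cluster" in data:
            node_data["cluster"] = data["cluster"]
        nodes.append({"data": node_data})
    edges = []
    for u, v, data in graph.edges(data=True):
        w = data["weight"]
        edge_data = {
            "source": u,
            "target": v,
            "weight": w,
            "width": round(1 + 9 * abs(float(w)) / max_w, 3),
        }
        if "sources" in data:
            edge_data["sources"] = data["sources"]
        edges.append({"data": edge_data})

    obj = {
        "elements": {"nodes": nodes, "edges": edges},
        "data": {
            "metric": network.metric,
            "threshold": network.threshold,
            "sources": list(network.sources),
        },
    }
    return _dump_json(obj, path)


def to_newick(tagging: ClusterTagging, path: str | Path | None = None) -> str:
    """Serialize a tagging's dendrogram as Newick.

    Internal node labels are bootstrap probabilities at 2 decimals; branch
    lengths are differences of merge heights (leaves sit at height 0).
    """
    Z = tagging.linkage_matrix
    n = len(tagging.terms)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_height: float | None) -> str:
        if node < n:
            body = tagging.terms[node]
        else:
            k = node - n
            left = render(int(Z[k, 0]), height(node))
            right = render(int(Z[k, 1]), height(node))
            body = f"({left},{right}){tagging.clusters[k].bootstrap_probability:.2f}"
        if parent_height is None:
            return body
        length = max(parent_height - height(node), 0.0)
        return f"{body}:{length:.6g}"

    if n == 1:
        newick = f"{tagging.terms[0]};"
    else:
        newick = render(n + len(Z) - 1, None) + ";"
    if path is not None:
        Path(path).write_text(newick + "\n", encoding="utf-8")
    return newick


def wordcloud_data(
    source: Union[WordNetwork, TermDocumentMatrix, "Corpus"],
    k: int,
    metric: str = "frequency",
) -> list[tuple[str, float]]:
    """Top-k (term, size) pairs for wordclouds and bar plots.

    ``metric="frequency"`` sizes by corpus occurrence count (node attribute,
    matrix row sum, or token count, depending on the source object);
    ``metric="degree"`` (networks only) sizes by weighted degree.  Descending
    by size with lexicographic tie-break, same rule as important-word
    ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(source, WordNetwork):
        if metric == "degree":
            values = {t: float(source.graph.degree(t, weight="weight")) for t in source.graph.nodes}
        elif metric == "frequency":
            values = {t: float(d["frequency"]) for t, d in source.graph.nodes(data=True)}
        else:
            raise ValueError(f"unknown wordcloud metric {metric!r}")
    elif isinstance(source, TermDocumentMatrix):
        if metric != "frequency":
            raise ValueError("term-document matrices support only the frequency metric")
        sums = source.weights.sum(axis=1)
        values = dict(zip(source.terms, (float(s) for s in sums)))
    else:  # Corpus
        if metric != "frequency":
            raise ValueError("corpora support only the frequency metric")
        values = {t: float(c) for t, c in corpus_term_counts(source).items()}
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


def write_wordcloud_tsv(data: list[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tsize\n")
        for term, size in data:
            fh.write(f"{term}\t{size:.10g}\n")


def annotate_cluster_graph(
    cluster_graph: nx.Graph,
    cluster_corpora: dict,
    k: int,
    path: str | Path | None = None,
) -> dict:
    """Annotate an externally supplied cluster graph with wordcloud data.

    ``cluster_graph`` is any graph whose nodes are cluster identifiers (gene
    co-expression modules, taxa groups ...); ``cluster_corpora`` maps each
    node to the Corpus of its members' descriptions.  Each output node
    carries the cluster's top-k (term, size) list; edge attributes pass
    through unchanged.  Returns Cytoscape.js-style JSON.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for node in cluster_graph.nodes:
        if node not in cluster_corpora:
            raise ValueError(f"no corpus supplied for cluster {node!r}")

    nodes = []
    for node in sorted(cluster_graph.nodes, key=str):
        corpus = cluster_corpora[node]
        cloud = wordcloud_data(corpus, k)
        data = {"id": str(node), "n_entities": len(corpus), "wordcloud": [[t, s] for t, s in cloud]}
        for key, value in sorted(cluster_graph.nodes[node].items()):
            data.setdefault(key, value)
        nodes.append({"data": data})
    edges = []
    for u, v, attrs in sorted(
        ((min(str(u), str(v)), max(str(u), str(v)), d) for u, v, d in cluster_graph.edges(data=True))
    ):
        data = {"source": u, "target": v}
        data.update(sorted(attrs.items()))
        edges.append({"data": data})
    return _dump_json({"elements": {"nodes": nodes, "edges": edges}}, path)
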