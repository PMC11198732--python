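"""Merging and comparing word networks across text sources.

Descriptions of the same entity list fetched from different sources (curated
gene summaries, enrichment-result descriptions, literature text ...) yield
one word network each.  These are combined by set union or intersection of
their node and edge sets; edge weights are merged by an explicit rule
(max / mean / min) because set semantics alone do not determine them.  The
defaults — max for union, min for intersection — make a union never lose a
strong relation and an intersection conservative.  Each merged edge carries
a ``sources`` provenance attribute listing the contributing networks.

Node frequencies are summed across the sources containing the node: the
corpora behind different sources are disjoint text, so counts add.
"""

from __future__ import annotations

from statistics import mean
from typing import Sequence

import networkx as nx

from .network import WordNetwork

__all__ = ["merge_networks", "compare_networks"]

_WEIGHT_RULES = {"max": max, "min": min, "mean": mean}


def _check_same_metric(networks: Sequence[WordNetwork]) -> str:
    metrics = {n.metric for n in networks}
    if len(metrics) != 1:
        raise ValueError(
            f"cannot combine networks of different metric kinds: {sorted(metrics)}"
        )
    return metrics.pop()


def merge_networks(
    networks: Sequence[WordNetwork],
    mode: str = "union",
    weight_rule: str | None = None,
) -> WordNetwork:
    """Merge >= 2 networks of the same metric kind by union or intersection.

    ``weight_rule`` defaults to ``max`` for union and ``min`` for
    intersection.  The merged network records each input's threshold in
    ``meta["per_source_thresholds"]`` and tags every edge with the set of
    contributing sources.
    """
    if len(networks) < 2:
        raise ValueError("merge requires at least 2 networks")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    metric = _check_same_metric(networks)
    if weight_rule is None:
        weight_rule = "max" if mode == "union" else "min"
    if weight_rule not in _WEIGHT_RULES:
        raise ValueError(f"unknown weight rule {weight_rule!r}")
    rule = _WEIGHT_RULES[weight_rule]

    def tag(i: int, net: WordNetwork) -> str:
        return net.sources[0] if len(net.sources) == 1 else f"network{i}"

    tags = [tag(i, n) for i, n in enumerate(networks)]

    node_sets = [set(n.graph.nodes) for n in networks]
    edge_maps = [
        {(min(u, v), max(u, v)): d["weight"] for u, v, d in n.graph.edges(data=True)}
        for n in networks
    ]
    if mode == "union":
        nodes = set.union(*node_sets)
        edges = set().union(*(m.keys() for m in edge_maps))
    else:
        nodes = set.intersection(*node_sets)
        edges = set.intersection(*(set(m.keys()) for m in edge_maps))

    graph = nx.Graph()
    for node in sorted(nodes):
        freq = sum(
            n.graph.nodes[node].get("frequency", 0) for n in networks if node in n.graph
        )
        graph.add_node(node, frequency=freq)
    for pair in sorted(edges):
        weights = [m[pair] for m in edge_maps if pair in m]
        contributing = sorted(t for t, m in zip(tags, edge_maps) if pair in m)
        graph.add_edge(*pair, weight=rule(weights), sources=";".join(contributing))

    thresholds = {t: n.threshold for t, n in zip(tags, networks)}
    merged_threshold = min(thresholds.values()) if mode == "union" else max(thresholds.values())
    return WordNetwork(
        graph=graph,
        metric=metric,
        threshold=merged_threshold,
        sources=sorted(set(tags)),
        meta={"merge_mode": mode, "weight_rule": weight_rule, "per_source_thresholds": thresholds},
    )


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0  # two empty sets are identical
    return len(a & b) / len(a | b)


def compare_networks(a: WordNetwork, b: WordNetwork) -> dict:
    """Overlap report between two networks of the same metric kind.

    Returns shared node/edge counts and Jaccard indices of the node and edge
    sets (an edge is an unordered term pair; weights are not compared).
    """
    _check_same_metric([a, b])
    nodes_a, nodes_b = set(a.graph.nodes), set(b.graph.nodes)
    edges_a = {(min(u, v), max(u, v)) for u, v in a.graph.edges}
    edges_b = {(min(u, v), max(u, v)) for u, v in b.graph.edges}
    return {
        "metric": a.metric,
        "n_nodes_a": len(nodes_a),
        "n_nodes_b": len(nodes_b),
        "n_edges_a": len(edges_a),
        "n_edges_b": len(edges_b),
        "shared_nodes": len(nodes_a & nodes_b),
        "shared_edges": len(edges_a & edges_b),
        "node_jaccard": _jaccard(nodes_a, nodes_b),
        "edge_jaccard": _jaccard(edges_a, edges_b),
    }
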