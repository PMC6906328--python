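"""Pathway-interaction (crosstalk) network and centrality selection.

Nodes are the selected activated pathways; two pathways are connected when
they cross-talk, measured as the number of genes they share plus the
number of PPI edges bridging their exclusive member sets. Closeness
centrality (Wasserman–Faust component-aware normalization, so values stay
comparable when the graph is disconnected) and degree are computed per
node, and pathways exceeding *both* network-wide averages — strictly — are
selected as central.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .data import PathwayDB, logger
from .enrichment import GLPAPSet


def crosstalk_weight(
    genes_p: frozenset[str] | set[str],
    genes_q: frozenset[str] | set[str],
    ppi: nx.Graph,
) -> int:
    """Shared genes plus PPI edges with one endpoint in P∖Q and one in Q∖P."""
    shared = len(genes_p & genes_q)
    only_p = genes_p - genes_q
    only_q = genes_q - genes_p
    bridges = 0
    # iterate the smaller exclusive side's adjacency
    if len(only_p) > len(only_q):
        only_p, only_q = only_q, only_p
    for u in only_p:
        if u not in ppi:
            continue
        for v in ppi.neighbors(u):
            if v in only_q:
                bridges += 1
    return shared + bridges


def build_pathway_graph(
    glpaps: GLPAPSet,
    db: PathwayDB,
    ppi: nx.Graph,
    min_crosstalk: int = 1,
) -> nx.Graph:
    """Build the crosstalk graph over the selected pathways.

    An edge joins P and Q when their crosstalk weight reaches
    ``min_crosstalk``; pathways left without any edge are omitted from the
    graph. Node attributes carry pathway name and category; edge attribute
    ``weight`` carries the crosstalk count.
    """
    if min_crosstalk < 1:
        raise ValueError("min_crosstalk must be >= 1")
    unknown = set(glpaps.pathway_ids) - set(db.ids)
    if unknown:
        raise ValueError(f"GLPAP ids not in pathway database: {sorted(unknown)[:5]}")
    if not glpaps.pathway_ids:
        logger.warning("empty GLPAP set: pathway graph is empty")
        return nx.Graph()

    # membership index: gene -> pathway ids, to count bridging edges in one
    # pass over the PPI edge list
    ids = sorted(glpaps.pathway_ids)
    genes = {pid: set(db[pid].genes) for pid in ids}
    membership: dict[str, list[str]] = {}
    for pid in ids:
        for g in genes[pid]:
            membership.setdefault(g, []).append(pid)

    weights: dict[tuple[str, str], int] = {}
    for p, q in combinations(ids, 2):
        shared = len(genes[p] & genes[q])
        if shared:
            weights[(p, q)] = shared
    for u, v in ppi.edges:
        for p in membership.get(u, ()):
            for q in membership.get(v, ()):
                if p == q:
                    continue
                if u in genes[q] or v in genes[p]:
                    continue  # endpoint not exclusive to its side
                key = (p, q) if p < q else (q, p)
                weights[key] = weights.get(key, 0) + 1

    graph = nx.Graph()
    for (p, q), w in weights.items():
        if w >= min_crosstalk:
            graph.add_edge(p, q, weight=w)
    for pid in graph.nodes:
        graph.nodes[pid]["name"] = db[pid].name
        graph.nodes[pid]["category"] = db[pid].category
    return graph


def closeness_centrality(graph: nx.Graph, node=None):
    """Wasserman–Faust closeness: ((r−1)/(n−1)) · ((r−1)/Σd) with r the
    number of nodes reachable from the node (itself included); reduces to
    (n−1)/Σd on a connected graph."""
    if node is not None and node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    values = nx.closeness_centrality(graph, wf_improved=True)
    return values if node is None else values[node]


@dataclass(frozen=True)
class CentralPathwaySelection:
    """Above-average selection: nodes strictly exceeding both cutoffs."""

    cutoff_closeness: float
    cutoff_degree: float
    selected: tuple[str, ...]
    closeness: dict[str, float]
    degree: dict[str, int]


def apply_centrality_cutoffs(
    closeness: Mapping[str, float],
    degree: Mapping[str, float],
    cutoff_closeness: float,
    cutoff_degree: float,
    restrict_to_ids: Iterable[str] | None = None,
) -> list[str]:
    """Nodes with closeness > cutoff AND degree > cutoff, sorted by id.

    ``restrict_to_ids`` limits which nodes are eligible for selection; the
    cutoffs themselves are taken as given.
    """
    eligible = set(closeness) if restrict_to_ids is None else set(restrict_to_ids) & set(closeness)
    return sorted(
        n
        for n in eligible
        if closeness[n] > cutoff_closeness and degree[n] > cutoff_degree
    )


def select_central_pathways(
    graph: nx.Graph, restrict_to: str | None = None
) -> CentralPathwaySelection:
    """Select pathways exceeding the network-average closeness and degree.

    Cutoffs are the arithmetic means over *all* nodes in the graph;
    ``restrict_to`` optionally limits the selection (not the cutoffs) to
    one pathway category.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot select central pathways from an empty graph")
    closeness = closeness_centrality(graph)
    degree = dict(graph.degree)
    cutoff_closeness = sum(closeness.values()) / len(closeness)
    cutoff_degree = sum(degree.values()) / len(degree)
    if restrict_to is None:
        restrict_ids = None
    else:
        restrict_ids = [
            n for n, data in graph.nodes(data=True) if data.get("category") == restrict_to
        ]
    selected = apply_centrality_cutoffs(
        closeness, degree, cutoff_closeness, cutoff_degree, restrict_ids
    )
    return CentralPathwaySelection(
        cutoff_closeness=cutoff_closeness,
        cutoff_degree=cutoff_degree,
        selected=tuple(selected),
        closeness={n: float(v) for n, v in closeness.items()},
        degree={n: int(v) for n, v in degree.items()},
    )


def write_graph_tsv(graph: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    """Edge table (pathway_a, pathway_b, weight) and node-metric table."""
    edge_rows = [
        {"pathway_a": a, "pathway_b": b, "weight": d["weight"]}
        for a, b, d in sorted(
            ((min(a, b), max(a, b), d) for a, b, d in graph.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        )
    ]
    pd.DataFrame(edge_rows, columns=["pathway_a", "pathway_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    closeness = closeness_centrality(graph) if graph.number_of_nodes() else {}
    node_rows = [
        {
            "pathway_id": n,
            "name": graph.nodes[n].get("name", ""),
            "category": graph.nodes[n].get("category", ""),
            "closeness": closeness[n],
            "degree": graph.degree[n],
        }
        for n in sorted(graph.nodes)
    ]
    pd.DataFrame(
        node_rows, columns=["pathway_id", "name", "category", "closeness", "degree"]
    ).to_csv(nodes_path, sep="\t", index=False, float_format="%.10g")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export for network viewers (e.g. Cytoscape)."""
    nx.write_graphml(graph, path)
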