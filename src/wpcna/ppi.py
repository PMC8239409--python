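"""Protein-protein interaction network on a query set: induced subgraph
("non-adding": no neighbor expansion), orphan removal, degrees, hub calling
and disease flagging."""

from __future__ import annotations

import networkx as nx


def build_induced_network(edges: list[tuple[str, str]], query: set[str]) -> nx.Graph:
    """Undirected simple graph on ``query``: only edges with both endpoints
    in the query survive; self-loops and duplicates are dropped.  Query
    proteins without any surviving edge remain as isolated nodes."""
    if not query:
        raise ValueError("query set is empty")
    g = nx.Graph()
    g.add_nodes_from(sorted(query))
    for a, b in edges:
        if a == b:
            continue
        if a in query and b in query:
            g.add_edge(a, b)
    return g


def remove_orphans(graph: nx.Graph) -> tuple[nx.Graph, int]:
    """Drop degree-0 nodes; returns (graph, number removed)."""
    orphans = [v for v, d in graph.degree() if d == 0]
    out = graph.copy()
    out.remove_nodes_from(orphans)
    return out, len(orphans)


def find_hubs(graph: nx.Graph, hub_min_degree: int = 30) -> list[str]:
    """Nodes with degree >= ``hub_min_degree`` (unique neighbors), sorted by
    degree descending then name."""
    hubs = [(d, v) for v, d in graph.degree() if d >= hub_min_degree]
    hubs.sort(key=lambda t: (-t[0], t[1]))
    return [v for _, v in hubs]


def flag_disease_nodes(graph: nx.Graph, disease_set: set[str]) -> nx.Graph:
    """Set a boolean ``disease`` attribute per node and store the flagged
    percentage (2 decimals, over current nodes) as a graph attribute."""
    for v in graph.nodes:
        graph.nodes[v]["disease"] = v in disease_set
    n = graph.number_of_nodes()
    flagged = sum(1 for v in graph.nodes if graph.nodes[v]["disease"])
    graph.graph["disease_pct"] = round(100.0 * flagged / n, 2) if n else None
    graph.graph["n_disease"] = flagged
    return graph


def disease_percentage(query: set[str], disease_set: set[str], decimals: int = 2) -> float | None:
    """Disease percentage over a protein set (the query-set convention)."""
    if not query:
        return None
    return round(100.0 * len(query & disease_set) / len(query), decimals)


def node_table(graph: nx.Graph, hubs: list[str] | None = None):
    import pandas as pd

    hubs = set(hubs or [])
    rows = [
        (
            v,
            d,
            v in hubs,
            bool(graph.nodes[v].get("disease", False)),
        )
        for v, d in sorted(graph.degree(), key=lambda t: (-t[1], t[0]))
    ]
    return pd.DataFrame(rows, columns=["accession", "degree", "hub", "disease_flag"])
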