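"""Graph aggregation of seriation solutions and the minmax reduction.

Each solution is a path graph over its assemblages. The aggregate graph is
the union of those paths: an edge exists iff some solution places its two
endpoints adjacently, weighted by the frequency distance between them and
annotated with the solutions that contributed it. The minmax graph reduces
the aggregate to the fewest, smallest-weight edges that connect every
participating assemblage — a Kruskal-style scan that additionally retains
equal-weight ties competitive at the moment a vertex first joined. Branches
of the minmax graph are hypotheses about the structure of transmission.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np

from .search import SolutionSet
from .types import FrequencyMatrix

#: Weight tolerance within which two edge weights count as tied.
TIE_TOL = 1e-12

EDGE_METRICS = ("euclidean", "summed_l1")


def edge_weight(
    a: str,
    b: str,
    freqs: FrequencyMatrix,
    metric: str = "euclidean",
) -> float:
    """Frequency distance between two assemblages.

    ``euclidean``: sqrt of summed squared per-type differences (default);
    ``summed_l1``: summed absolute differences. Symmetric, non-negative.
    """
    if a == b:
        raise ValueError("edge weight requires two distinct assemblages")
    if metric not in EDGE_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    d = freqs.row(a) - freqs.row(b)
    if metric == "euclidean":
        return float(np.sqrt(np.sum(d * d)))
    return float(np.sum(np.abs(d)))


def aggregate(
    solutions: SolutionSet,
    freqs: FrequencyMatrix,
    metric: str = "euclidean",
) -> nx.Graph:
    """Union of the path graphs of all solutions.

    Vertices are every assemblage appearing in any solution; an edge
    exists iff at least one solution places its endpoints adjacently. Edge
    attributes: ``weight`` (frequency distance) and ``solutions`` (sorted
    indices of the contributing members of the atlas).
    """
    g = nx.Graph()
    g.graph["metric"] = metric
    if len(solutions) == 0:
        import warnings

        warnings.warn("aggregating an empty solution set yields an empty graph")
        return g
    for v in solutions.member_ids():
        g.add_node(v)
    for si, order in enumerate(solutions.orders):
        for a, b in zip(order, order[1:]):
            if g.has_edge(a, b):
                g.edges[a, b]["solutions"].append(si)
            else:
                g.add_edge(
                    a, b,
                    weight=edge_weight(a, b, freqs, metric),
                    solutions=[si],
                )
    for _, _, data in g.edges(data=True):
        data["solutions"] = sorted(set(data["solutions"]))
    return g


def minmax(agg: nx.Graph, keep_all_ties: bool = False) -> nx.Graph:
    """Reduce an aggregate graph to its minmax form.

    Edges are scanned in ascending (weight, endpoints) order. An edge is
    accepted when it joins two previously disconnected components
    (Kruskal); within a group of tied weights (within ``TIE_TOL``), edges
    that touch a vertex first connected at that weight are retained as
    well, so equally good alternatives stay visible. With
    ``keep_all_ties`` every edge whose weight ties an accepted edge of the
    same group is kept, even between already-connected vertices.

    Disconnected aggregates yield one spanning structure per component.
    """
    g = nx.Graph()
    g.graph.update(agg.graph)
    for v in agg.nodes:
        g.add_node(v)
    edges = sorted(
        agg.edges(data=True),
        key=lambda e: (e[2]["weight"], min(e[0], e[1]), max(e[0], e[1])),
    )
    parent = {v: v for v in agg.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    connected: set[str] = set()  # vertices with degree >= 1 in the result
    i = 0
    while i < len(edges):
        # group edges of (numerically) equal weight
        w0 = edges[i][2]["weight"]
        group = [edges[i]]
        j = i + 1
        while j < len(edges) and abs(edges[j][2]["weight"] - w0) <= TIE_TOL:
            group.append(edges[j])
            j += 1
        i = j
        accepted = []
        newly_connected: set[str] = set()
        for u, v, data in group:
            if find(u) != find(v):
                parent[find(u)] = find(v)
                accepted.append((u, v, data))
                for x in (u, v):
                    if x not in connected:
                        newly_connected.add(x)
                        connected.add(x)
        if accepted:
            for u, v, data in group:
                if g.has_edge(u, v) or (u, v, data) in accepted:
                    continue
                if keep_all_ties or u in newly_connected or v in newly_connected:
                    accepted.append((u, v, data))
        for u, v, data in accepted:
            g.add_edge(u, v, **data, tie=False)
    # mark tie edges: those not needed for spanning (cycle edges)
    skeleton = minimum_spanning_weight_edges(agg)
    skel_set = {frozenset(e[:2]) for e in skeleton}
    for u, v in g.edges:
        g.edges[u, v]["tie"] = frozenset((u, v)) not in skel_set
    return g


def minimum_spanning_weight_edges(agg: nx.Graph) -> list[tuple[str, str, float]]:
    """Deterministic minimum spanning forest of the aggregate (ties broken
    lexicographically), used as the non-tie skeleton reference."""
    edges = sorted(
        agg.edges(data=True),
        key=lambda e: (e[2]["weight"], min(e[0], e[1]), max(e[0], e[1])),
    )
    parent = {v: v for v in agg.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    out = []
    for u, v, data in edges:
        if find(u) != find(v):
            parent[find(u)] = find(v)
            out.append((u, v, data["weight"]))
    return out


def spanning_weight(g: nx.Graph) -> float:
    """Total weight of a deterministic minimum spanning forest of ``g``."""
    return float(sum(w for _, _, w in minimum_spanning_weight_edges(g)))


def branches(mm: nx.Graph) -> list[list[str]]:
    """Descriptive branch listing: connected vertex groups remaining after
    removing hub vertices (degree >= 3). Hubs are assemblages shared by
    several orderings; the remaining subtrees are the candidate lineages."""
    hubs = [v for v in mm.nodes if mm.degree(v) >= 3]
    pruned = mm.copy()
    pruned.remove_nodes_from(hubs)
    return sorted(sorted(c) for c in nx.connected_components(pruned))


# ---------------------------------------------------------------------------
# Writers


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; list attributes are flattened to comma-joined
    strings so the output is valid and byte-stable."""
    h = nx.Graph()
    h.graph.update({k: str(v) for k, v in g.graph.items()})
    for v in sorted(g.nodes):
        h.add_node(v)
    for u, v in sorted(g.edges, key=lambda e: (min(e), max(e))):
        data = g.edges[u, v]
        attrs = {}
        for k, val in data.items():
            if isinstance(val, (list, tuple, set)):
                attrs[k] = ",".join(str(x) for x in sorted(val))
            elif isinstance(val, bool):
                attrs[k] = val
            elif isinstance(val, float):
                attrs[k] = round(val, 12)
            else:
                attrs[k] = val
        h.add_edge(u, v, **attrs)
    nx.write_graphml(h, str(path))


def write_dot(g: nx.Graph, path: str | Path, name: str = "G") -> None:
    """Minimal DOT export suitable for direct rendering with graphviz."""

    def q(s: str) -> str:
        return '"' + str(s).replace('"', r"\"") + '"'

    lines = [f"graph {q(name)} {{"]
    for v in sorted(g.nodes):
        lines.append(f"  {q(v)};")
    for u, v in sorted(g.edges, key=lambda e: (min(e), max(e))):
        data = g.edges[u, v]
        w = data.get("weight", 0.0)
        nsol = len(data.get("solutions", []))
        style = ' style="dashed"' if data.get("tie") else ""
        lines.append(
            f"  {q(min(u, v))} -- {q(max(u, v))} "
            f'[label="{w:.4f}" weight={w:.6f} provenance={nsol}{style}];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
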