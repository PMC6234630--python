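"""Independent brute-force oracles used by the test suite.

The Weisfeiler-Lehman kernel oracle enumerates rooted unordered subtrees
explicitly (canonical nested tuples, no interning, no iterative relabeling)
and counts matching vertex- and edge-rooted subtrees per depth.  It is
deliberately a different algorithm from the production kernel: the
production code relabels iteratively with a shared label dictionary, the
oracle recurses over the graph structure.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx


def _adjacency(g: nx.MultiDiGraph):
    node_label = {v: str(data.get("label", v)) for v, data in g.nodes(data=True)}
    out = {v: [] for v in g.nodes}
    for u, v, data in g.edges(data=True):
        out[u].append((str(data.get("label", "")), v))
    for v in out:
        out[v].sort()
    return node_label, out


def _depth_restricted(g: nx.MultiDiGraph, d: int):
    """Nodes and out-adjacency of the subgraph within d hops of the root."""
    node_label, out = _adjacency(g)
    root = g.graph["root"]
    depth = {root: 0}
    frontier = [root]
    kept_edges = {v: [] for v in g.nodes}
    for level in range(d):
        nxt = []
        for u in frontier:
            for lab, v in out[u]:
                kept_edges[u].append((lab, v))
                if v not in depth:
                    depth[v] = level + 1
                    nxt.append(v)
        frontier = nxt
    nodes = set(depth)
    return node_label, {v: kept_edges[v] for v in nodes}, nodes


def _vertex_subtree(v, t, node_label, out, memo):
    """Canonical form of the unordered rooted out-subtree of depth t at v."""
    key = (v, t)
    if key not in memo:
        if t == 0:
            memo[key] = ("V", node_label[v])
        else:
            children = tuple(
                sorted(
                    ("E", lab, _vertex_subtree(w, t - 1, node_label, out, memo))
                    for lab, w in out.get(v, [])
                )
            )
            memo[key] = ("V", node_label[v], children)
    return memo[key]


def _shape_counts(g: nx.MultiDiGraph, d: int, h: int) -> list[Counter]:
    """Per-depth counters of vertex- and edge-rooted subtree shapes.

    Depth-t vertex shapes are full unordered subtrees of depth t; depth-t
    edge shapes pair the edge label with the depth-(t-1) subtree below it
    (just the edge label at t = 0).
    """
    node_label, out, nodes = _depth_restricted(g, d)
    memo: dict = {}
    counters = []
    for t in range(h + 1):
        c: Counter = Counter()
        for v in nodes:
            c[_vertex_subtree(v, t, node_label, out, memo)] += 1
        for v in nodes:
            for lab, w in out.get(v, []):
                if t == 0:
                    c[("E", lab)] += 1
                else:
                    c[("E", lab, _vertex_subtree(w, t - 1, node_label, out, memo))] += 1
        counters.append(c)
    return counters


def brute_force_wl_kernel(
    g1: nx.MultiDiGraph, g2: nx.MultiDiGraph, d: int, h: int, normalize: bool = False
) -> float:
    """Subtree-counting kernel: sum over depths of matched-shape products."""
    c1, c2 = _shape_counts(g1, d, h), _shape_counts(g2, d, h)

    def dot(a, b):
        return float(sum(n * b.get(shape, 0) for shape, n in a.items()))

    k12 = sum(dot(a, b) for a, b in zip(c1, c2))
    if not normalize:
        return k12
    k11 = sum(dot(a, a) for a in c1)
    k22 = sum(dot(a, a) for a in c2)
    if k11 == 0 or k22 == 0:
        return 0.0
    return k12 / (k11 * k22) ** 0.5


def knowledge_graph_to_nx(kg) -> nx.MultiDiGraph:
    """Convert a package KnowledgeGraph to the oracle's input format."""
    g = nx.MultiDiGraph(root=kg.root)
    for s, p, o in sorted(kg.triples):
        for node in (s, o):
            if node not in g:
                g.add_node(node, label=node)
        g.add_edge(s, o, label=p)
    if kg.root in g:
        g.nodes[kg.root]["label"] = "root"
    return g
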