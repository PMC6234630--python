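"""Similarity features between patient samples and diagnosis concepts.

Two families of engineered features, both expressing "how much does this
patient look like the concept of each diagnosis":

* a fast Weisfeiler-Lehman (WL) subtree kernel for directed, edge-labeled
  knowledge graphs: iterative relabeling of vertices *and* edges counts the
  matching rooted subtrees of increasing depth between a patient's graph and
  each class-concept graph.  This route is purely knowledge-driven -- it
  needs no labeled training sample, which makes minimum-distance prediction
  on these similarities a cold-start classifier;
* data-driven RBF / cosine similarities between a sample's numeric encoding
  and per-class centroid or medoid vectors.

Label-information (typing) triples must be removed from sample graphs before
kernel computation; class-concept graphs never contain them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._encoding import NumericEncoder
from .codec import LabeledDataset, encode_sample, strip_typing
from .kb import KnowledgeBase, KnowledgeGraph, concept_graph

logger = logging.getLogger(__name__)


@dataclass
class WFConfig:
    """Weisfeiler-Lehman kernel configuration.

    ``d`` is the depth of the rooted subgraph extracted around each graph's
    root; ``h`` the number of relabeling iterations (h = 0 reduces the
    kernel to a dot product of raw label counts).  Concept graphs here are
    depth-2 stars, hence the small defaults.
    """

    d: int = 2
    h: int = 2
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("subgraph depth d must be >= 1")
        if self.h < 0:
            raise ValueError("iteration count h must be >= 0")


class _LabeledGraph:
    """Internal rooted, directed, node- and edge-labeled multigraph."""

    __slots__ = ("node_labels", "edges", "root")

    def __init__(self, node_labels: dict, edges: list, root):
        self.node_labels = node_labels  # node id -> label
        self.edges = edges  # (u, edge_label, v)
        self.root = root


#: Canonical label given to every graph root, so that sample and concept
#: roots (whose node identifiers differ) can match under the kernel.
ROOT_LABEL = "root"


def _to_labeled_graph(g) -> _LabeledGraph:
    if isinstance(g, KnowledgeGraph):
        nodes: dict = {}
        edges = []
        for s, p, o in sorted(g.triples):
            nodes.setdefault(s, s)
            nodes.setdefault(o, o)
            edges.append((s, p, o))
        if g.root in nodes:
            nodes[g.root] = ROOT_LABEL
        return _LabeledGraph(nodes, edges, g.root)
    # networkx (Multi)DiGraph with 'label' node/edge attributes and a
    # 'root' graph attribute
    import networkx as nx

    if isinstance(g, nx.DiGraph):
        nodes = {v: str(data.get("label", v)) for v, data in g.nodes(data=True)}
        edges = [
            (u, str(data.get("label", "")), v)
            for u, v, data in g.edges(data=True)
        ]
        root = g.graph.get("root")
        if root is None:
            raise ValueError("networkx graph needs a 'root' graph attribute")
        return _LabeledGraph(nodes, sorted(edges), root)
    raise TypeError(f"unsupported graph type {type(g)!r}")


def _depth_subgraph(g: _LabeledGraph, d: int) -> _LabeledGraph:
    """Rooted subgraph reachable within ``d`` directed hops of the root."""
    out: dict = {}
    for u, p, v in g.edges:
        out.setdefault(u, []).append((u, p, v))
    depth = {g.root: 0}
    frontier = [g.root]
    edges = []
    for level in range(d):
        nxt = []
        for u in frontier:
            for e in out.get(u, []):
                edges.append(e)
                v = e[2]
                if v not in depth:
                    depth[v] = level + 1
                    nxt.append(v)
        frontier = nxt
    nodes = {v: g.node_labels[v] for v in depth}
    return _LabeledGraph(nodes, edges, g.root)


class _Interner:
    """Exact string-interning dictionary shared across graphs.

    Interning exact strings (rather than rolling hashes) rules out label
    collisions; kernel values are unaffected by which other graphs share the
    dictionary because equal ids correspond to equal label strings.
    """

    def __init__(self):
        self._ids: dict[str, int] = {}

    def __call__(self, label: str) -> int:
        return self._ids.setdefault(label, len(self._ids))


def _wl_iteration_counts(
    graphs: Sequence[_LabeledGraph], cfg: WFConfig
) -> list[list[dict]]:
    """Per-graph, per-iteration label-count dictionaries (shared interner).

    Vertex and edge label alphabets live in one dictionary but are tagged
    apart at iteration 0, so a vertex token never aliases a predicate token.
    Each iteration first relabels edges with the label of their target
    vertex, then vertices with the sorted multiset of their (new) out-edge
    labels -- after ``t`` iterations a vertex label identifies its unordered
    rooted out-subtree of depth ``t``.
    """
    intern = _Interner()
    subs = [_depth_subgraph(g, cfg.d) for g in graphs]
    node_labels = [
        {v: intern("n:" + lab) for v, lab in sub.node_labels.items()}
        for sub in subs
    ]
    edge_labels = [
        [intern("e:" + p) for (_, p, _) in sub.edges] for sub in subs
    ]
    counts: list[list[dict]] = [[] for _ in graphs]

    def snapshot(gi: int) -> dict:
        c: dict[int, int] = {}
        for lab in node_labels[gi].values():
            c[lab] = c.get(lab, 0) + 1
        for lab in edge_labels[gi]:
            c[lab] = c.get(lab, 0) + 1
        return c

    for gi in range(len(graphs)):
        counts[gi].append(snapshot(gi))
    for _ in range(cfg.h):
        for gi, sub in enumerate(subs):
            new_edge = [
                intern(f"{edge_labels[gi][k]}|{node_labels[gi][v]}")
                for k, (_, _, v) in enumerate(sub.edges)
            ]
            out_by_node: dict = {v: [] for v in sub.node_labels}
            for k, (u, _, _) in enumerate(sub.edges):
                out_by_node[u].append(new_edge[k])
            new_node = {
                v: intern(
                    f"{node_labels[gi][v]}({','.join(map(str, sorted(neigh)))})"
                )
                for v, neigh in out_by_node.items()
            }
            node_labels[gi] = new_node
            edge_labels[gi] = new_edge
            counts[gi].append(snapshot(gi))
    return counts


def _dot(counts1: Sequence[dict], counts2: Sequence[dict]) -> float:
    total = 0.0
    for c1, c2 in zip(counts1, counts2):
        if len(c2) < len(c1):
            c1, c2 = c2, c1
        total += sum(n * c2.get(lab, 0) for lab, n in c1.items())
    return total


def wf_kernel(g1, g2, cfg: WFConfig | None = None) -> float:
    """Weisfeiler-Lehman subtree kernel between two rooted graphs.

    Accepts :class:`~headachedx.kb.KnowledgeGraph` instances (typing triples
    must already be stripped) or networkx DiGraphs with ``label`` node/edge
    attributes and a ``root`` graph attribute.  Returns the sum over
    iterations 0..h of the dot products of label-count vectors, normalized
    to ``k(g1,g2)/sqrt(k(g1,g1)*k(g2,g2))`` when ``cfg.normalize`` is set.
    An empty graph yields similarity 0 (with a warning).
    """
    cfg = cfg or WFConfig()
    lg1, lg2 = _to_labeled_graph(g1), _to_labeled_graph(g2)
    if not lg1.node_labels or not lg2.node_labels:
        logger.warning("empty graph in kernel computation; similarity 0")
        return 0.0
    counts = _wl_iteration_counts([lg1, lg2], cfg)
    k12 = _dot(counts[0], counts[1])
    if not cfg.normalize:
        return k12
    k11 = _dot(counts[0], counts[0])
    k22 = _dot(counts[1], counts[1])
    if k11 == 0 or k22 == 0:
        return 0.0
    return k12 / math.sqrt(k11 * k22)


@dataclass
class SimilarityBlock:
    """An n x C matrix of sample-to-class similarities."""

    matrix: np.ndarray
    metric: str
    classes: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.classes):
            raise ValueError("similarity matrix shape does not match classes")

    @property
    def column_names(self) -> list[str]:
        return [f"sim_{self.metric}_{c}" for c in self.classes]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.column_names)


def class_similarity_features(
    sample_graphs: Sequence[KnowledgeGraph],
    concept_graphs: Sequence[KnowledgeGraph],
    classes: Sequence[str],
    cfg: WFConfig | None = None,
) -> SimilarityBlock:
    """WL-kernel similarities of each sample graph to each concept graph.

    Typing triples are stripped from the sample graphs before computation;
    concept graphs are label-free by construction.
    """
    cfg = cfg or WFConfig()
    if len(concept_graphs) != len(classes):
        raise ValueError("one concept graph per class required")
    graphs = [_to_labeled_graph(strip_typing(g)) for g in sample_graphs]
    cgraphs = [_to_labeled_graph(g) for g in concept_graphs]
    counts = _wl_iteration_counts(list(graphs) + list(cgraphs), cfg)
    s_counts = counts[: len(graphs)]
    c_counts = counts[len(graphs):]
    self_s = [_dot(c, c) for c in s_counts]
    self_c = [_dot(c, c) for c in c_counts]
    matrix = np.zeros((len(graphs), len(cgraphs)))
    for i, ci in enumerate(s_counts):
        for j, cj in enumerate(c_counts):
            k = _dot(ci, cj)
            if cfg.normalize:
                denom = math.sqrt(self_s[i] * self_c[j])
                k = k / denom if denom > 0 else 0.0
            matrix[i, j] = k
    return SimilarityBlock(matrix, "wf", list(classes))


def wf_similarity_block(
    ds: LabeledDataset, kb: KnowledgeBase, cfg: WFConfig | None = None
) -> SimilarityBlock:
    """Convenience wrapper: encode a dataset and compare to all concepts."""
    sample_graphs = [
        encode_sample(fv, ds.vocab, sample_id=f"sample-{i}")
        for i, fv in enumerate(ds.iter_samples())
    ]
    cgraphs = [concept_graph(kb, label) for label in kb.class_labels]
    return class_similarity_features(sample_graphs, cgraphs, kb.class_labels, cfg)


# -- data-driven class vectors --------------------------------------------


@dataclass
class ClassVector:
    """Numeric class prototype: per-class centroid or medoid encoding."""

    label: str
    vector: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)


def build_class_vectors(
    ds: LabeledDataset,
    mode: str = "centroid",
    encoder: NumericEncoder | None = None,
) -> list[ClassVector]:
    """Per-class centroid (mean) or medoid (min summed distance) vectors.

    Medoid ties are broken by lowest row index within the class.
    """
    if mode not in ("centroid", "medoid"):
        raise ValueError(f"unknown class-vector mode {mode!r}")
    encoder = encoder or NumericEncoder(ds.vocab)
    X = encoder.transform(ds.frame)
    y = np.asarray(ds.labels)
    vectors = []
    for label in ds.classes:
        idx = np.flatnonzero(y == label)
        if len(idx) == 0:
            raise ValueError(f"class {label!r} is empty")
        block = X[idx]
        if mode == "centroid":
            vec = block.mean(axis=0)
        else:
            dists = np.linalg.norm(block[:, None, :] - block[None, :, :], axis=2)
            vec = block[int(np.argmin(dists.sum(axis=1)))]
        vectors.append(ClassVector(label, vec, mode))
    return vectors


def rbf_similarity(x: np.ndarray, c: ClassVector | np.ndarray, gamma: float) -> float:
    """``exp(-gamma * ||x - c||^2)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    cv = c.vector if isinstance(c, ClassVector) else np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != cv.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {cv.shape}")
    return float(np.exp(-gamma * np.sum((x - cv) ** 2)))


def cosine_similarity(x: np.ndarray, c: ClassVector | np.ndarray) -> float:
    """Cosine of the angle between the vectors; 0 if either norm is 0."""
    cv = c.vector if isinstance(c, ClassVector) else np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != cv.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {cv.shape}")
    nx_, nc = np.linalg.norm(x), np.linalg.norm(cv)
    if nx_ == 0 or nc == 0:
        return 0.0
    return float(np.dot(x, cv) / (nx_ * nc))


def vector_similarity_block(
    ds: LabeledDataset,
    metric: str = "rbf",
    class_vectors: Sequence[ClassVector] | None = None,
    mode: str = "centroid",
    gamma: float | None = None,
    encoder: NumericEncoder | None = None,
) -> SimilarityBlock:
    """RBF or cosine similarities of every sample to the class vectors.

    ``class_vectors`` may be precomputed (e.g. on training folds only);
    otherwise they are built from ``ds`` itself.  Default ``gamma`` is
    1 / encoded dimension.
    """
    if metric not in ("rbf", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    encoder = encoder or NumericEncoder(ds.vocab)
    X = encoder.transform(ds.frame)
    if class_vectors is None:
        class_vectors = build_class_vectors(ds, mode, encoder)
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    C = np.stack([cv.vector for cv in class_vectors])
    if metric == "rbf":
        sq = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        matrix = np.exp(-gamma * sq)
    else:
        norms = np.linalg.norm(X, axis=1, keepdims=True) * np.linalg.norm(
            C, axis=1
        )
        matrix = np.divide(
            X @ C.T, norms, out=np.zeros((X.shape[0], C.shape[0])), where=norms > 0
        )
    return SimilarityBlock(matrix, metric, [cv.label for cv in class_vectors])


def nearest_class_predict(block: SimilarityBlock) -> list[str]:
    """Minimum-distance (maximum-similarity) class per row.

    Ties -- including all-zero rows -- resolve to the first class in
    canonical order and are logged.
    """
    if block.matrix.size == 0:
        raise ValueError("empty similarity block")
    labels = []
    for i, row in enumerate(block.matrix):
        best = row.max()
        j = int(np.argmax(row))  # first maximum in canonical class order
        if np.count_nonzero(row == best) > 1:
            if best == 0:
                logger.warning("all-zero similarity row %d; tie-break applied", i)
            else:
                logger.debug("similarity tie on row %d; first class wins", i)
        labels.append(block.classes[j])
    return labels
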