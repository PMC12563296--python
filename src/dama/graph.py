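"""Graph data model, file I/O, BFS distances, and partition-quality metrics.

The in-memory :class:`Graph` is a simple undirected graph over nodes
``0..n_nodes-1`` with an optional real-valued feature matrix and optional
integer community labels.  Edges are stored once as canonical ``(i, j)``
pairs with ``i < j``; self-loops are rejected.  Heavier structural
statistics (diameter, path lengths, clustering) are delegated to networkx.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "read_edge_list",
    "write_edge_list",
    "load_linqs_bundle",
    "export_gml",
    "bfs_distances",
    "common_neighbor_count",
    "graph_statistics",
    "modularity",
]


@dataclass
class Graph:
    """Undirected simple graph with optional node features and labels.

    Parameters
    ----------
    n_nodes
        Number of nodes; ids are ``0..n_nodes-1``.
    edges
        ``(m, 2)`` integer array of unordered edges.  Normalised on
        construction: each pair stored once with ``i < j``, self-loops
        forbidden.
    features
        Optional ``(n_nodes, d)`` float matrix of node attributes.
    labels
        Optional length ``n_nodes`` integer vector of community ids.
    """

    n_nodes: int
    edges: np.ndarray
    features: np.ndarray | None = None
    labels: np.ndarray | None = None
    _adj: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            if (e < 0).any() or (e >= self.n_nodes).any():
                raise ValueError("edge endpoint outside [0, n_nodes)")
            if (e[:, 0] == e[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            e = np.sort(e, axis=1)
            e = np.unique(e, axis=0)
        else:
            e = np.empty((0, 2), dtype=np.int64)
        self.edges = e
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.n_nodes,):
                raise ValueError("labels must be a length-n_nodes vector")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != self.n_nodes:
                raise ValueError("features must have n_nodes rows")

    # -- structure ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix in CSR form (cached)."""
        if self._adj is None:
            m = self.n_edges
            if m:
                i, j = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(2 * m)
                a = sp.coo_matrix(
                    (data, (np.r_[i, j], np.r_[j, i])),
                    shape=(self.n_nodes, self.n_nodes),
                )
                self._adj = a.tocsr()
            else:
                self._adj = sp.csr_matrix((self.n_nodes, self.n_nodes))
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, v: int) -> np.ndarray:
        a = self.adjacency()
        return a.indices[a.indptr[v] : a.indptr[v + 1]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def copy(self) -> "Graph":
        return Graph(
            self.n_nodes,
            self.edges.copy(),
            None if self.features is None else self.features.copy(),
            None if self.labels is None else self.labels.copy(),
        )


# -- I/O -------------------------------------------------------------------


def read_edge_list(source: IO[str] | Iterable[str], zero_based: bool = True) -> Graph:
    """Parse a plain-text edge list into a :class:`Graph`.

    Lines are whitespace- or comma-separated pairs of integer node ids;
    ``#`` starts a comment; an optional leading ``%n m`` header declares the
    node count.  Duplicate lines, reversed duplicates and self-loops are
    collapsed/dropped (self-loops with a warning).  With
    ``zero_based=False`` ids are shifted down by one on input.
    """
    declared_n: int | None = None
    pairs: list[tuple[int, int]] = []
    n_self = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("%"):
            head = line[1:].replace(",", " ").split()
            if head:
                declared_n = int(head[0])
            continue
        toks = line.replace(",", " ").split()
        if len(toks) < 2:
            raise ValueError(f"line {lineno}: expected two integer tokens")
        try:
            u, v = int(toks[0]), int(toks[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer node id") from exc
        if not zero_based:
            u, v = u - 1, v - 1
        if u == v:
            n_self += 1
            continue
        pairs.append((u, v))
    if n_self:
        logger.warning("dropped %d self-loop line(s)", n_self)
    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    n = declared_n if declared_n is not None else (int(edges.max()) + 1 if edges.size else 0)
    return Graph(n_nodes=n, edges=edges)


def write_edge_list(g: Graph, stream: IO[str], header: bool = True) -> None:
    """Write the canonicalised edge set, optionally with a ``%n m`` header."""
    if header:
        stream.write(f"% {g.n_nodes} {g.n_edges}\n")
    for u, v in g.edges:
        stream.write(f"{u} {v}\n")


def load_linqs_bundle(content_path: str, cites_path: str) -> Graph:
    """Load a citation-network bundle in the linqs text format.

    ``<name>.content`` rows are ``<id> <feat_1> ... <feat_d> <label>``;
    ``<name>.cites`` rows are directed ``<cited> <citing>`` pairs.  Node ids
    and labels may be arbitrary strings.  Directed citation pairs are
    canonicalised to undirected edges, deduplicated, and self-citations are
    dropped; citations to ids absent from the content file are ignored with
    a warning.
    """
    ids: list[str] = []
    feats: list[list[float]] = []
    raw_labels: list[str] = []
    with open(content_path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            ids.append(toks[0])
            feats.append([float(t) for t in toks[1:-1]])
            raw_labels.append(toks[-1])
    index = {s: k for k, s in enumerate(ids)}
    label_names = sorted(set(raw_labels))
    label_map = {s: k for k, s in enumerate(label_names)}
    labels = np.array([label_map[s] for s in raw_labels], dtype=np.int64)
    features = np.asarray(feats, dtype=np.float64)

    pairs: list[tuple[int, int]] = []
    n_missing = 0
    with open(cites_path) as fh:
        for line in fh:
            toks = line.split()
            if len(toks) < 2:
                continue
            a, b = toks[0], toks[1]
            if a not in index or b not in index:
                n_missing += 1
                continue
            u, v = index[a], index[b]
            if u != v:
                pairs.append((u, v))
    if n_missing:
        logger.warning("ignored %d citation(s) to unknown node ids", n_missing)
    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    return Graph(n_nodes=len(ids), edges=edges, features=features, labels=labels)


def export_gml(g: Graph, path: str) -> None:
    nxg = g.to_networkx()
    if g.labels is not None:
        nx.set_node_attributes(nxg, {i: int(c) for i, c in enumerate(g.labels)}, "community")
    nx.write_gml(nxg, path)


# -- distances and local structure ----------------------------------------


def bfs_distances(g: Graph, source: int, cutoff: int | None = None) -> dict[int, int]:
    """Hop distances from ``source`` by breadth-first search.

    Returns a map ``node -> distance`` containing the source at distance 0;
    nodes farther than ``cutoff`` (or unreachable) are absent.
    """
    if not (0 <= source < g.n_nodes):
        raise ValueError(f"source {source} not in graph")
    a = g.adjacency()
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        du = dist[u]
        if cutoff is not None and du >= cutoff:
            continue
        for w in a.indices[a.indptr[u] : a.indptr[u + 1]]:
            w = int(w)
            if w not in dist:
                dist[w] = du + 1
                q.append(w)
    return dist


def common_neighbor_count(g: Graph, i: int, j: int) -> int:
    """|Γ(i) ∩ Γ(j)| for distinct nodes i, j."""
    if i == j:
        raise ValueError("common_neighbor_count is undefined on the diagonal")
    return int(np.intersect1d(g.neighbors(i), g.neighbors(j)).size)


def graph_statistics(g: Graph) -> dict[str, float]:
    """Average degree, diameter, average path length and average clustering.

    Diameter and average path length are computed on the largest connected
    component (logged if the graph is disconnected); the local clustering of
    nodes with degree < 2 counts as 0 in the average.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    nxg = g.to_networkx()
    avg_degree = 2.0 * g.n_edges / g.n_nodes
    avg_clustering = float(np.mean(list(nx.clustering(nxg).values())))
    comps = list(nx.connected_components(nxg))
    if len(comps) > 1:
        logger.info(
            "graph has %d components; diameter/path length on the largest", len(comps)
        )
    giant = nxg.subgraph(max(comps, key=len))
    diameter = nx.diameter(giant)
    avg_path_length = nx.average_shortest_path_length(giant)
    return {
        "avg_degree": avg_degree,
        "diameter": float(diameter),
        "avg_path_length": float(avg_path_length),
        "avg_clustering": avg_clustering,
    }


def modularity(g: Graph, partition: Mapping[int, int] | np.ndarray) -> float:
    """Newman modularity Q of a partition.

    ``Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)`` over ordered node
    pairs.  Evaluated in its aggregated per-community form, which is
    algebraically identical to the double sum.
    """
    if g.n_edges == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if isinstance(partition, Mapping):
        assign = np.array([partition[i] for i in range(g.n_nodes)], dtype=np.int64)
    else:
        assign = np.asarray(partition, dtype=np.int64)
    if assign.shape != (g.n_nodes,):
        raise ValueError("partition must assign every node")
    m = g.n_edges
    deg = g.degrees().astype(np.float64)
    _, comm = np.unique(assign, return_inverse=True)
    n_comm = comm.max() + 1
    intra = np.bincount(
        comm[g.edges[:, 0]],
        weights=(comm[g.edges[:, 0]] == comm[g.edges[:, 1]]).astype(float),
        minlength=n_comm,
    )
    deg_sum = np.bincount(comm, weights=deg, minlength=n_comm)
    return float(np.sum(intra / m - (deg_sum / (2.0 * m)) ** 2))
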