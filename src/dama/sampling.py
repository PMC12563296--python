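"""Information-flow-aware adaptive sparse neighbourhood sampling.

Starting from a target node, hop-level neighbourhoods are grown layer by
layer.  At hop k a dynamic threshold

    r(k) = μ · AVG{ a_jh : v_j in the previous layer, v_h in Γ(v_j) }

is computed over *all* ordered frontier→neighbour pairs (zero intensities
included), and only unvisited neighbours reached through a pair with
a_jh >= r(k) are retained.  The per-layer mean intensity Q̄(k) over the
retained layer's incident pairs drives early stopping: when the intensity
variation between consecutive layers falls below ε, expansion stops.  The
sparse neighbourhood of the node is the union of the retained layers.

μ = 0 retains every reachable neighbour (the exact k-hop ball); larger μ is
more selective.  The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph
from .influence import InfluenceMatrix

__all__ = [
    "SamplingConfig",
    "HopNeighborhoods",
    "ThresholdUndefined",
    "dynamic_threshold",
    "sample_node",
    "sample_all",
    "full_khop_neighborhoods",
]


class ThresholdUndefined(ValueError):
    """Raised when a frontier has no incident edges (sampling terminates)."""


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the adaptive sparse sampling procedure.

    mu        : sparsification coefficient >= 0; 0 keeps everything, 1 is
                the empirically best general-purpose setting.
    epsilon   : early-stop tolerance on the layer-to-layer intensity
                variation (> 0).
    max_hops  : maximum hop depth K (default 3; structural information is
                largely contained in low-order neighbourhoods).
    min_keep  : when a layer would be empty but unvisited candidates
                exist, keep this many top-intensity candidates instead
                (0 = strict mode, allow empty layers/termination).
    early_stop_mode : "abs" stops on |Q̄(k) − Q̄(k−1)| < ε (default);
                "signed" stops on Q̄(k) − Q̄(k−1) < ε, the literal signed
                difference.
    """

    mu: float = 1.0
    epsilon: float = 1e-3
    max_hops: int = 3
    min_keep: int = 1
    early_stop_mode: str = "abs"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")
        if self.early_stop_mode not in ("abs", "signed"):
            raise ValueError("early_stop_mode must be 'abs' or 'signed'")


@dataclass
class HopNeighborhoods:
    """Retained hop layers of one node and their union."""

    node: int
    layers: list[np.ndarray]        # sorted node ids per retained hop
    union: np.ndarray               # sorted union of the layers
    qbars: list[float]              # mean incident intensity per retained hop
    k_stop: int                     # number of layers actually retained
    isolated: bool = False          # node had no incident edges at all
    thresholds: list[float] = field(default_factory=list)


def _aligned_intensities(g: Graph, ifm: InfluenceMatrix) -> np.ndarray:
    """IFM values aligned with the adjacency CSR's (indptr, indices) layout."""
    a = g.adjacency()
    if a.nnz == 0:
        return np.zeros(0)
    rows = np.repeat(np.arange(g.n_nodes), np.diff(a.indptr))
    vals = np.asarray(ifm.matrix[rows, a.indices]).ravel()
    return vals


def _frontier_pairs(
    a_indptr: np.ndarray, a_indices: np.ndarray, vals: np.ndarray, frontier: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All (neighbour id, intensity) pairs incident to the frontier."""
    chunks_h = [a_indices[a_indptr[j] : a_indptr[j + 1]] for j in frontier]
    chunks_v = [vals[a_indptr[j] : a_indptr[j + 1]] for j in frontier]
    if not chunks_h:
        return np.zeros(0, dtype=np.int64), np.zeros(0)
    return np.concatenate(chunks_h), np.concatenate(chunks_v)


def dynamic_threshold(
    ifm: InfluenceMatrix, frontier, g: Graph, mu: float
) -> float:
    """Dynamic retention threshold r(k) = μ · mean incident intensity.

    The mean runs over every ordered pair (frontier node, its graph
    neighbour), counting zero-valued influence entries.  Raises
    :class:`ThresholdUndefined` if no frontier node has a neighbour.
    """
    frontier = np.asarray(sorted(frontier), dtype=np.int64)
    a = g.adjacency()
    vals = _aligned_intensities(g, ifm)
    _, pair_vals = _frontier_pairs(a.indptr, a.indices, vals, frontier)
    if pair_vals.size == 0:
        raise ThresholdUndefined("frontier has no incident edges")
    return float(mu * pair_vals.mean())


def _sample_node_impl(
    g: Graph,
    vals: np.ndarray,
    v: int,
    cfg: SamplingConfig,
    visited_buf: np.ndarray,
) -> HopNeighborhoods:
    a = g.adjacency()
    indptr, indices = a.indptr, a.indices
    if indptr[v + 1] == indptr[v]:
        return HopNeighborhoods(
            node=v, layers=[], union=np.zeros(0, dtype=np.int64),
            qbars=[], k_stop=0, isolated=True,
        )
    visited_buf[:] = False
    visited_buf[v] = True
    frontier = np.array([v], dtype=np.int64)
    layers: list[np.ndarray] = []
    qbars: list[float] = []
    thresholds: list[float] = []
    prev_qbar: float | None = None
    for _k in range(1, cfg.max_hops + 1):
        h, av = _frontier_pairs(indptr, indices, vals, frontier)
        if h.size == 0:
            break
        r = cfg.mu * av.mean()
        thresholds.append(float(r))
        # tiny slack keeps the all-equal-intensity case (a == r up to
        # summation order) independent of floating-point reduction order
        keep = av >= r - 1e-12 * max(1.0, abs(r))
        cand = h[~visited_buf[h]]
        retained = np.unique(h[keep & ~visited_buf[h]])
        if retained.size == 0:
            if cfg.min_keep > 0 and cand.size:
                # keep the top-min_keep unvisited candidates by their best
                # incoming intensity; ties broken toward lower node ids
                uniq = np.unique(cand)
                best = np.full(uniq.size, -np.inf)
                pos = np.searchsorted(uniq, h)
                mask = ~visited_buf[h]
                np.maximum.at(best, pos[mask], av[mask])
                order = np.lexsort((uniq, -best))
                retained = np.sort(uniq[order[: cfg.min_keep]])
            else:
                break
        layers.append(retained)
        visited_buf[retained] = True
        _, layer_av = _frontier_pairs(indptr, indices, vals, retained)
        qbar = float(layer_av.mean()) if layer_av.size else 0.0
        qbars.append(qbar)
        if prev_qbar is not None:
            delta = qbar - prev_qbar
            if cfg.early_stop_mode == "abs":
                delta = abs(delta)
            if delta < cfg.epsilon:
                break
        prev_qbar = qbar
        frontier = retained
    union = (
        np.unique(np.concatenate(layers)) if layers else np.zeros(0, dtype=np.int64)
    )
    return HopNeighborhoods(
        node=v, layers=layers, union=union, qbars=qbars,
        k_stop=len(layers), isolated=False, thresholds=thresholds,
    )


def sample_node(
    g: Graph, ifm: InfluenceMatrix, v: int, cfg: SamplingConfig | None = None
) -> HopNeighborhoods:
    """Adaptively sparsified hop neighbourhoods of a single node."""
    cfg = cfg or SamplingConfig()
    if not (0 <= v < g.n_nodes):
        raise ValueError(f"node {v} not in graph")
    vals = _aligned_intensities(g, ifm)
    buf = np.zeros(g.n_nodes, dtype=bool)
    return _sample_node_impl(g, vals, v, cfg, buf)


def sample_all(
    g: Graph, ifm: InfluenceMatrix, cfg: SamplingConfig | None = None
) -> dict[int, HopNeighborhoods]:
    """Sampled neighbourhoods for every node (deterministic)."""
    cfg = cfg or SamplingConfig()
    vals = _aligned_intensities(g, ifm)
    buf = np.zeros(g.n_nodes, dtype=bool)
    return {
        v: _sample_node_impl(g, vals, v, cfg, buf) for v in range(g.n_nodes)
    }


def full_khop_neighborhoods(g: Graph, max_hops: int = 3) -> dict[int, HopNeighborhoods]:
    """Unsparsified K-hop BFS rings — the 'sampling removed' ablation."""
    from .graph import bfs_distances

    out: dict[int, HopNeighborhoods] = {}
    for v in range(g.n_nodes):
        dist = bfs_distances(g, v, cutoff=max_hops)
        layers = []
        for k in range(1, max_hops + 1):
            ring = np.array(sorted(u for u, d in dist.items() if d == k), dtype=np.int64)
            if ring.size == 0:
                break
            layers.append(ring)
        union = (
            np.unique(np.concatenate(layers)) if layers else np.zeros(0, dtype=np.int64)
        )
        out[v] = HopNeighborhoods(
            node=v, layers=layers, union=union, qbars=[],
            k_stop=len(layers), isolated=union.size == 0,
        )
    return out
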