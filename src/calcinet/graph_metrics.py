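"""Thresholded functional graphs, topological metrics and communities.

The connectivity matrix is turned into an undirected weighted graph by
keeping edges with rho_max >= theta (inclusive; ``theta=None`` keeps every
non-degenerate pair).  All metrics are computed on the *unweighted*
topology of the thresholded graph — the degree, clustering-coefficient and
efficiency formulas are binary-adjacency formulas with hop-count shortest
paths; edge weights are retained for display and export only.

Community structure is found with Newman's leading-eigenvector method:
recursive spectral bisection on the (generalized) modularity matrix,
splitting a group only while the split strictly increases modularity.  The
implementation uses a dense symmetric eigendecomposition with a fixed
eigenvector sign convention, so the partition is fully deterministic —
identical inputs always give identical communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .core_io import CellTable, FunctionalGraph
from .connectivity import ConnectivityMatrix

__all__ = [
    "GraphMetrics",
    "CommunityPartition",
    "build_graph",
    "degree_stats",
    "clustering_coefficient",
    "global_efficiency",
    "detect_communities",
    "modularity",
]

#: an eigenvalue below this is treated as non-positive (indivisible group)
_EIG_TOL = 1e-10
#: a modularity gain below this does not justify a split
_GAIN_TOL = 1e-12
#: community size above which it counts as "large"
LARGE_COMMUNITY_MIN = 6


@dataclass
class GraphMetrics:
    degrees: dict[str, int]
    mean_degree: float
    clustering_coeff: float
    global_efficiency: float


@dataclass
class CommunityPartition:
    """Community index per node, the partition's modularity, and the number
    of large communities (more than five members)."""

    membership: dict[str, int]
    modularity: float
    large_community_count: int

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for c in self.membership.values():
            counts[c] = counts.get(c, 0) + 1
        return [counts[c] for c in sorted(counts)]


def build_graph(
    c: ConnectivityMatrix,
    theta: Optional[float] = 0.3,
    cells: Optional[CellTable] = None,
) -> FunctionalGraph:
    """Keep edges with rho_max >= theta; isolated nodes stay in the graph.

    ``theta=None`` disables filtering (complete weighted graph on all
    pairs with a defined correlation).  Node attributes ``x``, ``y`` and
    ``label`` are attached from the aligned cell table when given.
    """
    if theta is not None and not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1] or None")
    n = c.n_cells
    g = nx.Graph()
    for k, cid in enumerate(c.cell_ids):
        attrs = {}
        if cells is not None:
            attrs = {"x": float(cells.x[k]), "y": float(cells.y[k])}
            if cells.labels is not None and cells.labels[k] is not None:
                attrs["label"] = cells.labels[k]
        g.add_node(cid, **attrs)
    thr = -np.inf if theta is None else theta
    for i in range(n):
        for j in range(i + 1, n):
            w = c.rho_max[i, j]
            # zeroed rows of constant cells never clear a None threshold
            if w >= thr and w > 0.0:
                g.add_edge(c.cell_ids[i], c.cell_ids[j], weight=float(w))
    return FunctionalGraph(graph=g, theta=theta)


def degree_stats(g: FunctionalGraph) -> GraphMetrics:
    """Unweighted node degrees and their mean <k> = 2|E|/N.

    Returned with clustering/efficiency left at NaN; use the dedicated
    functions (or the pipeline) for those.
    """
    degs = {n: int(d) for n, d in g.graph.degree()}
    N = g.n_nodes
    mean_deg = 2.0 * g.n_edges / N if N else 0.0
    return GraphMetrics(
        degrees=degs,
        mean_degree=mean_deg,
        clustering_coeff=float("nan"),
        global_efficiency=float("nan"),
    )


def clustering_coefficient(
    g: FunctionalGraph, count_low_degree_as_zero: bool = False
) -> float:
    """Average local clustering coefficient of the unweighted topology.

    Per node, 2*e_i / (k_i * (k_i - 1)) where e_i counts edges among the
    node's neighbors.  Nodes with fewer than two neighbors have an
    undefined local coefficient and are excluded from the average by
    default (the local-average convention of igraph's transitivity);
    ``count_low_degree_as_zero=True`` instead counts them as 0.  Returns 0
    when no node has degree >= 2.
    """
    local = nx.clustering(g.graph)  # 0.0 for degree < 2
    if count_low_degree_as_zero:
        vals = list(local.values())
    else:
        deg = dict(g.graph.degree())
        vals = [c for n, c in local.items() if deg[n] >= 2]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def global_efficiency(g: FunctionalGraph) -> float:
    """Mean inverse hop-count distance over all ordered node pairs.

    G = (1/(N(N-1))) * sum_{i != j} 1/d_ij; pairs in different connected
    components contribute zero.  Requires N >= 2.
    """
    if g.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(nx.global_efficiency(g.graph))


# ---------------------------------------------------------------------------
# Leading-eigenvector community detection
# ---------------------------------------------------------------------------

def modularity(
    adj: np.ndarray, membership: np.ndarray, m: Optional[float] = None
) -> float:
    """Direct evaluation of Q = sum_c [e_c/m - (d_c/(2m))^2].

    ``adj`` is the unweighted symmetric adjacency matrix, ``membership``
    an integer community index per node.  Q = 0 for an edgeless graph.
    """
    adj = np.asarray(adj, dtype=float)
    k = adj.sum(axis=1)
    if m is None:
        m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        e_c = adj[np.ix_(idx, idx)].sum() / 2.0
        d_c = k[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def _leading_eig(B: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and its eigenvector, sign fixed so the first
    component of magnitude > tol is positive."""
    w, V = np.linalg.eigh(B)
    lam = float(w[-1])
    v = V[:, -1]
    for comp in v:
        if abs(comp) > _EIG_TOL:
            if comp < 0:
                v = -v
            break
    return lam, v


def _split(
    B_global: np.ndarray,
    idx: np.ndarray,
    m: float,
    membership: np.ndarray,
    next_label: list[int],
) -> None:
    """Recursively bisect the node group ``idx`` while modularity grows."""
    if idx.size < 2:
        return
    Bg = B_global[np.ix_(idx, idx)].copy()
    # generalized modularity matrix: remove row sums on the diagonal so
    # that splits of a subgroup leave the rest of the network intact
    Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
    lam, v = _leading_eig(Bg)
    if lam <= _EIG_TOL:
        return
    s = np.where(v >= 0.0, 1.0, -1.0)
    if np.all(s == s[0]):
        return
    gain = float(s @ Bg @ s) / (4.0 * m)
    if gain <= _GAIN_TOL:
        return
    left = idx[s > 0]
    right = idx[s < 0]
    label = next_label[0]
    next_label[0] += 1
    membership[right] = label
    _split(B_global, left, m, membership, next_label)
    _split(B_global, right, m, membership, next_label)


def detect_communities(g: FunctionalGraph) -> CommunityPartition:
    """Newman leading-eigenvector communities of the thresholded graph.

    Operates on the unweighted adjacency.  Nodes in different connected
    components never share a community; each component is bisected
    recursively on its modularity matrix until no split has a positive
    leading eigenvalue and a positive modularity gain.  An edgeless graph
    puts every node in its own community with Q = 0.
    """
    nodes = list(g.graph.nodes)
    n = len(nodes)
    if n == 0:
        return CommunityPartition({}, 0.0, 0)
    adj = nx.to_numpy_array(g.graph, nodelist=nodes, weight=None)
    m = adj.sum() / 2.0
    membership = np.zeros(n, dtype=int)
    if m == 0:
        membership = np.arange(n)
    else:
        k = adj.sum(axis=1)
        B = adj - np.outer(k, k) / (2.0 * m)
        next_label = [1]
        # seed the recursion per connected component (deterministic order)
        pos = {nd: i for i, nd in enumerate(nodes)}
        comp_label: dict[str, int] = {}
        for comp in nx.connected_components(g.graph):
            comp_nodes = sorted(comp, key=pos.__getitem__)
            if comp_label:
                lab = next_label[0]
                next_label[0] += 1
            else:
                lab = 0
            for cn in comp_nodes:
                comp_label[cn] = lab
        membership = np.array([comp_label[nd] for nd in nodes], dtype=int)
        for lab in sorted(set(comp_label.values())):
            idx = np.flatnonzero(membership == lab)
            _split(B, idx, m, membership, next_label)
    # relabel to consecutive indices in order of first appearance
    relabel: dict[int, int] = {}
    for c in membership:
        if c not in relabel:
            relabel[c] = len(relabel)
    membership = np.array([relabel[c] for c in membership], dtype=int)
    q = modularity(adj, membership, m=m)
    sizes = np.bincount(membership)
    large = int((sizes >= LARGE_COMMUNITY_MIN).sum())
    part = CommunityPartition(
        membership={nd: int(c) for nd, c in zip(nodes, membership)},
        modularity=q,
        large_community_count=large,
    )
    for nd in nodes:
        g.graph.nodes[nd]["community"] = part.membership[nd]
    return part
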