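"""PhenoGraph-style neighbor graph and Louvain community detection.

The graph stage builds directed k-nearest-neighbour lists in the embedding
(Euclidean metric, ties broken by node index), symmetrizes them by union,
and re-weights each edge by the Jaccard overlap of the two endpoints'
neighbourhood sets (each set includes the node itself); zero-overlap edges
are dropped. Louvain then greedily maximizes weighted modularity with
seed-shuffled node order, aggregating communities level by level.

Louvain and modularity are implemented here directly; igraph/leidenalg are
deliberately not used (they serve as an independent cross-check in the test
suite only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

_MIN_GAIN = 1e-9


@dataclass
class NeighborGraph:
    """Undirected weighted graph: ``edges[(i, j)] = w`` with i < j,
    weights in (0, 1] (Jaccard), no self-loops."""

    n_nodes: int
    edges: dict[tuple[int, int], float]
    k: int
    weight_kind: str = "jaccard"

    def adjacency(self) -> list[dict[int, float]]:
        adj = [dict() for _ in range(self.n_nodes)]
        for (i, j), w in self.edges.items():
            adj[i][j] = w
            adj[j][i] = w
        return adj

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def edge_list(self) -> np.ndarray:
        """(n_edges, 3) array of (i, j, w) rows, for export."""
        if not self.edges:
            return np.empty((0, 3))
        return np.array([(i, j, w) for (i, j), w in
                         sorted(self.edges.items())])


@dataclass
class Partition:
    """Community labels (contiguous ints starting at 0) plus modularity."""

    labels: np.ndarray
    n_communities: int
    modularity: float


def _knn_indices(emb: np.ndarray, k: int) -> np.ndarray:
    """Directed kNN lists (self excluded), ties broken by node index."""
    n = emb.shape[0]
    if n <= 4000:
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        idx = np.arange(n)
        # lexsort: primary key distance, secondary node index
        order = np.lexsort((np.broadcast_to(idx, (n, n)), d2), axis=1)
        return order[:, :k]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, ind = nn.kneighbors(emb)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = ind[i][ind[i] != i][:k]
        out[i] = row
    return out


def build_knn_graph(emb: np.ndarray, k: int) -> NeighborGraph:
    """kNN graph with Jaccard edge weights.

    Edge (i, j) exists when either node lists the other among its k nearest
    neighbours; its weight is |N(i) & N(j)| / |N(i) | N(j)| over the
    neighbourhood sets N(.) = kNN(.) + {self}. Zero-weight edges dropped.
    """
    emb = np.asarray(emb, dtype=float)
    n = emb.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    knn = _knn_indices(emb, k)
    sets = [set(knn[i]) | {i} for i in range(n)]
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in knn[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            inter = len(sets[a] & sets[b])
            if inter == 0:
                continue
            union = len(sets[a] | sets[b])
            edges[(a, b)] = inter / union
    return NeighborGraph(n_nodes=n, edges=edges, k=k)


def modularity(graph: NeighborGraph, labels) -> float:
    """Weighted Newman modularity Q = sum_c (w_c/W - (s_c/2W)^2), with w_c
    the intra-community weight, s_c the community strength and W the total
    edge weight."""
    labels = np.asarray(labels)
    if labels.shape[0] != graph.n_nodes:
        raise ValueError("labels must cover every node")
    W = graph.total_weight()
    if W == 0:
        return 0.0
    strength: dict = {}
    intra: dict = {}
    for (i, j), w in graph.edges.items():
        strength[labels[i]] = strength.get(labels[i], 0.0) + w
        strength[labels[j]] = strength.get(labels[j], 0.0) + w
        if labels[i] == labels[j]:
            intra[labels[i]] = intra.get(labels[i], 0.0) + w
    return float(sum(intra.get(c, 0.0) / W - (s / (2 * W)) ** 2
                     for c, s in strength.items()))


def _one_level(adj, node_w, self_w, m2, rng):
    """One Louvain local-moving phase on an aggregated graph.

    adj: list of {nbr: weight}; node_w: node strengths (incl. self-loops,
    self-loop weight counted twice); self_w: self-loop weights.
    Returns (labels, improved).
    """
    n = len(adj)
    comm = np.arange(n)
    tot = node_w.copy()          # community strengths
    improved = False
    moved = True
    while moved:
        moved = False
        for u in rng.permutation(n):
            cu = comm[u]
            ku = node_w[u]
            # weights from u to neighbouring communities
            link: dict[int, float] = {}
            for v, w in adj[u].items():
                if v != u:
                    link[comm[v]] = link.get(comm[v], 0.0) + w
            tot[cu] -= ku
            base = link.get(cu, 0.0) - tot[cu] * ku / m2
            best_c, best_gain = cu, 0.0
            for c, kuc in link.items():
                if c == cu:
                    continue
                gain = kuc - tot[c] * ku / m2 - base
                if gain > best_gain + _MIN_GAIN or \
                        (abs(gain - best_gain) <= _MIN_GAIN and
                         best_c != cu and c < best_c):
                    best_gain, best_c = gain, c
            comm[u] = best_c
            tot[best_c] += ku
            if best_c != cu:
                moved = improved = True
    return comm, improved


def _aggregate(adj, self_w, comm):
    """Collapse communities into nodes; intra weight becomes self-loops."""
    uniq, new = np.unique(comm, return_inverse=True)
    k = len(uniq)
    agg = [dict() for _ in range(k)]
    selfw = np.zeros(k)
    for u, nbrs in enumerate(adj):
        cu = new[u]
        for v, w in nbrs.items():
            if v < u:
                continue
            cv = new[v]
            if cu == cv:
                selfw[cu] += w
            else:
                agg[cu][cv] = agg[cu].get(cv, 0.0) + w
                agg[cv][cu] = agg[cv].get(cu, 0.0) + w
    # carry forward existing self-loops
    for u, w in enumerate(self_w):
        selfw[new[u]] += w
    return agg, selfw, new


def louvain(graph: NeighborGraph, seed: int | None = None) -> Partition:
    """Louvain modularity maximization (greedy local moving + aggregation,
    iterated until no pass improves modularity by more than 1e-9).

    Node visiting order is shuffled by ``seed``; identical graph and seed
    give identical labels. Disconnected components are handled naturally
    (they simply never merge).
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)
    adj = graph.adjacency()
    self_w = np.zeros(graph.n_nodes)
    labels = np.arange(graph.n_nodes)
    W = graph.total_weight()
    if W == 0:
        return Partition(labels=np.zeros(graph.n_nodes, dtype=int),
                         n_communities=1, modularity=0.0)
    m2 = 2.0 * W

    mapping = np.arange(graph.n_nodes)
    while True:
        node_w = np.array([sum(a.values()) for a in adj]) + 2.0 * self_w
        comm, improved = _one_level(adj, node_w, self_w, m2, rng)
        adj, self_w, new = _aggregate(adj, self_w, comm)
        mapping = new[mapping]
        if not improved:
            break

    uniq, labels = np.unique(mapping, return_inverse=True)
    q = modularity(graph, labels)
    return Partition(labels=labels.astype(int),
                     n_communities=len(uniq), modularity=q)


def adjusted_rand_index(p1, p2) -> float:
    """Chance-corrected partition agreement (pair-counting ARI)."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions must have the same length")
    return float(adjusted_rand_score(p1, p2))
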