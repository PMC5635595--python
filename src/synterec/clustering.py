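"""Homolog-graph construction and Markov clustering into candidate
homolog groups (CHGs).

Edges require *bidirectional* hits, each with E-value below 1e-10 and
majority (>50%) coverage of the longer sequence; edge weights are the
mean of -log10(E) over the two directions.  Clustering uses standard MCL
(expansion by matrix squaring, inflation by elementwise power, default
inflation 1.4), whose setting is sanity-checked with the average
silhouette width; clusters of ten or more members become CHGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import HitTable

E_CAP = 1e-200  # floor so -log10 stays finite at reported E = 0


def build_similarity_graph(
    hits: HitTable, e_max: float = 1e-10, cov_min: float = 0.5
) -> nx.Graph:
    """Filtered undirected similarity graph.

    An edge (u, v) exists iff hits exist in *both* directions, each with
    E < e_max (strict) and coverage of the longer sequence > cov_min
    (strict); its weight is the mean over both directions of
    -log10(max(E, 1e-200)).  Row order in the hit table is immaterial.
    """
    df = hits.df
    passed = df[(df["evalue"] < e_max) & (df["coverage"] > cov_min)]
    best: dict[tuple[str, str], float] = {}
    for q, s, e in zip(passed["query"], passed["subject"], passed["evalue"]):
        if q == s:
            continue
        key = (q, s)
        w = -math.log10(max(e, E_CAP))
        if key not in best or w > best[key]:
            best[key] = w
    g = nx.Graph()
    g.add_nodes_from(sorted(set(df["query"]) | set(df["subject"])))
    for (q, s), w in best.items():
        if (s, q) in best and q < s:
            g.add_edge(q, s, weight=(w + best[(s, q)]) / 2)
    return g


@dataclass
class Clustering:
    """A partition of graph nodes into clusters."""

    assignment: dict                   # node -> cluster id (int)

    @property
    def clusters(self) -> list[list]:
        out: dict[int, list] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return [sorted(out[c]) for c in sorted(out)]

    def __len__(self) -> int:
        return len(set(self.assignment.values()))


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 1.4,
    max_iter: int = 1000,
    tol: float = 1e-8,
    prune: float = 1e-10,
) -> Clustering:
    """Markov clustering of the similarity graph.

    Self-loops are set to each node's maximum incident edge weight
    (isolated nodes get 1), the transition matrix is column-stochastic,
    and expansion (matrix squaring) alternates with inflation
    (elementwise power then renormalization) until the maximum
    elementwise change drops below ``tol``.  Clusters are the weakly
    connected components of the converged attractor structure; the
    procedure is deterministic for fixed input.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(g.nodes)
    if not nodes:
        return Clustering(assignment={})
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations (residual {delta:.2e})"
        )
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-7)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    assignment = {}
    comps = sorted(
        (sorted(c) for c in nx.connected_components(support)),
        key=lambda c: (-len(c), nodes[c[0]]),
    )
    for cid, comp in enumerate(comps):
        for i in comp:
            assignment[nodes[i]] = cid
    return Clustering(assignment=assignment)


def silhouette_width(g: nx.Graph, clustering: Clustering) -> float:
    """Average silhouette width of a clustering of the similarity graph.

    Distances: d(u, v) = 1 - w(u, v) / w_max for edges, 1 for non-edges.
    Per node, s = (b - a) / max(a, b) with a the mean intra-cluster
    distance and b the smallest mean distance to another cluster;
    singleton-cluster nodes contribute 0.
    """
    clusters = clustering.clusters
    if len(clusters) < 2:
        raise ValueError("silhouette width needs at least 2 clusters")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w_max = max(
        (d.get("weight", 1.0) for _, _, d in g.edges(data=True)), default=1.0
    )
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for u, v, data in g.edges(data=True):
        d = 1.0 - data.get("weight", 1.0) / w_max
        dist[index[u], index[v]] = d
        dist[index[v], index[u]] = d
    members = [np.array([index[v] for v in c]) for c in clusters]
    total = 0.0
    for ci, mem in enumerate(members):
        for i in mem:
            if len(mem) == 1:
                continue
            a = dist[i, mem].sum() / (len(mem) - 1)
            b = min(
                dist[i, other].mean()
                for cj, other in enumerate(members)
                if cj != ci
            )
            denom = max(a, b)
            if denom > 0:
                total += (b - a) / denom
    return total / n


@dataclass
class CHG:
    """A candidate homolog group: one cluster of >= min_size members."""

    id: str
    members: list

    @property
    def size(self) -> int:
        return len(self.members)


def define_chgs(clustering: Clustering, min_size: int = 10) -> list[CHG]:
    """Clusters with >= min_size members, as CHGs ``ch1, ch2, ...``
    ordered by decreasing size then lexicographically smallest member."""
    big = [c for c in clustering.clusters if len(c) >= min_size]
    big.sort(key=lambda c: (-len(c), c[0]))
    return [CHG(id=f"ch{i + 1}", members=c) for i, c in enumerate(big)]


def inflation_sweep(
    g: nx.Graph, inflations=(1.2, 1.4, 1.6, 2.0)
) -> dict[float, float]:
    """Average silhouette width per inflation setting (diagnostic for
    choosing the clustering granularity)."""
    out = {}
    for inf in inflations:
        c = mcl_cluster(g, inflation=inf)
        try:
            out[inf] = silhouette_width(g, c)
        except ValueError:
            out[inf] = float("nan")
    return out
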