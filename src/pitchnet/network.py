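"""Directed weighted passing networks and geodesic centralities.

The passing network of one team is the 10 x 10 adjacency ``A[v, w]`` =
number of successful passes from player v to player w.  Pass counts induce
a geodesic distance between players under one of two conventions:

* ``"reciprocal"`` (default): edge length 1 / A[v, w] — frequently-used
  connections are "short", so closeness rewards strong links;
* ``"hop"``: every existing edge has length 1 (unweighted replication).

Closeness of v is the reciprocal of its farness, the summed geodesic
distance to every *reachable* teammate (unreachable targets are excluded
and the reachable count reported, since a single isolated receiver would
otherwise zero out every score).  Betweenness of v sums the pair-dependency
``delta_st(v) = sigma_st(v) / sigma_st`` over ordered pairs s != v != t,
where ``sigma_st`` counts shortest s->t paths and ``sigma_st(v)`` those
passing through v.  Equal-length path ties are detected with a relative
tolerance of 1e-12 to keep reciprocal-length arithmetic stable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PassLog

REL_TOL = 1e-12

CONVENTIONS = ("reciprocal", "hop")


@dataclass
class PassingNetwork:
    """One team's directed pass-count adjacency."""

    nodes: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        n = len(self.nodes)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape does not match node list")
        if np.any(self.A < 0) or np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency must be non-negative with zero diagonal")

    @property
    def n_passes(self) -> int:
        return int(self.A.sum())


@dataclass
class PathCensus:
    """All-pairs geodesic structure of a weighted digraph.

    dist[s, t]            geodesic length (inf if unreachable)
    sigma[s, t]           number of shortest s->t paths (0 if unreachable)
    sigma_through[v,s,t]  number of shortest s->t paths with v as an
                          intermediate node (v not in {s, t})
    """

    dist: np.ndarray
    sigma: np.ndarray
    sigma_through: np.ndarray
    convention: str = "reciprocal"


@dataclass
class CentralityScores:
    closeness: np.ndarray
    betweenness: np.ndarray
    reachable_count: np.ndarray
    nodes: list[str] = field(default_factory=list)
    convention: str = "reciprocal"

    def to_frame(self, roles: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "player_id": self.nodes,
            "closeness": self.closeness,
            "betweenness": self.betweenness,
            "reachable_count": self.reachable_count,
        })
        if roles is not None:
            df.insert(1, "role", roles)
        return df


def build_adjacency(log: PassLog, roster: list[str], team: str) -> PassingNetwork:
    """Count successful directed passes into a PassingNetwork."""
    index = {p: i for i, p in enumerate(roster)}
    A = np.zeros((len(roster), len(roster)), dtype=int)
    for _, row in log.successful(team).iterrows():
        try:
            i, j = index[row["passer_id"]], index[row["receiver_id"]]
        except KeyError as exc:
            raise ValueError(f"pass event references non-roster player: {exc}") from exc
        if i == j:
            raise ValueError(f"self-pass in log for {row['passer_id']}")
        A[i, j] += 1
    return PassingNetwork(nodes=list(roster), A=A)


def edge_distances(net: PassingNetwork, convention: str = "reciprocal") -> np.ndarray:
    """Map pass counts to edge lengths (inf where no pass occurred)."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown distance convention: {convention!r}")
    A = net.A.astype(float)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A if convention == "reciprocal" else 1.0, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_path_census(lengths: np.ndarray,
                         convention: str = "reciprocal") -> PathCensus:
    """All-pairs geodesics with tie-aware path counting.

    Runs Dijkstra from every source, accumulating the number of shortest
    paths ``sigma`` over predecessors whose relaxation is tight within
    relative tolerance 1e-12; through-counts follow from the factorisation
    ``sigma_st(v) = sigma_sv * sigma_vt`` when v lies on a geodesic.
    """
    L = np.asarray(lengths, float)
    n = L.shape[0]
    if L.shape != (n, n):
        raise ValueError("lengths must be square")
    if np.any(L < 0):
        raise ValueError("edge lengths must be non-negative")
    if np.any(np.diag(L) != 0):
        raise ValueError("diagonal of the length matrix must be zero")

    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s], sigma[s] = _dijkstra_count(L, s)

    sigma_through = np.zeros((n, n, n))
    for v in range(n):
        for s in range(n):
            if s == v:
                continue
            for t in range(n):
                if t in (s, v) or not np.isfinite(dist[s, t]):
                    continue
                if _close(dist[s, v] + dist[v, t], dist[s, t]):
                    sigma_through[v, s, t] = sigma[s, v] * sigma[v, t]
    return PathCensus(dist=dist, sigma=sigma, sigma_through=sigma_through,
                      convention=convention)


def _close(a: float, b: float) -> bool:
    if not (np.isfinite(a) and np.isfinite(b)):
        return False
    return abs(a - b) <= REL_TOL * max(abs(a), abs(b), 1.0)


def _dijkstra_count(L: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    n = L.shape[0]
    dist = np.full(n, np.inf)
    dist[s] = 0.0
    done = np.zeros(n, bool)
    heap = [(0.0, s)]
    order = []
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        order.append(u)
        for w in range(n):
            if np.isfinite(L[u, w]) and w != u:
                nd = d + L[u, w]
                if nd < dist[w] - REL_TOL * max(nd, 1.0):
                    dist[w] = nd
                    heapq.heappush(heap, (nd, w))
    # count geodesics in non-decreasing distance order
    sigma = np.zeros(n)
    sigma[s] = 1.0
    for u in sorted(range(n), key=lambda i: dist[i]):
        if u == s or not np.isfinite(dist[u]):
            continue
        for p in range(n):
            if p != u and np.isfinite(dist[p]) and np.isfinite(L[p, u]) \
                    and _close(dist[p] + L[p, u], dist[u]):
                sigma[u] += sigma[p]
    return dist, sigma


def closeness(census: PathCensus) -> tuple[np.ndarray, np.ndarray]:
    """Per-node closeness = 1 / sum of distances to reachable targets.

    Returns (closeness, reachable_count); a node reaching no one scores 0.
    """
    n = census.dist.shape[0]
    scores = np.zeros(n)
    reach = np.zeros(n, dtype=int)
    for v in range(n):
        d = np.delete(census.dist[v], v)
        finite = np.isfinite(d)
        reach[v] = int(finite.sum())
        far = d[finite].sum()
        scores[v] = 1.0 / far if far > 0 else 0.0
    return scores, reach


def betweenness(census: PathCensus) -> np.ndarray:
    """Per-node betweenness: sum of sigma_st(v) / sigma_st over ordered pairs."""
    n = census.dist.shape[0]
    scores = np.zeros(n)
    for v in range(n):
        for s in range(n):
            if s == v:
                continue
            for t in range(n):
                if t in (s, v) or census.sigma[s, t] == 0:
                    continue
                scores[v] += census.sigma_through[v, s, t] / census.sigma[s, t]
    return scores


def centrality_scores(net: PassingNetwork,
                      convention: str = "reciprocal") -> CentralityScores:
    """Convenience: adjacency -> census -> closeness + betweenness."""
    census = shortest_path_census(edge_distances(net, convention), convention)
    close, reach = closeness(census)
    return CentralityScores(closeness=close, betweenness=betweenness(census),
                            reachable_count=reach, nodes=list(net.nodes),
                            convention=convention)


def export_network(net: PassingNetwork, scores: CentralityScores | None,
                   path, roles: list[str] | None = None,
                   mean_area_m2: np.ndarray | None = None) -> None:
    """Write the network to GraphML for external rendering tools."""
    import networkx as nx

    G = nx.DiGraph()
    for i, node in enumerate(net.nodes):
        attrs: dict = {}
        if roles is not None:
            attrs["role"] = roles[i]
        if scores is not None:
            attrs["closeness"] = float(scores.closeness[i])
            attrs["betweenness"] = float(scores.betweenness[i])
        if mean_area_m2 is not None:
            attrs["mean_area_m2"] = float(mean_area_m2[i])
        G.add_node(node, **attrs)
    for i, v in enumerate(net.nodes):
        for j, w in enumerate(net.nodes):
            if net.A[i, j] > 0:
                G.add_edge(v, w, passes=int(net.A[i, j]))
    nx.write_graphml(G, path)


def import_network(path) -> PassingNetwork:
    """Round-trip companion of :func:`export_network`."""
    import networkx as nx

    G = nx.read_graphml(path)
    nodes = list(G.nodes)
    A = np.zeros((len(nodes), len(nodes)), dtype=int)
    index = {v: i for i, v in enumerate(nodes)}
    for v, w, attrs in G.edges(data=True):
        A[index[v], index[w]] = int(attrs.get("passes", 1))
    return PassingNetwork(nodes=nodes, A=A)
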