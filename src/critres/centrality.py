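"""Per-residue centrality descriptors of the contact graph.

Eleven measures are computed on hop distances (unit edge weights):

- excentricity and its reciprocal: longest shortest distance from a node;
- degree: contact count;
- sphere degree: sum of the degrees of a node's neighbors (second-level
  degree), and its accumulated variant (SNN) which adds the node's own
  degree;
- mean distance and closeness: per-component sums of shortest distances,
  with closeness = 1 / sum(d) and mean distance = sum(d) / #reachable;
- clustering coefficient o/(n*(n-1)) with o the number of ordered adjacent
  pairs among the n neighbors, and its reciprocal;
- traversity A and B: for every residue pair a single shortest path is
  selected deterministically and each strictly interior residue on it is
  credited once.  Variant A selects the lexicographically smallest
  shortest path by residue index, variant B the lexicographically largest
  (the path found by greedy predecessor tracking that iterates neighbors
  in descending residue index).

Disconnected graphs: distance-based measures are computed within a node's
component; isolated nodes score 0 on every measure, and reciprocals of 0
are defined as 0 so feature tables stay finite.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd

from .contact_graph import ResidueContactGraph

#: Column order of the descriptor profile.
CENTRALITY_COLUMNS = [
    "excentricity",
    "excentricity_inverted",
    "degree",
    "sphere_degree",
    "sphere_degree_accumulated",
    "mean_distance",
    "closeness",
    "clustering_coefficient",
    "clustering_coefficient_inverted",
    "traversity_A",
    "traversity_B",
]


def shortest_path_lengths(g: ResidueContactGraph, source: int) -> dict[int, int]:
    """Hop distances from *source* to every reachable node (BFS)."""
    if not (0 <= source < g.n_nodes):
        raise IndexError(f"node {source} out of range")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_pairs_lengths(g: ResidueContactGraph) -> list[dict[int, int]]:
    return [shortest_path_lengths(g, i) for i in range(g.n_nodes)]


def excentricity(g: ResidueContactGraph, i: int) -> float:
    """Longest shortest distance from node *i*; 0 for isolated nodes."""
    dist = shortest_path_lengths(g, i)
    if len(dist) == 1:
        return 0.0
    return float(max(dist.values()))


def excentricity_inverted(g: ResidueContactGraph, i: int) -> float:
    e = excentricity(g, i)
    return 1.0 / e if e > 0 else 0.0


def degree(g: ResidueContactGraph, i: int) -> int:
    return g.degree(i)


def sphere_degree(g: ResidueContactGraph, i: int) -> int:
    """Sum of neighbor degrees (degree at the second level)."""
    return sum(g.degree(k) for k in g.neighbors(i))


def sphere_degree_accumulated(g: ResidueContactGraph, i: int) -> int:
    """Sphere degree plus the node's own neighbor count (SNN)."""
    return g.degree(i) + sphere_degree(g, i)


def _distance_sums(dist: dict[int, int]) -> tuple[int, int]:
    total = sum(d for d in dist.values())
    reachable = len(dist) - 1
    return total, reachable


def mean_distance(g: ResidueContactGraph, i: int) -> float:
    total, reachable = _distance_sums(shortest_path_lengths(g, i))
    return total / reachable if reachable else 0.0


def closeness(g: ResidueContactGraph, i: int) -> float:
    total, reachable = _distance_sums(shortest_path_lengths(g, i))
    return 1.0 / total if reachable else 0.0


def clustering_coefficient(g: ResidueContactGraph, i: int) -> float:
    nbrs = g.neighbors(i)
    n = len(nbrs)
    if n <= 1:
        return 0.0
    # o = ordered adjacent pairs among the neighbors (2x undirected edges)
    o = sum(1 for a in nbrs for b in nbrs if a < b and b in g.neighbors(a)) * 2
    return o / (n * (n - 1))


def clustering_coefficient_inverted(g: ResidueContactGraph, i: int) -> float:
    c = clustering_coefficient(g, i)
    return 1.0 / c if c > 0 else 0.0


def _select_path(g, s, t, dist_to_t, largest: bool) -> list[int]:
    """Greedy shortest path from s to t, min- or max-index at each step.

    Choosing the extreme-index valid successor at every step yields the
    lexicographically smallest (or largest) shortest path.
    """
    path = [s]
    cur = s
    pick = max if largest else min
    while cur != t:
        cands = [u for u in g.neighbors(cur) if dist_to_t.get(u, -2) == dist_to_t[cur] - 1]
        cur = pick(cands)
        path.append(cur)
    return path


def traversity(g: ResidueContactGraph, variant: str = "A") -> np.ndarray:
    """Interior-node counts over one selected shortest path per residue pair."""
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    largest = variant == "B"
    counts = np.zeros(g.n_nodes, dtype=float)
    lengths = _all_pairs_lengths(g)
    for s in range(g.n_nodes):
        for t in range(s + 1, g.n_nodes):
            d = lengths[t].get(s)
            if d is None or d < 2:
                continue
            path = _select_path(g, s, t, lengths[t], largest)
            for node in path[1:-1]:
                counts[node] += 1
    return counts


def centrality_profile(g: ResidueContactGraph) -> pd.DataFrame:
    """All 11 centrality descriptors, one row per residue."""
    n = g.n_nodes
    lengths = _all_pairs_lengths(g)
    ecc = np.zeros(n)
    meand = np.zeros(n)
    close = np.zeros(n)
    for i in range(n):
        dist = lengths[i]
        if len(dist) > 1:
            ecc[i] = max(dist.values())
            total, reachable = _distance_sums(dist)
            meand[i] = total / reachable
            close[i] = 1.0 / total
    deg = np.array([g.degree(i) for i in range(n)], dtype=float)
    sph = np.array([sphere_degree(g, i) for i in range(n)], dtype=float)
    cc = np.array([clustering_coefficient(g, i) for i in range(n)])
    with np.errstate(divide="ignore"):
        ecc_inv = np.where(ecc > 0, 1.0 / np.where(ecc > 0, ecc, 1), 0.0)
        cc_inv = np.where(cc > 0, 1.0 / np.where(cc > 0, cc, 1), 0.0)
    return pd.DataFrame(
        {
            "excentricity": ecc,
            "excentricity_inverted": ecc_inv,
            "degree": deg,
            "sphere_degree": sph,
            "sphere_degree_accumulated": deg + sph,
            "mean_distance": meand,
            "closeness": close,
            "clustering_coefficient": cc,
            "clustering_coefficient_inverted": cc_inv,
            "traversity_A": traversity(g, "A"),
            "traversity_B": traversity(g, "B"),
        },
        columns=CENTRALITY_COLUMNS,
    )
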