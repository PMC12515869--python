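"""Molecular complex detection (MCODE) on protein-interaction graphs.

Vertex weighting by the density of the highest k-core of each closed
neighbourhood, seeded breadth-first expansion with a weight threshold
relative to the seed, and density x size cluster scoring.  Defaults mirror
the published tool (node score cutoff 0.2, haircut on, fluff off).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


def _check_simple(graph: nx.Graph) -> None:
    if any(u == v for u, v in graph.edges):
        raise ValueError("self-loops are not allowed")


def density(graph: nx.Graph) -> float:
    """Simple-graph density 2E / (n(n-1)); 0 for graphs with < 2 nodes."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph with minimum degree >= k (iterative pruning)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    _check_simple(graph)
    return nx.k_core(graph, k)


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: k_max x density of the highest k-core of N[v].

    The closed neighbourhood of each node is reduced to its highest-order
    core; the weight is that core number times the core's density.  Isolated
    nodes weigh 0.
    """
    _check_simple(graph)
    weights: dict[str, float] = {}
    for v in graph.nodes:
        closed = list(graph.neighbors(v)) + [v]
        sub = graph.subgraph(closed)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        core = sub.subgraph([u for u, c in core_numbers.items() if c >= k_max])
        weights[v] = k_max * density(core)
    return weights


def cluster_score(graph: nx.Graph, members) -> float:
    """Cluster score = induced-subgraph density x member count."""
    members = set(members)
    if len(members) < 2:
        raise ValueError("a cluster needs at least 2 members")
    sub = graph.subgraph(members)
    return density(sub) * len(members)


@dataclass(frozen=True)
class Cluster:
    """A detected molecular complex."""

    members: frozenset[str]
    score: float
    seed: str

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def mcode_find_complexes(graph: nx.Graph, node_score_cutoff: float = 0.2,
                         haircut: bool = True, fluff: bool = False,
                         fluff_threshold: float = 0.8,
                         max_depth: int = 100) -> list[Cluster]:
    """Seeded complex detection.

    Seeds are processed in descending vertex weight (ties lexicographic);
    from each unvisited seed a breadth-first expansion includes unvisited
    neighbours whose weight is at least ``(1 - node_score_cutoff)`` times
    the seed weight, up to ``max_depth`` hops.  Post-processing drops
    candidates without a 2-core, optionally removes singly-connected members
    (haircut) and optionally adds boundary neighbours whose closed
    neighbourhood is denser than ``fluff_threshold`` (fluff).  Clusters are
    returned in descending score, ties broken by member list.
    """
    if not 0.0 <= node_score_cutoff <= 1.0:
        raise ValueError("node_score_cutoff must lie in [0, 1]")
    if not 0.0 <= fluff_threshold <= 1.0:
        raise ValueError("fluff_threshold must lie in [0, 1]")
    _check_simple(graph)
    weights = vertex_weights(graph)
    seeds = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    clusters: list[Cluster] = []
    for seed in seeds:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for node in frontier:
                for nb in sorted(graph.neighbors(node)):
                    if nb in visited:
                        continue
                    if weights[nb] >= threshold:
                        visited.add(nb)
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        sub = graph.subgraph(members)
        two_core = nx.k_core(sub, 2)
        if two_core.number_of_nodes() == 0:
            continue
        if haircut:
            kept = {v for v in members
                    if sub.degree(v) >= 2}
            # nodes shaved off stay available to later seeds
            visited -= members - kept
            members = kept
        if fluff:
            boundary = set()
            for v in sorted(members):
                for nb in sorted(graph.neighbors(v)):
                    if nb in members or nb in boundary:
                        continue
                    closed = list(graph.neighbors(nb)) + [nb]
                    if density(graph.subgraph(closed)) > fluff_threshold:
                        boundary.add(nb)
            members |= boundary
        if len(members) < 2:
            continue
        clusters.append(Cluster(members=frozenset(members),
                                score=cluster_score(graph, members),
                                seed=seed))
    clusters.sort(key=lambda c: (-c.score, c.sorted_members()))
    return clusters
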