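"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
betweenness by explicit shortest-path enumeration, hypergeometric tails by
enumeration of all draws, modularity optima by exhaustive partition search,
and coverage optima by exhaustive subset search.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Tuple

import networkx as nx
import pytest

from vhenet.types import GeneNetwork, Interactome, NodeRole


# ---------------------------------------------------------------------------
# construction helpers


def make_network(edges: Iterable[Tuple[str, str]], isolated: Iterable[str] = ()) -> GeneNetwork:
    """A GeneNetwork with all connected nodes as DEGs and degree-0 DEG extras."""
    g = nx.Graph()
    g.add_edges_from((a.upper(), b.upper()) for a, b in edges)
    g.add_nodes_from(s.upper() for s in isolated)
    return GeneNetwork(g, {n: NodeRole.DEG for n in g.nodes})


@pytest.fixture
def toy_interactome() -> Interactome:
    return Interactome(
        [("A", "L"), ("L", "C"), ("A", "B"), ("C", "D"), ("L", "E"), ("E", "F")]
    )


# ---------------------------------------------------------------------------
# oracles


def brute_force_betweenness(graph: nx.Graph) -> Tuple[Dict, Dict]:
    """Unnormalized node and edge betweenness by enumerating shortest paths.

    Every unordered node pair contributes 1, split equally over its shortest
    paths; endpoints are not counted for node betweenness.
    """

    def all_simple_paths(s, t):
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in graph[u]:
                if v not in path:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    node_b = {v: 0.0 for v in graph.nodes}
    edge_b = {frozenset(e): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        shortest_len = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == shortest_len]
        w = 1.0 / len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                node_b[v] += w
            for a, b in zip(p, p[1:]):
                edge_b[frozenset((a, b))] += w
    return node_b, edge_b


def brute_force_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws from a labelled universe."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def iter_set_partitions(items: List) -> Iterable[List[List]]:
    """All set partitions via restricted growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def emit():
        blocks: Dict[int, List] = {}
        for i, b in enumerate(rgs):
            blocks.setdefault(b, []).append(items[i])
        return [blocks[b] for b in sorted(blocks)]

    while True:
        yield emit()
        # next restricted growth string
        i = n - 1
        while i > 0:
            if rgs[i] <= max(rgs[:i]):
                break
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        for j in range(i + 1, n):
            rgs[j] = 0


def brute_force_best_modularity(network: GeneNetwork, max_modules: int = None) -> float:
    """Maximum Newman modularity over all partitions (optionally bounded)."""
    from vhenet.clustering import modularity

    nodes = sorted(network.graph.nodes)
    best = -math.inf
    for blocks in iter_set_partitions(nodes):
        if max_modules is not None and len(blocks) > max_modules:
            continue
        assignment = {g: i for i, block in enumerate(blocks) for g in block}
        best = max(best, modularity(network, assignment))
    return best


def brute_force_max_coverage(sets: Dict[str, frozenset], k: int) -> int:
    """Largest union achievable with any k of the sets, by exhaustion."""
    best = 0
    for combo in itertools.combinations(sorted(sets), min(k, len(sets))):
        union = set().union(*(sets[d] for d in combo))
        best = max(best, len(union))
    return best


def brute_force_min_linkers(
    seed_genes: List[str], interactome: Interactome, max_size: int = 4
):
    """Smallest non-seed subset whose addition connects all covered seeds."""
    graph = interactome.graph
    active = [s for s in seed_genes if s in graph]
    candidates = sorted(set(graph.nodes) - set(seed_genes))
    for size in range(0, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            sub = graph.subgraph(active + list(combo))
            for comp in nx.connected_components(sub):
                if set(active) <= comp:
                    return set(combo)
    return None
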