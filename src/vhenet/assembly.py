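"""Disease-network assembly: connect DEG and QTL seed genes over a reference
interactome by adding a minimal set of non-seed linker genes.

The linker search is a greedy Steiner-tree-style approximation: repeatedly add
the non-seed interactome gene that merges the largest number of currently
distinct seed components (ties broken by smaller interactome degree, then
lexicographically), falling back to the interior of a shortest
between-component interactome path when no single gene merges two components,
and finally pruning linkers whose removal leaves connectivity unchanged. Seed
genes absent from the interactome altogether are reported as isolated and kept
in the assembled network as degree-0 nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

import networkx as nx

from .types import GeneNetwork, Interactome, NodeRole, SeedGene, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "LinkerSearchResult",
    "identify_isolated_seeds",
    "find_linkers",
    "assemble_network",
    "seeds_from_lists",
]


@dataclass
class LinkerSearchResult:
    linkers: frozenset
    connected_components_before: int
    connected_components_after: int
    isolated_seeds: list

    def __post_init__(self) -> None:
        if self.connected_components_after > self.connected_components_before:
            raise ValueError("linker search increased the component count")


def seeds_from_lists(deg_genes: Iterable[str], qtl_genes: Iterable[str]) -> List[SeedGene]:
    """Merge DEG and QTL gene lists into seeds.

    A gene present in both layers keeps origin DEG and is counted once.
    """
    seeds = {}
    for g in deg_genes:
        seeds[normalize_symbol(g)] = SeedGene(g, "DEG")
    for g in qtl_genes:
        g = normalize_symbol(g)
        if g not in seeds:
            seeds[g] = SeedGene(g, "QTL")
    return [seeds[g] for g in sorted(seeds)]


def _seed_names(seeds: Iterable) -> List[str]:
    names = []
    for s in seeds:
        names.append(s.gene if isinstance(s, SeedGene) else normalize_symbol(s))
    return sorted(set(names))


def identify_isolated_seeds(seeds: Iterable, interactome: Interactome) -> List[str]:
    """Seed genes with no interaction data at all, sorted lexicographically."""
    names = _seed_names(seeds)
    if not names:
        raise ValueError("no seed genes supplied")
    return [g for g in names if g not in interactome.nodes]


def _candidate_linkers(seed_set: Set[str], graph: nx.Graph, max_path_len: int) -> Set[str]:
    """Non-seed genes within ``max_path_len`` interactome hops of >= 2 seeds."""
    coverage: dict = {}
    for s in seed_set:
        if s not in graph:
            continue
        dist = nx.single_source_shortest_path_length(graph, s, cutoff=max_path_len)
        for v in dist:
            if v not in seed_set:
                coverage[v] = coverage.get(v, 0) + 1
    return {v for v, c in coverage.items() if c >= 2}


def _n_components(graph: nx.Graph, nodes: Set[str]) -> int:
    if not nodes:
        return 0
    return nx.number_connected_components(graph.subgraph(nodes))


def _bridge_path(graph: nx.Graph, current: Set[str]) -> List[str]:
    """Interior of a shortest interactome path between two components of the
    current node set; empty when no such path exists."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph.subgraph(current))),
        key=lambda c: c[0],
    )
    if len(comps) <= 1:
        return []
    source = set(comps[0])
    other = {v: i for i, comp in enumerate(comps[1:], start=1) for v in comp}
    # Multi-source BFS from the first component, deterministic via sorted adjacency.
    parents = {v: None for v in source}
    frontier = sorted(source)
    best = None
    while frontier and best is None:
        nxt = []
        for u in frontier:
            for v in sorted(graph[u]):
                if v in parents:
                    continue
                parents[v] = u
                if v in other:
                    best = v if best is None or v < best else best
                elif v not in current:
                    nxt.append(v)
        frontier = sorted(set(nxt))
    if best is None:
        return []
    path = []
    v = parents[best]
    while v is not None and v not in source:
        path.append(v)
        v = parents[v]
    return [p for p in path if p not in current]


def find_linkers(
    seeds: Iterable, interactome: Interactome, max_path_len: int = 3
) -> LinkerSearchResult:
    """Find a small set of non-seed linker genes connecting the seeds.

    Post-condition: after adding the linkers, all non-isolated seeds lie in a
    single connected component whenever the interactome permits, and the
    linker set is setwise-minimal (removing any one linker breaks
    connectivity).
    """
    names = _seed_names(seeds)
    if not names:
        raise ValueError("no seed genes supplied")
    graph = interactome.graph
    isolated = [g for g in names if g not in graph]
    active = set(names) - set(isolated)
    before = _n_components(graph, active)

    candidates = _candidate_linkers(set(names), graph, max_path_len)
    chosen: List[str] = []
    current = set(active)
    while _n_components(graph, current) > 1:
        comps = list(nx.connected_components(graph.subgraph(current)))
        comp_id = {v: i for i, comp in enumerate(comps) for v in comp}
        best = None
        best_key = None
        for v in candidates - current:
            merged = {comp_id[u] for u in graph[v] if u in comp_id}
            if len(merged) < 2:
                continue
            key = (-len(merged), graph.degree(v), v)
            if best_key is None or key < best_key:
                best, best_key = v, key
        if best is not None:
            chosen.append(best)
            current.add(best)
            continue
        bridge = _bridge_path(graph, current)
        if not bridge:
            break  # interactome does not permit further merging
        chosen.extend(bridge)
        current.update(bridge)

    # Prune: drop any linker whose removal leaves the component count unchanged.
    pruned = True
    while pruned:
        pruned = False
        target = _n_components(graph, current)
        for v in sorted(chosen):
            trial = current - {v}
            if _n_components(graph, trial) == target:
                chosen.remove(v)
                current = trial
                pruned = True
                break

    after = _n_components(graph, current)
    logger.info(
        "linker search: %d seed component(s) -> %d with %d linker(s); %d isolated seed(s)",
        before,
        after,
        len(chosen),
        len(isolated),
    )
    return LinkerSearchResult(
        linkers=frozenset(chosen),
        connected_components_before=before,
        connected_components_after=after,
        isolated_seeds=isolated,
    )


def assemble_network(
    seeds: Sequence[SeedGene], linkers: Iterable[str], interactome: Interactome
) -> GeneNetwork:
    """Induce the disease network on seeds ∪ linkers with role-typed nodes.

    Isolated seeds are retained as degree-0 nodes carrying their seed role;
    the edge set is exactly the interactome edges among the retained nodes.
    """
    roles = {}
    for s in seeds:
        if not isinstance(s, SeedGene):
            raise TypeError("seeds must be SeedGene records")
        if s.gene in roles and roles[s.gene] != NodeRole(s.origin.value):
            raise ValueError(f"conflicting roles for seed {s.gene}")
        roles[s.gene] = NodeRole(s.origin.value)
    for g in linkers:
        g = normalize_symbol(g)
        if g in roles:
            raise ValueError(f"linker {g} is also a seed")
        roles[g] = NodeRole.LINKER

    graph = nx.Graph()
    graph.add_nodes_from(roles)
    sub = interactome.graph.subgraph([g for g in roles if g in interactome.nodes])
    graph.add_edges_from(sub.edges(data=True))
    return GeneNetwork(graph, roles)
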