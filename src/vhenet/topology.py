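"""Network topology analysis: degree and betweenness centrality, top-fraction
hub flagging, and a power-law degree-distribution diagnostic.

Betweenness is computed exactly on the undirected simple graph from all-pairs
shortest paths, unnormalized (raw pair counts; each unordered pair counted
once), so small-graph results can be checked against explicit path
enumeration. The hub rule is the top 10% by score with floor rounding (never
fewer than one), ties at the cutoff resolved lexicographically after score —
on a 78-gene network this flags 7 hub genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .types import GeneNetwork

__all__ = ["CentralityReport", "PowerLawFit", "compute_centralities", "flag_hubs", "fit_power_law"]


@dataclass
class CentralityReport:
    node_degree: Dict[str, int]
    node_betweenness: Dict[str, float]
    edge_betweenness: Dict[frozenset, float]
    hub_nodes: List[str]
    hub_edges: List[frozenset]

    def __post_init__(self) -> None:
        if sum(self.node_degree.values()) != 2 * len(self.edge_betweenness):
            raise ValueError("degree sum inconsistent with edge count")
        if any(v < 0 for v in self.node_betweenness.values()):
            raise ValueError("negative node betweenness")
        if any(v < 0 for v in self.edge_betweenness.values()):
            raise ValueError("negative edge betweenness")


@dataclass
class PowerLawFit:
    exponent: float
    r_squared: float
    n_degree_bins: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent):
            raise ValueError("non-finite power-law exponent")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


def compute_centralities(network: GeneNetwork, hub_fraction: float = 0.10) -> CentralityReport:
    """Exact degree, node betweenness and edge betweenness, plus hub lists.

    Connected components are handled independently by the shortest-path
    counting itself; isolated nodes get betweenness 0.
    """
    graph = network.graph
    if graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    node_degree = {g: int(d) for g, d in graph.degree()}
    node_bet = nx.betweenness_centrality(graph, normalized=False)
    edge_bet = {
        frozenset(e): v
        for e, v in nx.edge_betweenness_centrality(graph, normalized=False).items()
    }
    report = CentralityReport(
        node_degree=node_degree,
        node_betweenness={g: float(v) for g, v in node_bet.items()},
        edge_betweenness={e: float(v) for e, v in edge_bet.items()},
        hub_nodes=[],
        hub_edges=[],
    )
    report.hub_nodes, report.hub_edges = flag_hubs(report, hub_fraction)
    return report


def _top_fraction(scores: dict, fraction: float, keyfunc) -> list:
    n = max(1, int(fraction * len(scores)))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], keyfunc(kv[0])))
    return [k for k, _ in ranked[:n]]


def flag_hubs(report: CentralityReport, fraction: float = 0.10) -> Tuple[list, list]:
    """Top-``fraction`` nodes by degree and edges by betweenness (floor, min 1)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("hub fraction must be in (0, 1]")
    hub_nodes = _top_fraction(report.node_degree, fraction, lambda g: g)
    hub_edges = _top_fraction(report.edge_betweenness, fraction, lambda e: tuple(sorted(e)))
    return hub_nodes, hub_edges


def fit_power_law(report) -> PowerLawFit:
    """Log–log least-squares fit of the empirical degree histogram.

    Accepts a :class:`CentralityReport` or a plain gene→degree mapping. Fits
    log(count) against log(degree) over distinct positive degrees (zero-count
    degrees carry no histogram mass and degree-0 nodes cannot be
    log-transformed, so both are skipped) and returns exponent = −slope. A
    scale-free network yields exponent roughly in [1.5, 3.5] with high r².
    """
    node_degree = report.node_degree if isinstance(report, CentralityReport) else report
    degrees = [d for d in node_degree.values() if d > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValueError("degree distribution too degenerate")
    fit = stats.linregress(np.log(values), np.log(counts))
    return PowerLawFit(
        exponent=-float(fit.slope),
        r_squared=float(fit.rvalue) ** 2,
        n_degree_bins=int(len(values)),
    )
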