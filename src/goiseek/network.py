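"""Cell-specific network restriction and topology summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .types import GeneSet, NetworkEdgeList

__all__ = ["TopologySummary", "restrict_to_genes", "topology_summary"]


@dataclass(frozen=True)
class TopologySummary:
    """Basic undirected-graph statistics of an edge list.

    ``avg_clustering`` and ``degree_assortativity`` are ``None`` when
    undefined (empty network; constant degrees for assortativity).
    """

    n_nodes: int
    n_edges: int
    n_components: int
    avg_clustering: Optional[float]
    degree_assortativity: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "avg_clustering": self.avg_clustering,
            "degree_assortativity": self.degree_assortativity,
        }


def restrict_to_genes(network: NetworkEdgeList, expressed: GeneSet) -> NetworkEdgeList:
    """Keep exactly the edges whose both endpoints are in ``expressed``."""
    keep = set(expressed)
    return NetworkEdgeList.from_edges(
        (a, b, s) for a, b, s in network.edges() if a in keep and b in keep
    )


def topology_summary(network: NetworkEdgeList) -> TopologySummary:
    """Node/edge/component counts, mean local clustering and assortativity.

    Local clustering of degree-0/1 nodes counts as 0.  Degree assortativity is
    the Pearson correlation of endpoint degrees over both orientations of
    every edge; it is undefined (``None``) when degrees are constant.
    """
    if len(network) == 0:
        return TopologySummary(0, 0, 0, None, None)
    g = network.to_networkx()
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    n_components = nx.number_connected_components(g)
    avg_clustering = float(nx.average_clustering(g))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            assort = float(nx.degree_assortativity_coefficient(g))
        except (ZeroDivisionError, ValueError):
            assort = float("nan")
    degree_assortativity = None if assort != assort else assort
    return TopologySummary(
        n_nodes, n_edges, n_components, avg_clustering, degree_assortativity
    )
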