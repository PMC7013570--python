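"""Social-network measures for disease networks.

Conventions follow common network-analysis practice for directed graphs
rendered in Gephi-style tools: density uses the directed formula
E / (N·(N−1)) by default, while clustering, diameter and average path
length are computed on the undirected unweighted projection (path measures
over the largest connected component).  Both density conventions are
available and the one used is recorded in the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Union

import networkx as nx
import pandas as pd

from .attribution import FinalDiseaseNetwork, final_to_networkx
from .network import DiseaseNetwork, to_networkx


@dataclass
class NetworkSummary:
    label: str
    n_nodes: int
    n_edges: int
    density: float
    diameter: float
    avg_clustering: float
    avg_path_length: float
    density_convention: str
    largest_component_share: float

    def to_dict(self) -> dict:
        return asdict(self)


def _positive_digraph(
    net: Union[DiseaseNetwork, FinalDiseaseNetwork, nx.DiGraph],
) -> nx.DiGraph:
    """Directed graph of nodes/edges with positive frequency, weight or score."""
    if isinstance(net, nx.DiGraph):
        return net
    if isinstance(net, FinalDiseaseNetwork):
        return final_to_networkx(net, prune_zero=True)
    g = to_networkx(net)
    g.remove_edges_from(
        [(u, v) for u, v, w in g.edges(data="weight") if w <= 0]
    )
    g.remove_nodes_from(
        [n for n, f in g.nodes(data="frequency") if f <= 0]
    )
    return g


def summarize(
    net: Union[DiseaseNetwork, FinalDiseaseNetwork, nx.DiGraph],
    label: str = "",
    density_convention: str = "directed",
) -> NetworkSummary:
    """Compute node/edge counts, density, diameter, clustering, path length.

    Single-node or edgeless graphs have no defined path measures; they are
    reported as NaN, and density is 0.
    """
    if density_convention not in ("directed", "undirected"):
        raise ValueError("density_convention must be 'directed' or 'undirected'")
    g = _positive_digraph(net)
    n = g.number_of_nodes()
    e = g.number_of_edges()
    und = g.to_undirected()

    if n < 2:
        density = 0.0
    elif density_convention == "directed":
        density = e / (n * (n - 1))
    else:
        density = und.number_of_edges() / (n * (n - 1) / 2)

    avg_clustering = nx.average_clustering(und) if n >= 1 else math.nan

    diameter = math.nan
    avg_path = math.nan
    lcc_share = math.nan
    if n >= 1:
        components = sorted(nx.connected_components(und), key=len, reverse=True)
        lcc = und.subgraph(components[0])
        lcc_share = lcc.number_of_nodes() / n
        if lcc.number_of_nodes() >= 2:
            diameter = float(nx.diameter(lcc))
            avg_path = float(nx.average_shortest_path_length(lcc))

    return NetworkSummary(
        label=label or str(g.graph.get("label", "")),
        n_nodes=n,
        n_edges=e,
        density=float(density),
        diameter=diameter,
        avg_clustering=float(avg_clustering),
        avg_path_length=avg_path,
        density_convention=density_convention,
        largest_component_share=float(lcc_share),
    )


def summary_table(summaries: Iterable[NetworkSummary]) -> pd.DataFrame:
    """One row per network, columns matching the usual measure names."""
    rows = [s.to_dict() for s in summaries]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "n_nodes", "n_edges", "density", "diameter",
            "avg_clustering", "avg_path_length", "density_convention",
            "largest_component_share",
        ],
    )
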