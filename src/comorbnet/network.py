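"""Directed weighted disease networks from admission sequences.

A patient's observation window — an ordered list of admissions, each
carrying a set of comorbidity categories — becomes an *individual disease
network*:

* node frequency of a category = number of episodes whose category set
  contains it (episode-level presence, once per episode however many codes
  of that category were recorded);
* for each episode, every ordered pair of distinct co-occurring categories
  contributes +1 in both directions (same-admission co-occurrence is
  bi-directional);
* for each pair of consecutive episodes (E_i, E_{i+1}), every ordered pair
  (d in E_i, d' in E_{i+1}, d != d') contributes +1 from d to d'.  The same
  category recurring across consecutive episodes does not create a
  self-loop; recurrence is captured by node frequency.

A cohort's *baseline disease network* is the element-wise sum of its
members' individual networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .cohorts import ObservationWindow
from .icd import ComorbidityMap


@dataclass
class DiseaseNetwork:
    """Directed weighted graph over comorbidity categories.

    ``nodes`` maps category → frequency; ``edges`` maps (source, target) →
    weight.  For individual and baseline networks both are non-negative
    integers.
    """

    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop edge {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) endpoint missing from nodes")
            if w < 0:
                raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
        if any(f < 0 for f in self.nodes.values()):
            raise ValueError("negative node frequency")

    @property
    def total_frequency(self) -> int:
        return sum(self.nodes.values())

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())


def network_from_category_sequence(
    episode_categories: Sequence[Iterable[str]],
    meta: Optional[dict] = None,
) -> DiseaseNetwork:
    """Core counting rule, on an ordered sequence of category sets."""
    net = DiseaseNetwork(meta=dict(meta or {}))
    sets = [sorted(set(cats)) for cats in episode_categories]
    for cats in sets:
        for d in cats:
            net.nodes[d] = net.nodes.get(d, 0) + 1
        for u in cats:  # same-admission pairs, both directions
            for v in cats:
                if u != v:
                    net.edges[(u, v)] = net.edges.get((u, v), 0) + 1
    for prev, curr in zip(sets, sets[1:]):  # consecutive-admission pairs
        for u in prev:
            for v in curr:
                if u != v:
                    net.edges[(u, v)] = net.edges.get((u, v), 0) + 1
    net.meta.setdefault("n_patients", 1 if sets else 0)
    net.meta["n_episodes"] = len(sets)
    net.validate()
    return net


def map_window_categories(
    window: ObservationWindow, cmap: ComorbidityMap
) -> list[set[str]]:
    """Map each episode's codes to comorbidity categories.

    Unmapped codes are ignored; index-disease codes (T2DM, CVD) never map
    to a category, so the index diagnoses themselves do not appear as
    network nodes.
    """
    out = []
    for ep in window.qualifying_episodes:
        cats = set()
        for code in ep.codes:
            category = cmap.map_code(code)
            if category is not None:
                cats.add(category)
        out.append(cats)
    return out


def build_individual(
    window: ObservationWindow, cmap: ComorbidityMap
) -> DiseaseNetwork:
    """Individual disease network for one patient's observation window."""
    net = network_from_category_sequence(
        map_window_categories(window, cmap),
        meta={"patient_id": window.patient_id, "n_patients": 1},
    )
    return net


def aggregate(networks: Iterable[DiseaseNetwork], label: str) -> DiseaseNetwork:
    """Element-wise sum of individual networks → a baseline network."""
    out = DiseaseNetwork(meta={"label": label, "n_patients": 0, "n_episodes": 0})
    for net in networks:
        for d, f in net.nodes.items():
            out.nodes[d] = out.nodes.get(d, 0) + f
        for e, w in net.edges.items():
            out.edges[e] = out.edges.get(e, 0) + w
        out.meta["n_patients"] += net.meta.get("n_patients", 1)
        out.meta["n_episodes"] += net.meta.get("n_episodes", 0)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Serialization (GraphML / GEXF for Gephi-style rendering, flat CSV)
# ---------------------------------------------------------------------------


def to_networkx(net: DiseaseNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for d in sorted(net.nodes):
        g.add_node(d, frequency=int(net.nodes[d]))
    for (u, v) in sorted(net.edges):
        g.add_edge(u, v, weight=int(net.edges[(u, v)]))
    for key in sorted(net.meta):
        value = net.meta[key]
        if isinstance(value, (str, int, float, bool)):
            g.graph[key] = value
    return g


def write_graphml(net: DiseaseNetwork, path: Union[str, Path]) -> None:
    nx.write_graphml(to_networkx(net), path)


def write_gexf(net: DiseaseNetwork, path: Union[str, Path]) -> None:
    nx.write_gexf(to_networkx(net), path)


def node_table(net: DiseaseNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [{"category": d, "frequency": net.nodes[d]} for d in sorted(net.nodes)],
        columns=["category", "frequency"],
    )


def edge_table(net: DiseaseNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"source": u, "target": v, "weight": net.edges[(u, v)]}
            for (u, v) in sorted(net.edges)
        ],
        columns=["source", "target", "weight"],
    )
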