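"""Attribution adjustment: merge the two baseline networks into the final
disease network.

A category can be frequent in the dual-disease cohort simply because it is
frequent in diabetic patients generally.  The final network therefore
scores each category (and each transition) by how much more *prevalent in
proportion* it is in the dual-cohort baseline than in the single-cohort
baseline:

    raw(d)   = max(0, freq_AB(d)/Σ freq_AB  −  freq_A(d)/Σ freq_A)
    score(d) = raw(d) / max_d raw(d)        (0 when every raw score is 0)

Proportions make the comparison scale-free (doubling every count in one
baseline changes nothing), clipping keeps only categories more prevalent
in the dual cohort, and the max-normalization puts scores on [0, 1] with
the most exclusive category scoring exactly 1.  Edges are treated
identically using edge-weight proportions.

A two-proportion Z-test annotates every node and edge with a p-value for
the difference in proportions between the two baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd
from scipy import stats as sps

from .network import DiseaseNetwork

ADJUSTMENT_METHOD = "proportion-difference, clipped at 0, max-normalized"


def normalize(values: dict) -> dict:
    """Divide by the maximum; all-zero input stays all-zero."""
    if any(v < 0 for v in values.values()):
        raise ValueError("normalize requires non-negative values")
    top = max(values.values(), default=0.0)
    if top <= 0:
        return {k: 0.0 for k in values}
    return {k: v / top for k, v in values.items()}


def significance(freq_AB: int, total_AB: int, freq_A: int, total_A: int) -> float:
    """Two-sided two-proportion Z-test with pooled variance.

    Degenerate pooled proportions (0 or 1) carry no evidence of a
    difference and return p = 1.
    """
    if total_AB <= 0 or total_A <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= freq_AB <= total_AB and 0 <= freq_A <= total_A):
        raise ValueError("counts must lie within [0, total]")
    pooled = (freq_AB + freq_A) / (total_AB + total_A)
    if pooled <= 0.0 or pooled >= 1.0:
        return 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / total_AB + 1 / total_A))
    z = (freq_AB / total_AB - freq_A / total_A) / se
    return float(2 * sps.norm.sf(abs(z)))


@dataclass
class FinalDiseaseNetwork:
    """Attribution-adjusted network: [0,1] scores plus significance."""

    node_scores: dict[str, float] = field(default_factory=dict)
    edge_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    node_p: dict[str, float] = field(default_factory=dict)
    edge_p: dict[tuple[str, str], float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _adjust(counts_ab: dict, counts_a: dict) -> dict:
    total_ab = sum(counts_ab.values())
    total_a = sum(counts_a.values())
    keys = sorted(set(counts_ab) | set(counts_a))
    raw = {}
    for key in keys:
        p_ab = counts_ab.get(key, 0) / total_ab if total_ab else 0.0
        p_a = counts_a.get(key, 0) / total_a if total_a else 0.0
        raw[key] = max(0.0, p_ab - p_a)
    return normalize(raw)


def _p_values(counts_ab: dict, counts_a: dict, fdr: bool) -> dict:
    total_ab = sum(counts_ab.values())
    total_a = sum(counts_a.values())
    keys = sorted(set(counts_ab) | set(counts_a))
    p = {
        key: significance(
            counts_ab.get(key, 0), total_ab, counts_a.get(key, 0), total_a
        )
        for key in keys
    }
    if fdr and p:
        p = dict(zip(keys, _benjamini_hochberg([p[k] for k in keys])))
    return p


def _benjamini_hochberg(p_values: list[float]) -> list[float]:
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def attribution_adjust(
    net_AB: DiseaseNetwork, net_A: DiseaseNetwork, fdr: bool = False
) -> FinalDiseaseNetwork:
    """Build the final disease network from the two baselines.

    Nodes/edges with zero score are retained (prune on export if desired).
    Raises if the dual-cohort baseline is empty — there is no exposure
    signal to adjust.
    """
    if sum(net_AB.nodes.values()) == 0:
        raise ValueError("empty dual-cohort baseline network")
    final = FinalDiseaseNetwork(
        node_scores=_adjust(net_AB.nodes, net_A.nodes),
        edge_scores=_adjust(net_AB.edges, net_A.edges),
        node_p=_p_values(net_AB.nodes, net_A.nodes, fdr),
        edge_p=_p_values(net_AB.edges, net_A.edges, fdr),
        meta={
            "adjustment": ADJUSTMENT_METHOD,
            "fdr_correction": bool(fdr),
            "baseline_AB": net_AB.meta.get("label", "AB"),
            "baseline_A": net_A.meta.get("label", "A"),
        },
    )
    return final


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def final_to_networkx(
    final: FinalDiseaseNetwork, prune_zero: bool = False
) -> nx.DiGraph:
    g = nx.DiGraph()
    for d in sorted(final.node_scores):
        score = final.node_scores[d]
        if prune_zero and score <= 0:
            continue
        g.add_node(d, score=float(score), p_value=float(final.node_p[d]))
    for (u, v) in sorted(final.edge_scores):
        score = final.edge_scores[(u, v)]
        if prune_zero and score <= 0:
            continue
        if u in g and v in g:
            g.add_edge(u, v, score=float(score), p_value=float(final.edge_p[(u, v)]))
    for key in sorted(final.meta):
        value = final.meta[key]
        if isinstance(value, (str, int, float, bool)):
            g.graph[key] = value
    return g


def write_final_graphml(
    final: FinalDiseaseNetwork, path: Union[str, Path], prune_zero: bool = False
) -> None:
    nx.write_graphml(final_to_networkx(final, prune_zero), path)


def write_final_gexf(
    final: FinalDiseaseNetwork, path: Union[str, Path], prune_zero: bool = False
) -> None:
    nx.write_gexf(final_to_networkx(final, prune_zero), path)


def top_nodes(final: FinalDiseaseNetwork, k: int) -> pd.DataFrame:
    """Top-k comorbidities by normalized node score."""
    ranked = sorted(
        final.node_scores.items(), key=lambda item: (-item[1], item[0])
    )[:k]
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "category": d,
                "score": score,
                "p_value": final.node_p[d],
            }
            for i, (d, score) in enumerate(ranked)
        ],
        columns=["rank", "category", "score", "p_value"],
    )


def top_edges(final: FinalDiseaseNetwork, k: int) -> pd.DataFrame:
    """Top-k transitions (initial condition → next condition) by score."""
    ranked = sorted(
        final.edge_scores.items(), key=lambda item: (-item[1], item[0])
    )[:k]
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "initial_condition": u,
                "next_condition": v,
                "score": score,
                "p_value": final.edge_p[(u, v)],
            }
            for i, ((u, v), score) in enumerate(ranked)
        ],
        columns=["rank", "initial_condition", "next_condition", "score", "p_value"],
    )
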