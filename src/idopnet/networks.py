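"""Personalized, signed, weighted network construction from a fitted system.

A network evaluated at EI value E has one directed edge j' -> j per
selected regulator, weighted by the dependent expression amount
G_{j|j'}(E) (positive = promotion, negative = inhibition), and node sizes
equal to the independent amounts G_j(E).  Because the amounts are
functions of EI, a personalized network for any sample — observed,
interpolated or extrapolated — is obtained by evaluating at that sample's
EI.  Perturbed networks integrate the dependent rate between two EIs and
so quantify how regulation changes between two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .qdode import QdODEResults

__all__ = [
    "ZERO_WEIGHT",
    "build_network_at",
    "build_network_for_sample",
    "perturbed_network",
    "average_networks",
    "classify_interaction",
    "classify_nodes",
    "network_to_edge_table",
    "write_graphml",
]

#: numerical neutrality threshold: |w| below this counts as "no link"
ZERO_WEIGHT = 1e-10


@dataclass
class PerturbationEdge:
    """Integrated regulatory change Delta_{j|j'} between two EI values."""

    source: str
    target: str
    delta: float
    from_ei: float
    to_ei: float


def build_network_at(results: QdODEResults, ei_value: float, extrapolate: bool = False) -> nx.DiGraph:
    """Signed, weighted directed graph of the system at one EI value."""
    lo, hi = results.e[0], results.e[-1]
    if not extrapolate and not (lo - 1e-12 <= ei_value <= hi + 1e-12):
        raise ValueError(
            f"EI {ei_value} outside fitted range [{lo:.4g}, {hi:.4g}]; "
            "pass extrapolate=True to evaluate anyway"
        )
    g = nx.DiGraph(context={"ei": float(ei_value)})
    for gene in results.gene_ids:
        size = float(results.independent_amount(gene, [ei_value])[0])
        g.add_node(gene, size=size)
    for target in results.gene_ids:
        for reg in results.models[target].regulators:
            w = float(results.dependent_amount(target, reg, [ei_value])[0])
            if abs(w) > ZERO_WEIGHT:
                g.add_edge(reg, target, weight=w, sign="+" if w > 0 else "-")
    classify_nodes(g)
    return g


def build_network_for_sample(results: QdODEResults, sample_id: str) -> nx.DiGraph:
    """Personalized network of one sample, evaluated at its own EI."""
    ids = results.model.x.sample_ids
    if sample_id not in ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    ei = float(results.e[ids.index(sample_id)])
    g = build_network_at(results, ei)
    g.graph["context"]["sample"] = sample_id
    return g


def perturbed_network(results: QdODEResults, e1: float, e2: float) -> list[PerturbationEdge]:
    """Edge-wise integrals of the dependent rates from e1 to e2.

    delta > 0 reads as promotion gained over the EI interval, delta < 0 as
    inhibition; deltas are exactly additive over adjacent intervals.
    """
    if e1 >= e2:
        raise ValueError(f"need e1 < e2, got {e1} >= {e2}")
    edges = []
    for target in results.gene_ids:
        for reg in results.models[target].regulators:
            lo, hi = results.dependent_amount(target, reg, [e1, e2])
            edges.append(
                PerturbationEdge(source=reg, target=target, delta=float(hi - lo),
                                 from_ei=float(e1), to_ei=float(e2))
            )
    return edges


def perturbation_graph(results: QdODEResults, e1: float, e2: float) -> nx.DiGraph:
    g = nx.DiGraph(context={"from_ei": float(e1), "to_ei": float(e2)})
    g.add_nodes_from(results.gene_ids)
    for pe in perturbed_network(results, e1, e2):
        if abs(pe.delta) > ZERO_WEIGHT:
            g.add_edge(pe.source, pe.target, weight=pe.delta,
                       sign="+" if pe.delta > 0 else "-")
    classify_nodes(g)
    return g


def average_networks(graphs: list[nx.DiGraph]) -> nx.DiGraph:
    """Edge- and node-wise arithmetic mean of networks on a common node set.

    An edge absent from a graph contributes weight 0; labels are
    recomputed on the averaged graph.
    """
    if not graphs:
        raise ValueError("no graphs to average")
    nodes = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != nodes:
            raise ValueError("graphs have mismatched node sets")
    k = len(graphs)
    out = nx.DiGraph(context={"averaged_over": k})
    for n in graphs[0].nodes:
        size = sum(g.nodes[n].get("size", 0.0) for g in graphs) / k
        out.add_node(n, size=size)
    wsum: dict[tuple, float] = {}
    for g in graphs:
        for u, v, d in g.edges(data=True):
            wsum[(u, v)] = wsum.get((u, v), 0.0) + d["weight"]
    for (u, v), w in wsum.items():
        w /= k
        if abs(w) > ZERO_WEIGHT:
            out.add_edge(u, v, weight=w, sign="+" if w > 0 else "-")
    classify_nodes(out)
    return out


def classify_interaction(w_ji: float, w_ij: float) -> str:
    """Interaction taxonomy for the ordered pair (j' -> j weight, j -> j' weight).

    synergism (+,+); antagonism (-,-); directional synergism (+,0);
    directional antagonism (-,0); synergistic repression (-,+): the
    inhibitor is promoted back by its victim; antagonistic altruism (+,-):
    the promoter is inhibited back; neutral (0,0).
    """
    def s(w):
        return 0 if abs(w) <= ZERO_WEIGHT else (1 if w > 0 else -1)

    a, b = s(w_ji), s(w_ij)
    table = {
        (1, 1): "synergism",
        (-1, -1): "antagonism",
        (1, 0): "directional synergism",
        (0, 1): "directional synergism",
        (-1, 0): "directional antagonism",
        (0, -1): "directional antagonism",
        (-1, 1): "synergistic repression",
        (1, -1): "antagonistic altruism",
        (0, 0): "neutral",
    }
    return table[(a, b)]


def classify_nodes(g: nx.DiGraph) -> nx.DiGraph:
    """Attach social/core/solitary/hub labels in place (labels may co-occur).

    social: more outgoing (active) than incoming (passive) links;
    core: more outgoing links than the per-node average of total links;
    solitary: fewer total links than that average;
    hub: total connectivity strictly above the average.
    """
    n = g.number_of_nodes()
    mean_links = 2.0 * g.number_of_edges() / n if n else 0.0
    for node in g.nodes:
        out_d, in_d = g.out_degree(node), g.in_degree(node)
        total = out_d + in_d
        labels = []
        if out_d > in_d:
            labels.append("social")
        if out_d > mean_links:
            labels.append("core")
        if total < mean_links:
            labels.append("solitary")
        if total > mean_links:
            labels.append("hub")
        g.nodes[node]["labels"] = labels
    return g


def network_to_edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
        for u, v, d in g.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
    for key, val in (g.graph.get("context") or {}).items():
        df[key] = val
    return df


def write_graphml(g: nx.DiGraph, path) -> None:
    h = g.copy()
    h.graph.pop("context", None)
    for node in h.nodes:
        labels = h.nodes[node].get("labels")
        if isinstance(labels, list):
            h.nodes[node]["labels"] = ",".join(labels)
    nx.write_graphml(h, path)
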