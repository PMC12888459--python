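"""Three-method consensus screening and herb–compound–indicator network.

A peak survives for an indicator when it passes all three screens (Pearson
top-k by |r|, grey relational degree above threshold, VIP ≥ 1).  Surviving
compounds, the indicators they serve, and their source herbs form a typed
tripartite graph; compounds are then prioritized by how many of their three
centralities (degree, betweenness, closeness) strictly exceed the
compound-wise medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .gra import GRAResult, grd_screen
from .pearson import CorrelationResult
from .tables import ValidationError

__all__ = ["MethodRules", "ConsensusTable", "ConsensusNetwork", "method_sets",
           "intersect_sets", "union_dedup", "build_network", "median_filter",
           "write_graphml", "write_sif"]


@dataclass(frozen=True)
class MethodRules:
    """Configurable screening rules for the three correlation engines."""

    pearson_top_k: int = 5
    grd_threshold: float = 0.8
    gra_top_k: int = 10
    vip_threshold: float = 1.0


@dataclass
class ConsensusTable:
    """Per-indicator consensus peak sets with the per-method inputs retained."""

    sets: dict[str, list[str]]                      # indicator → sorted peaks
    method_sets: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def indicators(self) -> list[str]:
        return list(self.sets)


def method_sets(pearson_result: CorrelationResult | list[str],
                gra_result: GRAResult | list[str],
                vip_values: pd.Series | list[str],
                rules: MethodRules = MethodRules()) -> dict[str, list[str]]:
    """Apply the per-method selection rules for one indicator.

    Each argument may alternatively be a pre-selected peak list (used when
    reconstructing published per-method top lists).
    """
    if pearson_result is None or gra_result is None or vip_values is None:
        raise ValidationError("all three method results are required")
    if isinstance(pearson_result, CorrelationResult):
        pearson_set = pearson_result.table.index[: rules.pearson_top_k].tolist()
    else:
        pearson_set = list(pearson_result)
    if isinstance(gra_result, GRAResult):
        gra_set = grd_screen(gra_result, threshold=rules.grd_threshold,
                             k=rules.gra_top_k)
    else:
        gra_set = list(gra_result)
    if isinstance(vip_values, pd.Series):
        opls_set = vip_values.index[vip_values >= rules.vip_threshold].tolist()
    else:
        opls_set = list(vip_values)
    return {"pearson": pearson_set, "gra": gra_set, "opls": opls_set}


def intersect_sets(per_indicator: dict[str, dict[str, list[str]]]) -> ConsensusTable:
    """Three-way intersection per indicator, ordered by peak id."""
    sets = {}
    for indicator, methods in per_indicator.items():
        missing = {"pearson", "gra", "opls"} - set(methods)
        if missing:
            raise ValidationError(f"{indicator}: missing method results {missing}")
        common = (set(methods["pearson"]) & set(methods["gra"])
                  & set(methods["opls"]))
        sets[indicator] = sorted(common)
    return ConsensusTable(sets=sets, method_sets=per_indicator)


def union_dedup(table: ConsensusTable | dict[str, list[str]]) -> pd.Series:
    """Deduplicated union of all indicator sets, sorted by peak id.

    Returns a Series: peak id → multiplicity (number of indicators that
    retained it, the overall-rating pseudo-indicator included).
    """
    sets = table.sets if isinstance(table, ConsensusTable) else table
    counts: dict[str, int] = {}
    for peaks in sets.values():
        for p in set(peaks):
            counts[p] = counts.get(p, 0) + 1
    return pd.Series(counts, dtype=int).sort_index().rename("n_indicators")


@dataclass
class ConsensusNetwork:
    """Typed tripartite graph with per-node centralities."""

    graph: nx.Graph
    centralities: pd.DataFrame  # compound rows: betweenness, closeness, degree

    def compound_ids(self) -> list[str]:
        return list(self.centralities.index)


def _closeness(graph: nx.Graph) -> dict:
    # (reachable nodes) / (sum of distances) within the component, the
    # Cytoscape convention (no cross-component rescaling)
    return nx.closeness_centrality(graph, wf_improved=False)


def build_network(table: ConsensusTable | dict[str, list[str]],
                  herb_map: pd.Series | dict,
                  include_overall: bool = True,
                  overall_label: str = "Overall rating") -> ConsensusNetwork:
    """Build the herb–compound–indicator graph and compute centralities.

    Nodes: every consensus compound, one node per indicator (the composite
    overall rating included unless ``include_overall`` is false), and one
    node per source herb.  Edges: compound–indicator for each consensus
    membership and exactly one compound–herb edge, so a compound's degree is
    its indicator count plus one.
    """
    sets = table.sets if isinstance(table, ConsensusTable) else table
    if not include_overall:
        sets = {k: v for k, v in sets.items() if k != overall_label}
    herb_map = pd.Series(herb_map)

    compounds = sorted({p for peaks in sets.values() for p in peaks})
    missing = [p for p in compounds if p not in herb_map.index]
    if missing:
        raise ValidationError(f"compounds without herb assignment: {missing}")

    g = nx.Graph()
    for indicator in sets:
        g.add_node(indicator, kind="indicator")
    for c in compounds:
        g.add_node(c, kind="compound")
        g.add_node(herb_map[c], kind="herb")
        g.add_edge(c, herb_map[c])
    for indicator, peaks in sets.items():
        for p in peaks:
            g.add_edge(p, indicator)

    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = _closeness(g)
    cent = pd.DataFrame(
        {
            "betweenness": [betweenness[c] for c in compounds],
            "closeness": [closeness[c] for c in compounds],
            "degree": [g.degree[c] for c in compounds],
        },
        index=pd.Index(compounds, name="peak_id"),
    )
    return ConsensusNetwork(graph=g, centralities=cent)


def median_filter(centralities: pd.DataFrame, k_of_3: int = 2) -> list[str]:
    """Compounds whose centralities strictly exceed the compound-wise medians.

    A compound is flagged when at least ``k_of_3`` of its degree, betweenness
    and closeness lie strictly above the respective median computed over
    compound nodes only (even counts: midpoint of the central order
    statistics).  Output sorted by peak id.
    """
    if centralities.empty:
        return []
    cols = ["betweenness", "closeness", "degree"]
    medians = centralities[cols].median()
    exceed = (centralities[cols] > medians).sum(axis=1)
    return sorted(centralities.index[exceed >= k_of_3])


def write_graphml(network: ConsensusNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))


def write_sif(network: ConsensusNetwork, path: str | Path) -> None:
    """Simple interaction format for Cytoscape interchange."""
    kinds = nx.get_node_attributes(network.graph, "kind")
    lines = []
    for u, v in sorted(network.graph.edges()):
        # orient compound → partner for readability
        if kinds.get(v) == "compound" and kinds.get(u) != "compound":
            u, v = v, u
        rel = "source_herb" if kinds.get(v) == "herb" else "associated_with"
        lines.append(f"{u}\t{rel}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
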