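"""Confidence-filtered interaction networks and degree-based hub ranking.

Edges below (or at) the confidence threshold are discarded — the filter is
strictly greater-than, matching the ``> 0.7`` convention of STRING-style
high-confidence analyses. Hubs are ranked by degree either within the
subgraph induced by the differential genes (default: only those genes are
displayed, so only their mutual edges count) or, with
``global_degree=True``, by their degree in the full filtered network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from ddipipe.io import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class HubReport:
    """Ranked degree table over the retained genes (degree desc, then gene id)."""

    table: pd.DataFrame  # columns: gene, degree, immune
    n_edges: int
    global_degree: bool

    def top(self, k: int) -> list[str]:
        return list(self.table["gene"].head(k))


def filter_edges(net: InteractionNetwork, min_conf: float = 0.7) -> InteractionNetwork:
    """Keep edges with confidence strictly greater than ``min_conf``."""
    return InteractionNetwork(edges=[e for e in net.edges if e[2] > min_conf])


def to_graph(net: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    for a, b, conf in net.edges:
        g.add_edge(a, b, confidence=conf)
    return g


def induce_and_rank(
    net: InteractionNetwork,
    genes: Iterable[str],
    immune: Iterable[str] = (),
    global_degree: bool = False,
) -> HubReport:
    """Degree ranking of ``genes`` in the (induced or full) network.

    With ``global_degree=False`` only edges whose BOTH endpoints are in
    ``genes`` count; otherwise each gene's degree in the whole filtered
    network is used. Genes absent from the network simply have degree 0 and
    are omitted from the table; an entirely disconnected input produces an
    empty report with a warning.
    """
    gene_set = set(genes)
    immune_set = set(immune)
    graph = to_graph(net)
    if global_degree:
        present = [g for g in gene_set if g in graph]
        degrees = {g: graph.degree(g) for g in present}
        n_edges = graph.number_of_edges()
    else:
        sub = graph.subgraph([g for g in gene_set if g in graph])
        degrees = {g: d for g, d in sub.degree() if d > 0}
        n_edges = sub.number_of_edges()
    if not degrees:
        logger.warning("none of the %d gene(s) has an edge in the network", len(gene_set))
        return HubReport(
            table=pd.DataFrame(columns=["gene", "degree", "immune"]),
            n_edges=0,
            global_degree=global_degree,
        )
    table = pd.DataFrame(
        {
            "gene": list(degrees),
            "degree": list(degrees.values()),
        }
    )
    table["immune"] = table["gene"].isin(immune_set)
    table = table.sort_values(
        by=["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return HubReport(table=table, n_edges=n_edges, global_degree=global_degree)
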