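"""Interaction-network reconstruction over the significant genes.

Given a STRING-export-style edge table (``protein1, protein2,
combined_score``), keep the medium-or-better-confidence edges whose both
endpoints are significantly regulated genes, annotate each node with its
fold change and adjusted p, and report degrees, hubs (nodes with at least
10 interaction partners by default) and connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .de import DEResult
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["InteractionNetwork", "build_network", "find_hubs"]


@dataclass
class InteractionNetwork:
    """Undirected simple graph over significant genes, with DE annotations."""

    graph: nx.Graph
    min_score: float
    n_skipped_unknown: int = 0
    components: list[frozenset[str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        comp_of = {n: i for i, comp in enumerate(self.components) for n in comp}
        rows = [
            {
                "gene": n,
                "log2fc": d.get("log2fc"),
                "p_adj": d.get("p_adj"),
                "degree": self.graph.degree[n],
                "component": comp_of[n],
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene", "log2fc", "p_adj", "degree", "component"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"protein1": min(a, b), "protein2": max(a, b), "combined_score": d["combined_score"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).sort_values(
            ["protein1", "protein2"], ignore_index=True
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _detect_scale(scores: pd.Series) -> float:
    """STRING exports use either a 0-999 integer or 0-1 float score scale."""
    return 999.0 if scores.max() > 1.0 else 1.0


def build_network(
    de: DEResult | pd.DataFrame,
    edges: pd.DataFrame,
    min_score: float | None = None,
) -> InteractionNetwork:
    """Significant-gene subnetwork from an interaction edge table.

    Keeps edges with ``combined_score >= min_score`` whose both endpoints
    are significant genes; isolated significant genes are not represented.
    ``min_score`` defaults to medium confidence (400 on the 0-999 scale,
    0.4 on the 0-1 scale, auto-detected from the score column).  Symbol
    matching is case-insensitive.  Edge symbols absent from the DE table
    are skipped and counted.
    """
    gene_table = de.genes if isinstance(de, DEResult) else de
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edges.columns):
        raise ConfigurationError(f"edge table must have columns {sorted(required)}")

    scale = _detect_scale(edges["combined_score"]) if len(edges) else 999.0
    if min_score is None:
        min_score = 0.4 * scale
    elif not 0 <= min_score <= scale:
        raise ConfigurationError(f"min_score={min_score} outside score scale [0, {scale}]")

    sig = gene_table[gene_table["significant"]] if "significant" in gene_table else gene_table
    by_upper = {g.upper(): g for g in sig.index}
    known_genes = set(gene_table.index.str.upper())

    g = nx.Graph()
    n_skipped = 0
    kept = edges[edges["combined_score"] >= min_score]
    for a, b, score in kept[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        au, bu = str(a).upper(), str(b).upper()
        if au == bu:
            continue  # self-loop
        if au not in known_genes or bu not in known_genes:
            n_skipped += 1
            continue
        if au not in by_upper or bu not in by_upper:
            continue  # known but not significant
        na, nb = by_upper[au], by_upper[bu]
        # multi-edges collapse keeping the maximal score
        if g.has_edge(na, nb):
            g[na][nb]["combined_score"] = max(g[na][nb]["combined_score"], score)
        else:
            g.add_edge(na, nb, combined_score=score)
    if n_skipped:
        logger.info("build_network: %d edges skipped (symbol not in DE table)", n_skipped)

    for n in g.nodes:
        row = sig.loc[n]
        g.nodes[n]["log2fc"] = float(row["log2fc"])
        g.nodes[n]["p_adj"] = float(row["p_adj"])

    components = [frozenset(c) for c in sorted(nx.connected_components(g), key=len, reverse=True)]
    return InteractionNetwork(graph=g, min_score=min_score,
                              n_skipped_unknown=n_skipped, components=components)


def find_hubs(net: InteractionNetwork, min_degree: int = 10) -> pd.DataFrame:
    """Hub nodes: degree >= min_degree, sorted by degree descending.

    Ties break lexicographically; the single top hub is flagged (the
    analysis this mirrors singled out the highest-degree node, fibronectin,
    as the centre of its largest subnetwork).
    """
    rows = [
        {"gene": n, "degree": d}
        for n, d in net.graph.degree
        if d >= min_degree
    ]
    hubs = pd.DataFrame(rows, columns=["gene", "degree"])
    hubs = hubs.sort_values(["degree", "gene"], ascending=[False, True], ignore_index=True)
    hubs["is_top_hub"] = False
    if len(hubs):
        hubs.loc[0, "is_top_hub"] = True
    return hubs
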