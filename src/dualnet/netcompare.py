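"""Overlap analysis of two tissue networks built on a common gene set.

Edges are unordered gene pairs; an *overlapped* edge is significant in both
tissues. Summary percentages are reported with explicit denominators
because different published figures use different ones (the gene universe,
the any-edge gene count, or the larger tissue's connected-gene count).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ggm import GeneNetwork, ShrunkGGM

__all__ = [
    "ComparisonCounts",
    "NetworkComparison",
    "EdgeScatterTable",
    "compare_networks",
    "summarize_counts",
    "edge_scatter",
]

P_FLOOR = 1e-300  # guard before -log10


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to two decimals (0.00 for an empty denominator)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ComparisonCounts:
    """Raw counts feeding the percentage summary."""

    universe: int
    connected_a: int
    edges_a: int
    connected_b: int
    edges_b: int
    any_edge_genes: int
    common_edge_genes: int
    overlapped_edges: int


@dataclass
class NetworkComparison:
    """Edge-level and gene-level classification of two tissue networks."""

    universe: list[str]
    edges_a: set[tuple[str, str]]
    edges_b: set[tuple[str, str]]
    overlapped: set[tuple[str, str]]
    only_a: set[tuple[str, str]]
    only_b: set[tuple[str, str]]
    gene_classes: pd.DataFrame  # gene_id, connected_a, connected_b, any_edge, common_edge, isolated

    @property
    def counts(self) -> ComparisonCounts:
        gc = self.gene_classes
        return ComparisonCounts(
            universe=len(self.universe),
            connected_a=int(gc["connected_a"].sum()),
            edges_a=len(self.edges_a),
            connected_b=int(gc["connected_b"].sum()),
            edges_b=len(self.edges_b),
            any_edge_genes=int(gc["any_edge"].sum()),
            common_edge_genes=int(gc["common_edge"].sum()),
            overlapped_edges=len(self.overlapped),
        )


def _endpoints(edges: set[tuple[str, str]]) -> set[str]:
    out: set[str] = set()
    for a, b in edges:
        out.add(a)
        out.add(b)
    return out


def compare_networks(net_a: GeneNetwork, net_b: GeneNetwork) -> NetworkComparison:
    """Classify edges and genes of two networks over an identical universe."""
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share an identical gene universe")
    edges_a = {tuple(sorted(e)) for e in net_a.edge_set}
    edges_b = {tuple(sorted(e)) for e in net_b.edge_set}
    overlapped = edges_a & edges_b
    conn_a = _endpoints(edges_a)
    conn_b = _endpoints(edges_b)
    any_edge = conn_a | conn_b
    common = _endpoints(overlapped)
    universe = sorted(net_a.nodes)
    gene_classes = pd.DataFrame(
        {
            "gene_id": universe,
            "connected_a": [g in conn_a for g in universe],
            "connected_b": [g in conn_b for g in universe],
            "any_edge": [g in any_edge for g in universe],
            "common_edge": [g in common for g in universe],
            "isolated": [g not in any_edge for g in universe],
        }
    )
    return NetworkComparison(
        universe, edges_a, edges_b, overlapped, edges_a - overlapped, edges_b - overlapped, gene_classes
    )


def summarize_counts(counts: ComparisonCounts | NetworkComparison) -> pd.DataFrame:
    """Counts and percentages with an explicit denominator per row.

    Connected-gene and any-edge percentages use the gene universe;
    common-edge genes are reported against both the any-edge gene count and
    the larger tissue's connected-gene count (published summaries use
    either, depending on the gene set).
    """
    c = counts.counts if isinstance(counts, NetworkComparison) else counts
    larger = max(c.connected_a, c.connected_b)
    rows = [
        ("connected_genes_a", c.connected_a, "universe", c.universe),
        ("edges_a", c.edges_a, "", 0),
        ("connected_genes_b", c.connected_b, "universe", c.universe),
        ("edges_b", c.edges_b, "", 0),
        ("any_edge_genes", c.any_edge_genes, "universe", c.universe),
        ("common_edge_genes", c.common_edge_genes, "any_edge_genes", c.any_edge_genes),
        ("common_edge_genes_vs_larger_tissue", c.common_edge_genes, "larger_tissue_connected", larger),
        ("overlapped_edges", c.overlapped_edges, "", 0),
    ]
    return pd.DataFrame(
        [
            {
                "quantity": name,
                "count": count,
                "denominator_name": dname,
                "denominator": denom,
                "percent": round_percent(count, denom) if dname else float("nan"),
            }
            for name, count, dname, denom in rows
        ]
    )


@dataclass
class EdgeScatterTable:
    """-log10 BH q per tissue for every pair significant in at least one."""

    table: pd.DataFrame  # gene_a, gene_b, neglog10_q_a, neglog10_q_b, class
    critical: float  # -log10(threshold)


def edge_scatter(
    ggm_a: ShrunkGGM, ggm_b: ShrunkGGM, threshold: float = 0.01
) -> EdgeScatterTable:
    """Edge-wise comparison of BH q-values between the two tissues."""
    ta = ggm_a.edge_table.set_index(["gene_a", "gene_b"])
    tb = ggm_b.edge_table.set_index(["gene_a", "gene_b"])
    if not ta.index.equals(tb.index):
        raise ValueError("the two models must test an identical pair universe")
    sig_a = ta["q"] <= threshold
    sig_b = tb["q"] <= threshold
    keep = sig_a | sig_b
    qa = np.maximum(ta.loc[keep, "q"].to_numpy(), P_FLOOR)
    qb = np.maximum(tb.loc[keep, "q"].to_numpy(), P_FLOOR)
    cls = np.where(
        sig_a[keep] & sig_b[keep], "overlapped", np.where(sig_a[keep], "a_only", "b_only")
    )
    table = pd.DataFrame(
        {
            "gene_a": [i for i, _ in ta.index[keep]],
            "gene_b": [j for _, j in ta.index[keep]],
            "neglog10_q_a": -np.log10(qa),
            "neglog10_q_b": -np.log10(qb),
            "class": cls,
        }
    )
    return EdgeScatterTable(table, float(-np.log10(threshold)))
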