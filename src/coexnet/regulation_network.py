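"""Cis/trans classification, trans-network construction and hub scoring.

A significant lncRNA-mRNA pair is *cis* when both loci sit on the same
chromosome with at most 300 kb between the two gene intervals (the gap is
measured between whole intervals under the half-open convention, and the
300,000 bp boundary itself is still cis); it is *trans* when the loci are
farther apart or on different chromosomes. Pairs with a missing locus stay
*unclassified*. Strand is ignored: an "up- and downstream" window is
symmetric around the lncRNA.

Hubs of the trans network are ranked by the maximum neighborhood component
(MNC): the order of the largest connected component of the subgraph induced
by a node's neighborhood. The open-neighborhood form (the cytoHubba
definition) is the default; on a strictly bipartite lncRNA-mRNA graph it is
degenerate (every score is 0 or 1), so a closed-neighborhood mode and an
option to add mRNA-mRNA co-expression edges are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import CoexprPair, correlation_grid
from .diffexpr import DEResult
from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneLocus, ProbeAnnotation

DEFAULT_WINDOW_BP = 300_000
DEFAULT_TOP_K = 100

REGULATION_TABLE_COLUMNS = (
    "lnc_probe",
    "lnc_symbol",
    "mrna_probe",
    "mrna_symbol",
    "r",
    "p_value",
    "n",
    "regulation",
    "distance_bp",
)


@dataclass
class RegulatoryPair:
    """A co-expression pair with its genomic relationship."""

    pair: CoexprPair
    regulation: str  # cis | trans | unclassified
    distance_bp: int | None


@dataclass
class NodeScore:
    """Hub score of one network node."""

    node_symbol: str
    role: str  # lncRNA | mRNA
    degree: int
    mnc: int


def interval_gap(a: GeneLocus, b: GeneLocus) -> int | None:
    """Base pairs strictly between two half-open intervals.

    ``None`` for different chromosomes; 0 when the intervals overlap or
    touch.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_cis_trans(
    pairs: Sequence[CoexprPair],
    ann: ProbeAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[RegulatoryPair]:
    """Label every pair cis/trans by the gap between its gene loci.

    Missing loci yield ``unclassified``; different chromosomes are trans
    with no distance.
    """
    out: list[RegulatoryPair] = []
    for p in pairs:
        lnc_locus = ann.locus(p.lnc_probe) if p.lnc_probe in ann else None
        mrna_locus = ann.locus(p.mrna_probe) if p.mrna_probe in ann else None
        if lnc_locus is None or mrna_locus is None:
            out.append(RegulatoryPair(p, "unclassified", None))
            continue
        gap = interval_gap(lnc_locus, mrna_locus)
        if gap is None:
            out.append(RegulatoryPair(p, "trans", None))
        elif gap <= window_bp:
            out.append(RegulatoryPair(p, "cis", gap))
        else:
            out.append(RegulatoryPair(p, "trans", gap))
    return out


def regulation_counts(rpairs: Sequence[RegulatoryPair]) -> dict[str, int]:
    counts = {"cis": 0, "trans": 0, "unclassified": 0}
    for rp in rpairs:
        counts[rp.regulation] += 1
    return counts


def _display_symbols(rpairs: Sequence[RegulatoryPair]) -> dict[tuple[str, str], str]:
    """Resolve symbol/role collisions: a symbol used by both biotypes gets a
    role suffix on both sides."""
    roles: dict[str, set[str]] = {}
    for rp in rpairs:
        roles.setdefault(rp.pair.lnc_symbol, set()).add("lncRNA")
        roles.setdefault(rp.pair.mrna_symbol, set()).add("mRNA")
    display = {}
    for symbol, rset in roles.items():
        for role in rset:
            display[(symbol, role)] = (
                f"{symbol}({role})" if len(rset) > 1 else symbol
            )
    return display


def build_trans_network(
    rpairs: Sequence[RegulatoryPair], edge_class: str = "trans"
) -> nx.Graph:
    """Undirected bipartite graph of the pairs of one regulation class;
    edge weight is |r|."""
    selected = [rp for rp in rpairs if rp.regulation == edge_class]
    display = _display_symbols(selected)
    g = nx.Graph()
    for rp in selected:
        u = display[(rp.pair.lnc_symbol, "lncRNA")]
        v = display[(rp.pair.mrna_symbol, "mRNA")]
        g.add_node(u, role="lncRNA")
        g.add_node(v, role="mRNA")
        g.add_edge(u, v, weight=abs(rp.pair.r), r=rp.pair.r)
    return g


def add_mrna_coexpression_edges(
    g: nx.Graph,
    m: ExpressionMatrix,
    de: Sequence[DEResult],
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> int:
    """Optionally densify the trans network with mRNA-mRNA co-expression
    edges above the same |r|/p filter. Returns the number of edges added.

    This is an analysis option, not part of the default pipeline: it gives
    the open-neighborhood MNC a non-degenerate ranking on an otherwise
    bipartite graph.
    """
    de_mrna = [r for r in de if r.status != "ns" and r.biotype == "mRNA"]
    present = [r for r in de_mrna if r.gene_symbol in g]
    if len(present) < 2:
        return 0
    X = m.data.loc[[r.probe_id for r in present]].to_numpy(dtype=float)
    r_grid, p_grid = correlation_grid(X, X)
    added = 0
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            rij, pij = r_grid[i, j], p_grid[i, j]
            if not np.isnan(rij) and abs(rij) > r_threshold and pij < alpha:
                u, v = present[i].gene_symbol, present[j].gene_symbol
                if not g.has_edge(u, v):
                    g.add_edge(u, v, weight=abs(float(rij)), r=float(rij))
                    added += 1
    return added


def mnc_scores(g: nx.Graph, neighborhood: str = "open") -> list[NodeScore]:
    """Maximum-neighborhood-component score for every node.

    For node v the subgraph induced on N(v) (open) or N(v) + {v} (closed)
    is examined; the score is the order of its largest connected component.
    Scores are sorted descending, ties broken by symbol.
    """
    if neighborhood not in ("open", "closed"):
        raise ValidationError(f"unknown neighborhood mode {neighborhood!r}")
    adjacency = {v: set(g[v]) for v in g}
    scores: list[NodeScore] = []
    for v in g:
        nodes = set(adjacency[v])
        if neighborhood == "closed":
            nodes.add(v)
        scores.append(
            NodeScore(
                node_symbol=v,
                role=g.nodes[v].get("role", ""),
                degree=g.degree(v),
                mnc=_largest_component(nodes, adjacency),
            )
        )
    scores.sort(key=lambda s: (-s.mnc, s.node_symbol))
    return scores


def _largest_component(nodes: set, adjacency: dict) -> int:
    """Order of the largest connected component of the induced subgraph."""
    remaining = set(nodes)
    best = 0
    while remaining:
        stack = [remaining.pop()]
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            linked = adjacency[u] & remaining
            remaining -= linked
            stack.extend(linked)
        best = max(best, size)
    return best


def top_k_pairs(
    rpairs: Sequence[RegulatoryPair],
    k: int = DEFAULT_TOP_K,
    class_filter: str = "trans",
) -> list[RegulatoryPair]:
    """Strongest k pairs of one class, ranked by |r| descending, then p
    ascending, then (lncRNA symbol, mRNA symbol)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if class_filter not in ("trans", "cis", "any"):
        raise ValidationError(f"unknown class_filter {class_filter!r}")
    selected = [
        rp
        for rp in rpairs
        if class_filter == "any" or rp.regulation == class_filter
    ]
    selected.sort(
        key=lambda rp: (
            -abs(rp.pair.r),
            rp.pair.p_value,
            rp.pair.lnc_symbol,
            rp.pair.mrna_symbol,
        )
    )
    return selected[:k]


def regulation_to_frame(rpairs: Sequence[RegulatoryPair]) -> pd.DataFrame:
    rows = []
    for rp in rpairs:
        row = asdict(rp.pair)
        row["regulation"] = rp.regulation
        row["distance_bp"] = rp.distance_bp
        rows.append(row)
    df = pd.DataFrame(rows, columns=REGULATION_TABLE_COLUMNS)
    df["distance_bp"] = df["distance_bp"].astype("Int64")
    return df


def write_regulation_table(rpairs: Sequence[RegulatoryPair], path: str | Path) -> None:
    regulation_to_frame(rpairs).to_csv(path, sep="\t", index=False, na_rep="")


def scores_to_frame(scores: Sequence[NodeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [asdict(s) for s in scores],
        columns=["node_symbol", "role", "degree", "mnc"],
    )


def write_scores_table(scores: Sequence[NodeScore], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)
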