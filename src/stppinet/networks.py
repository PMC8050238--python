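"""Interval co-expression networks.

For one spatiotemporal interval, every physical interaction in the
brain-expressed interactome is tested for co-expression: the edge is kept
iff the Spearman correlation of the two genes across that interval's
samples exceeds the threshold (0.5 by default).  The query-centred view of
such a network separates CNV (query) genes from their interacting partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import CoexpressionParams, ExpressionMatrix, IntervalKey, QueryGeneSet

logger = logging.getLogger(__name__)

MIN_COEXPRESSION_N = 3


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midranks for ties.

    Defined as the Pearson correlation of the average-rank-transformed
    vectors.  Returns NaN (undefined) when either vector is constant; the
    caller treats such an edge as not co-expressed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < MIN_COEXPRESSION_N:
        raise ValueError(f"need at least {MIN_COEXPRESSION_N} observations, got {x.size}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx_ = np.linalg.norm(rx)
    ny_ = np.linalg.norm(ry)
    if nx_ == 0 or ny_ == 0:
        return float("nan")
    return float(np.clip(rx @ ry / (nx_ * ny_), -1.0, 1.0))


def rank_zscores(values: np.ndarray) -> np.ndarray:
    """Row-wise rank transform, centred and L2-normalised.

    The Spearman correlation of two rows is then the dot product of their
    transformed rows.  Constant rows come back as all-NaN so downstream
    dot products propagate the undefined correlation.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    out = np.full_like(ranks, np.nan, dtype=float)
    ok = norms[:, 0] > 0
    out[ok] = ranks[ok] / norms[ok]
    return out


@dataclass
class IntervalNetwork:
    """Co-expression-filtered PPI network for one interval.

    ``graph`` carries a ``rho`` attribute per edge; isolated nodes are
    dropped (nodes are the union of retained-edge endpoints).
    """

    key: IntervalKey
    graph: nx.Graph
    n_skipped_missing: int = 0
    n_constant: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


def build_interval_network(
    hi_be: nx.Graph,
    m: ExpressionMatrix,
    samples: Sequence[str],
    params: CoexpressionParams | None = None,
    key: IntervalKey | None = None,
) -> IntervalNetwork:
    """Retain interactome edges that are co-expressed within the interval.

    Edges whose genes lack an expression row are skipped and counted (the
    interactome should already be restricted to measured genes, so this
    path only fires on inconsistent inputs).  Edges with a constant
    expression vector get an undefined rho and are not retained.
    """
    params = params or CoexpressionParams()
    key = key or IntervalKey("P?", "R?")
    if len(samples) < MIN_COEXPRESSION_N:
        raise ValueError(
            f"interval {key.label}: {len(samples)} samples < {MIN_COEXPRESSION_N} "
            "required for rank correlation"
        )
    gene_index = {g: i for i, g in enumerate(m.genes)}
    usable = [(a, b) for a, b in hi_be.edges if a in gene_index and b in gene_index]
    n_skipped = hi_be.number_of_edges() - len(usable)
    if n_skipped:
        logger.warning("interval %s: %d interactome edges lack expression rows",
                       key.label, n_skipped)

    g = nx.Graph()
    n_constant = 0
    if usable:
        sub = m.values.loc[:, list(samples)].to_numpy(dtype=float)
        z = rank_zscores(sub)
        ia = np.array([gene_index[a] for a, _ in usable])
        ib = np.array([gene_index[b] for _, b in usable])
        rhos = np.einsum("ij,ij->i", z[ia], z[ib])
        rhos = np.clip(rhos, -1.0, 1.0)
        for (a, b), rho in zip(usable, rhos):
            if np.isnan(rho):
                n_constant += 1
                continue
            if params.passes(float(rho)):
                g.add_edge(a, b, rho=float(rho))
    return IntervalNetwork(key=key, graph=g, n_skipped_missing=n_skipped, n_constant=n_constant)


@dataclass
class QuerySubnetwork:
    """Query-centred view of an interval network.

    Partners are the non-query genes adjacent to at least one query gene.
    Edge kinds: query-query, query-partner, and (optionally, for
    functional-module views) partner-partner.
    """

    key: IntervalKey
    query_nodes: set[str]
    partner_nodes: set[str]
    edges: dict[frozenset[str], str] = field(default_factory=dict)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.query_nodes | self.partner_nodes)
        for pair, kind in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, kind=kind)
        return g

    def partners_of(self, gene: str) -> set[str]:
        out = set()
        for pair, kind in self.edges.items():
            if gene in pair and kind in ("query-partner", "query-query"):
                (other,) = pair - {gene}
                if other in self.partner_nodes:
                    out.add(other)
        return out


def extract_query_subnetwork(
    net: IntervalNetwork,
    q: QueryGeneSet,
    include_partner_partner: bool = False,
) -> QuerySubnetwork:
    """Extract the query genes, their partners and the connecting edges."""
    g = net.graph
    query_nodes = {n for n in q.genes if n in g}
    partner_nodes: set[str] = set()
    for qn in query_nodes:
        partner_nodes.update(g.neighbors(qn))
    partner_nodes -= set(q.genes)

    edges: dict[frozenset[str], str] = {}
    for a, b in g.edges:
        a_q, b_q = a in q.genes, b in q.genes
        if a_q and b_q:
            if a in query_nodes and b in query_nodes:
                edges[frozenset((a, b))] = "query-query"
        elif a_q or b_q:
            edges[frozenset((a, b))] = "query-partner"
        elif include_partner_partner and a in partner_nodes and b in partner_nodes:
            edges[frozenset((a, b))] = "partner-partner"
    return QuerySubnetwork(key=net.key, query_nodes=query_nodes,
                           partner_nodes=partner_nodes, edges=edges)


def write_edge_list(net: IntervalNetwork, path) -> None:
    """Edge-list TSV: gene_a, gene_b, rho, interval."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\trho\tinterval\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['rho']:.6f}\t{net.key.label}\n")
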