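"""Comparison of significant interval networks and driver-gene search.

Covers: node-overlap summaries across networks (Venn-style counts for query
genes and partners separately), per-gene partner-turnover ratios between
two networks with a one-way ANOVA on the ratio groups, and the
diameter-normalised radiality centrality used to call the driver gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import QueryGeneSet
from .networks import IntervalNetwork, QuerySubnetwork

logger = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    """Sharing structure of node sets across k networks."""

    labels: list[str]
    query_sets: dict[str, set[str]]
    partner_sets: dict[str, set[str]]
    query_shared_by: dict[int, int]
    partner_shared_by: dict[int, int]

    def shared_by_all(self, category: str) -> tuple[int, int, float]:
        """(count shared by all networks, union size, fraction)."""
        sets = self.query_sets if category == "query" else self.partner_sets
        if not sets:
            return 0, 0, 0.0
        union = set().union(*sets.values())
        inter = set.intersection(*sets.values()) if sets else set()
        frac = len(inter) / len(union) if union else 0.0
        return len(inter), len(union), frac


def network_overlap(nets: Sequence[QuerySubnetwork]) -> OverlapSummary:
    """Tabulate how many networks each query gene / partner appears in."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to compare")
    labels = [n.key.label for n in nets]
    query_sets = {n.key.label: set(n.query_nodes) for n in nets}
    partner_sets = {n.key.label: set(n.partner_nodes) for n in nets}

    def shared_counts(sets: dict[str, set[str]]) -> dict[int, int]:
        union = set().union(*sets.values()) if sets else set()
        counts = {k: 0 for k in range(1, len(sets) + 1)}
        for gene in union:
            k = sum(gene in s for s in sets.values())
            counts[k] += 1
        return counts

    return OverlapSummary(
        labels=labels,
        query_sets=query_sets,
        partner_sets=partner_sets,
        query_shared_by=shared_counts(query_sets),
        partner_shared_by=shared_counts(partner_sets),
    )


@dataclass
class GenePartnerProfile:
    """Partner turnover of one query gene between two networks.

    Ratios are over the union of the two partner sets, so the three
    components sum to 1.
    """

    gene: str
    partners_a: set[str]
    partners_b: set[str]

    @property
    def r_shared(self) -> float:
        union = self.partners_a | self.partners_b
        return len(self.partners_a & self.partners_b) / len(union)

    @property
    def r_unique_a(self) -> float:
        union = self.partners_a | self.partners_b
        return len(self.partners_a - self.partners_b) / len(union)

    @property
    def r_unique_b(self) -> float:
        union = self.partners_a | self.partners_b
        return len(self.partners_b - self.partners_a) / len(union)


def partner_ratios(
    a: QuerySubnetwork, b: QuerySubnetwork, q: QueryGeneSet
) -> list[GenePartnerProfile]:
    """Per-query-gene unique/shared partner ratios between two networks.

    Query genes with no partners in either network are skipped (and
    logged): their ratios are undefined.
    """
    profiles = []
    skipped = []
    for gene in sorted(q.genes):
        pa = a.partners_of(gene) if gene in a.query_nodes else set()
        pb = b.partners_of(gene) if gene in b.query_nodes else set()
        if not (pa | pb):
            skipped.append(gene)
            continue
        profiles.append(GenePartnerProfile(gene=gene, partners_a=pa, partners_b=pb))
    if skipped:
        logger.info("partner_ratios %s vs %s: %d query genes with empty partner union skipped",
                    a.key.label, b.key.label, len(skipped))
    return profiles


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (F = MS_between / MS_within)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    if n <= k:
        raise ValueError("degenerate degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        f = float("inf") if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return AnovaResult(F=float(f), df_between=df_b, df_within=df_w, p=p)


def partner_ratio_anova(
    a: QuerySubnetwork, b: QuerySubnetwork, q: QueryGeneSet, grouping: str = "three"
) -> AnovaResult:
    """ANOVA over the partner-ratio groups of two networks.

    Default grouping: three groups (unique-to-a, unique-to-b, shared
    ratios), one observation per query gene.  ``grouping='two'`` pools the
    two unique ratios against the shared ratios.
    """
    profiles = partner_ratios(a, b, q)
    if len(profiles) < 2:
        raise ValueError("fewer than 2 query genes with partners; ANOVA undefined")
    ua = [p.r_unique_a for p in profiles]
    ub = [p.r_unique_b for p in profiles]
    sh = [p.r_shared for p in profiles]
    if grouping == "three":
        return one_way_anova([ua, ub, sh])
    if grouping == "two":
        return one_way_anova([ua + ub, sh])
    raise ValueError("grouping must be 'three' or 'two'")


def radiality(net: IntervalNetwork | QuerySubnetwork | nx.Graph) -> pd.DataFrame:
    """Diameter-normalised radiality per node, computed per connected component.

    Within a component of size n >= 2 with unweighted diameter D,
    Rad(v) = (D + 1 - mean_{u != v} d(v, u)) / D.  Nodes adjacent to every
    other node in a D = 1 component score 1; singleton components score 0
    by convention.  Returns a DataFrame indexed by gene with columns
    radiality, degree, component.
    """
    g = net if isinstance(net, nx.Graph) else net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute radiality of an empty network")
    rows = {}
    for comp_id, comp in enumerate(nx.connected_components(g)):
        sub = g.subgraph(comp)
        n = sub.number_of_nodes()
        if n == 1:
            (v,) = comp
            rows[v] = (0.0, g.degree(v), comp_id)
            continue
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            avg = sum(dists[v][u] for u in comp if u != v) / (n - 1)
            rows[v] = ((diam + 1 - avg) / diam, g.degree(v), comp_id)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["radiality", "degree", "component"])
    df.index.name = "gene"
    df["degree"] = df["degree"].astype(int)
    df["component"] = df["component"].astype(int)
    return df.sort_index()


def identify_driver(
    table: pd.DataFrame, candidates: Iterable[str]
) -> tuple[str, float]:
    """The candidate gene with maximal radiality.

    Ties break by higher degree, then lexicographically smaller symbol, so
    the call is deterministic.
    """
    cand = [g for g in candidates if g in table.index]
    if not cand:
        raise ValueError("no candidate gene present in the centrality table")
    sub = table.loc[cand]
    best = sorted(
        sub.itertuples(),
        key=lambda r: (-r.radiality, -r.degree, r.Index),
    )[0]
    return str(best.Index), float(best.radiality)
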