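"""Over-representation analysis of network proteins against gene sets.

Two flavours: Fisher-based enrichment of a network gene list against
curated disease/annotation sets over a fixed background universe
(default 20,240 genes), and hypergeometric term enrichment with the
triple filter p < 0.01, overlap count >= 3, enrichment factor > 1.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection, normalize_gene
from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_BACKGROUND_N = 20240


@dataclass(frozen=True)
class TermEnrichmentParams:
    """Filter thresholds for term enrichment reporting."""

    p_max: float = 0.01
    min_count: int = 3
    min_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members, tab-separated)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        sets[fields[0]] = {normalize_gene(g) for g in fields[2:] if g.strip()}
    return GeneSetCollection(name=name or Path(path).stem, sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sname, members in collection.sets.items():
            fh.write("\t".join([sname, collection.source or "na", *sorted(members)]) + "\n")


def _hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def set_enrichment(
    network_genes: Iterable[str],
    collection: GeneSetCollection,
    background_n: int = DEFAULT_BACKGROUND_N,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of the network genes in each set.

    The 2x2 table per set is [[k, n-k], [K-k, N-n-K+k]] with k the overlap,
    n the network size, K the set size and N the background universe.
    Returns a DataFrame with one row per set, BH-corrected across the
    collection.
    """
    genes = {normalize_gene(g) for g in network_genes}
    if not genes:
        raise ValueError("network gene set is empty")
    n = len(genes)
    rows = []
    for sname, members in collection.sets.items():
        K = len(members)
        union = len(genes | members)
        if background_n < union:
            raise ValueError(
                f"background ({background_n}) smaller than observed union ({union}) for {sname}"
            )
        k = len(genes & members)
        table = np.array([[k, n - k], [K - k, background_n - n - K + k]])
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({
            "set_name": sname, "k": k, "n": n, "K": K, "N": background_n,
            "odds_ratio": float(odds), "p": float(p),
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def term_enrichment(
    query_genes: Iterable[str],
    annotation: GeneSetCollection,
    params: TermEnrichmentParams | None = None,
    background_n: int = DEFAULT_BACKGROUND_N,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with count/factor/p filtering.

    Per term: the cumulative hypergeometric upper tail
    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n) and the enrichment
    factor (k / n) / (K / N) — observed over expected overlap.  Terms pass
    iff p < p_max AND k >= min_count AND factor > min_factor (strict).  BH
    q-values are computed across the whole annotation before filtering.
    """
    params = params or TermEnrichmentParams()
    annotated_universe = set().union(*annotation.sets.values())
    genes = {normalize_gene(g) for g in query_genes}
    n_dropped = len(genes - annotated_universe)
    genes &= annotated_universe
    if n_dropped:
        logger.info("term_enrichment: dropped %d query genes absent from the annotation universe",
                    n_dropped)
    if not genes:
        raise ValueError("no query genes left after restricting to the annotation universe")
    n = len(genes)
    rows = []
    for tname, members in annotation.sets.items():
        K = len(members)
        union = len(genes | members)
        if background_n < union:
            raise ValueError(
                f"background ({background_n}) smaller than observed union ({union}) for {tname}"
            )
        k = len(genes & members)
        p = _hypergeom_tail(k, n, K, background_n)
        factor = (k / n) / (K / background_n)
        rows.append({"term": tname, "k": k, "n": n, "K": K, "N": background_n,
                     "factor": factor, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    keep = (df["p"] < params.p_max) & (df["k"] >= params.min_count) & (df["factor"] > params.min_factor)
    out = df[keep].reset_index(drop=True)
    logger.info("term_enrichment: %d / %d terms pass the filters", len(out), len(df))
    return out
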