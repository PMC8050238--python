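"""Readers and cleaning steps for expression, interaction and gene-list inputs.

This stage turns raw TSV inputs into validated containers: the expression
matrix with sample metadata, the brain-expression filter, the physical
interactome restricted to brain-expressed genes (HI_BE), and the query CNV
gene set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionFilterParams, ExpressionMatrix, QueryGeneSet, normalize_gene

logger = logging.getLogger(__name__)

# BioGRID tab2 column names; a minimal 3-column dialect is also accepted.
TAB2_COLS = {
    "gene_a": "Official Symbol Interactor A",
    "gene_b": "Official Symbol Interactor B",
    "system_type": "Experimental System Type",
}
MINIMAL_COLS = {"gene_a": "gene_a", "gene_b": "gene_b", "system_type": "system_type"}


def read_expression(values_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample-metadata TSV.

    The values file has a leading ``gene`` column; every remaining column
    must appear in the metadata file (``sample_id``, ``stage``,
    ``structure``).  Duplicate gene rows are collapsed by keeping the row
    with the highest mean expression.
    """
    raw = pd.read_csv(values_path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene":
        raise ValueError(f"first column of {values_path} must be 'gene', got {raw.columns[0]!r}")
    raw = raw.set_index("gene")
    raw.index = [normalize_gene(g) for g in raw.index]

    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        if coerced.isna().any():
            gene = raw.index[np.flatnonzero(coerced.isna())[0]]
            raise ValueError(f"missing expression value at gene {gene!r}, sample {col!r}")
        raw[col] = coerced

    if raw.index.duplicated().any():
        means = raw.mean(axis=1)
        keep_pos: dict[str, int] = {}
        for pos, gene in enumerate(raw.index):
            if gene not in keep_pos or means.iloc[pos] > means.iloc[keep_pos[gene]]:
                keep_pos[gene] = pos
        dup_genes = sorted(set(raw.index[raw.index.duplicated()]))
        logger.warning(
            "collapsed %d duplicated gene rows (kept highest-mean row): %s",
            len(dup_genes), ", ".join(dup_genes[:10]),
        )
        raw = raw.iloc[sorted(keep_pos.values())]

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str, "structure": str})
    required = {"sample_id", "stage", "structure"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}, got {list(meta.columns)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id")

    missing = [c for c in raw.columns if c not in meta.index]
    if missing:
        raise ValueError(f"sample columns missing from metadata: {missing}")
    return ExpressionMatrix(raw, meta)


def filter_brain_expressed(
    m: ExpressionMatrix, p: ExpressionFilterParams | None = None
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Apply the brain-expression floor filters.

    A gene is removed when log2(value + offset) stays below the intensity
    floor in every sample, or when the coefficient of variation (population
    sd / mean, on linear values) falls below the CV floor; ``filter_logic``
    in the params switches OR to AND.  Returns the filtered matrix and a
    mapping removed gene -> reason.  Gene order is preserved.
    """
    p = p or ExpressionFilterParams()
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("cannot filter an empty expression matrix")

    vals = m.values.to_numpy(dtype=float)
    log2 = np.log2(vals + p.log2_offset)
    low_intensity = (log2 < p.log2_intensity_min).all(axis=1)

    mean = vals.mean(axis=1)
    sd = vals.std(axis=1)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    low_cv = cv < p.cv_min

    if p.filter_logic == "or":
        drop = low_intensity | low_cv
    else:
        drop = low_intensity & low_cv

    removed: dict[str, str] = {}
    for gene, li, lc, d in zip(m.genes, low_intensity, low_cv, drop):
        if d:
            reasons = []
            if li:
                reasons.append(f"log2 intensity < {p.log2_intensity_min} in all samples")
            if lc:
                reasons.append(f"CV < {p.cv_min}")
            removed[gene] = " and ".join(reasons)
    kept = [g for g in m.genes if g not in removed]
    logger.info("brain-expression filter: kept %d / %d genes", len(kept), m.shape[0])
    return ExpressionMatrix(m.values.loc[kept], m.meta), removed


def read_interactions(path: str | Path, physical_only: bool = True) -> pd.DataFrame:
    """Read an interaction TSV (BioGRID tab2 or minimal dialect).

    Returns a DataFrame with columns gene_a, gene_b, system_type; symbols
    normalized.  Rows whose experimental-system type is not "physical" are
    dropped when ``physical_only``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for dialect in (TAB2_COLS, MINIMAL_COLS):
        if set(dialect.values()).issubset(df.columns):
            table = df[[dialect["gene_a"], dialect["gene_b"], dialect["system_type"]]].copy()
            table.columns = ["gene_a", "gene_b", "system_type"]
            break
    else:
        raise ValueError(
            "interaction file lacks required columns; expected "
            f"{sorted(TAB2_COLS.values())} (tab2) or {sorted(MINIMAL_COLS.values())} (minimal), "
            f"got {list(df.columns)}"
        )
    if len(table) == 0:
        return table
    table["gene_a"] = table["gene_a"].map(normalize_gene)
    table["gene_b"] = table["gene_b"].map(normalize_gene)
    table["system_type"] = table["system_type"].str.strip().str.lower()
    if physical_only:
        n0 = len(table)
        table = table[table["system_type"] == "physical"].reset_index(drop=True)
        logger.info("kept %d / %d physical interaction rows", len(table), n0)
    return table


def build_brain_interactome(table: pd.DataFrame, brain_genes: Iterable[str]) -> nx.Graph:
    """Restrict interactions to brain-expressed genes and clean the graph.

    Keeps rows where both endpoints are brain-expressed, removes self-loops,
    and collapses duplicates (including orientation-swapped duplicates) into
    a simple undirected graph — the brain-expressed interactome (HI_BE).
    """
    brain = set(brain_genes)
    g = nx.Graph()
    n_self = n_dup = 0
    for a, b in zip(table["gene_a"], table["gene_b"]):
        if a == b:
            n_self += 1
            continue
        if a not in brain or b not in brain:
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    logger.info(
        "interactome: %d nodes, %d edges (dropped %d self-loops, %d duplicate rows)",
        g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
    )
    return g


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(normalize_gene(line))
    return genes


def load_query_genes(
    path: str | Path,
    exclusions: Sequence[tuple[str, str]] = (),
    brain_genes: Iterable[str] | None = None,
    name: str = "query",
) -> QueryGeneSet:
    """Load the query (CNV) gene list, applying explicit exclusions and the
    brain-expression restriction.

    ``exclusions`` are (gene, reason) pairs, e.g. locus genes known not to
    be expressed in the tissue.  Every removal is recorded with its reason;
    an empty resulting set is an error.
    """
    listed = read_gene_list(path)
    genes = set(listed)
    excluded: dict[str, str] = {}
    for gene, reason in exclusions:
        gene = normalize_gene(gene)
        if gene in genes:
            genes.discard(gene)
            excluded[gene] = reason
        else:
            logger.warning("exclusion of %s is a no-op (not in list)", gene)
    if brain_genes is not None:
        brain = set(brain_genes)
        for gene in sorted(genes - brain):
            genes.discard(gene)
            excluded[gene] = "not brain-expressed"
    if not genes:
        raise ValueError(f"query gene set from {path} is empty after exclusions")
    logger.info("query set %r: %d genes kept, %d excluded", name, len(genes), len(excluded))
    return QueryGeneSet(name=name, genes=genes, excluded=excluded)
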