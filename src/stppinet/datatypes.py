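"""Core containers shared across the pipeline.

The pipeline operates on three kinds of objects: a genes x samples
expression matrix with per-sample developmental-stage / anatomical-structure
metadata, an undirected physical-interaction graph, and gene sets.  This
module holds the matrix container, parameter dataclasses and the small value
types (interval keys, gene-set records) that every stage exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "normalize_gene",
    "SampleMeta",
    "ExpressionMatrix",
    "ExpressionFilterParams",
    "CoexpressionParams",
    "IntervalKey",
    "QueryGeneSet",
    "GeneSetCollection",
]


def normalize_gene(symbol: str) -> str:
    """Canonical gene identifier: stripped and upper-cased.

    Expression sources and interaction databases disagree on symbol case;
    normalisation is idempotent and raises on empty symbols.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


class SampleMeta(NamedTuple):
    """Per-sample annotation: developmental stage code and structure code."""

    sample_id: str
    stage: int
    structure: str


class ExpressionMatrix:
    """Linear-scale (RPKM-like) expression values with sample metadata.

    Parameters
    ----------
    values
        genes x samples DataFrame; index = normalized gene symbols,
        columns = sample ids.  Values must be finite and non-negative.
    meta
        DataFrame indexed by sample id with columns ``stage`` (int) and
        ``structure`` (str), covering every column of ``values``.
    """

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample columns: {dupes}")
        missing = [c for c in values.columns if c not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values.astype(float)
        self.meta = meta.loc[list(values.columns), ["stage", "structure"]].copy()
        self.meta["stage"] = self.meta["stage"].astype(int)
        self.meta["structure"] = self.meta["structure"].astype(str)

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_meta(self) -> list[SampleMeta]:
        return [
            SampleMeta(sid, int(row.stage), str(row.structure))
            for sid, row in self.meta.iterrows()
        ]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.meta)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.meta.equals(other.meta)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, values_path: str | Path, metadata_path: str | Path) -> None:
        """Write the matrix (first column ``gene``) and the metadata table."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(values_path, sep="\t")
        meta = self.meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


@dataclass(frozen=True)
class ExpressionFilterParams:
    """Brain-expression filter thresholds.

    A gene is dropped when its log2 intensity stays below
    ``log2_intensity_min`` in every sample, or when the coefficient of
    variation of its linear values falls below ``cv_min`` (``filter_logic``
    switches the OR combination to AND).  ``log2_offset`` is the pseudo-count
    added before the log2 transform.
    """

    log2_intensity_min: float = 0.4
    cv_min: float = 0.07
    log2_offset: float = 1.0
    filter_logic: str = "or"

    def __post_init__(self) -> None:
        if self.log2_offset <= 0:
            raise ValueError("log2_offset must be positive")
        if self.filter_logic not in ("or", "and"):
            raise ValueError("filter_logic must be 'or' or 'and'")


@dataclass(frozen=True)
class CoexpressionParams:
    """Edge-retention rule: keep an interacting pair iff Spearman rho
    exceeds ``rho_threshold`` (strictly, unless ``strict`` is False in which
    case >= is used)."""

    rho_threshold: float = 0.5
    strict: bool = True

    def passes(self, rho: float) -> bool:
        if not np.isfinite(rho):
            return False
        return rho > self.rho_threshold if self.strict else rho >= self.rho_threshold


class IntervalKey(NamedTuple):
    """One period x region cell of the spatiotemporal grid, e.g. P1R3."""

    period: str
    region: str

    @property
    def label(self) -> str:
        return f"{self.period}{self.region}"

    @classmethod
    def parse(cls, label: str) -> "IntervalKey":
        # labels are <period><region> with region starting at the last 'R'
        idx = label.rfind("R")
        if idx <= 0:
            raise ValueError(f"cannot parse interval label {label!r}")
        return cls(label[:idx], label[idx:])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class QueryGeneSet:
    """The CNV gene set under study, plus the genes removed on the way in."""

    name: str
    genes: set[str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.genes & set(self.excluded)
        if overlap:
            raise ValueError(f"genes both kept and excluded: {sorted(overlap)}")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), members normalized."""

    name: str
    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for sname, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set {sname!r}")
            self.sets[sname] = {normalize_gene(g) for g in members}


def as_gene_pairs(pairs: Iterable[tuple[str, str]]) -> set[frozenset[str]]:
    """Canonicalize an iterable of gene pairs to unordered, self-loop-free."""
    out: set[frozenset[str]] = set()
    for a, b in pairs:
        if a != b:
            out.add(frozenset((a, b)))
    return out
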