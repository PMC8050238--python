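"""Per-interval co-expression fractions and Fisher enrichment vs controls.

The test statistic is the fraction of candidate gene pairs that are
co-expressed (Spearman rho above threshold) within one spatiotemporal
interval.  The query universe (interactome edges touching the CNV set) is
compared against three control universes with a one-sided Fisher's exact
test; p-values are Benjamini-Hochberg corrected across intervals within
each control comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CoexpressionParams, ExpressionMatrix, IntervalKey, QueryGeneSet
from .networks import MIN_COEXPRESSION_N, rank_zscores

logger = logging.getLogger(__name__)

UNIVERSE_KINDS = ("query_ppi", "common_cnv_ppi", "query_all_brain", "all_ppi")
CONTROL_KINDS = ("common_cnv_ppi", "query_all_brain", "all_ppi")


@dataclass
class PairUniverse:
    """A named universe of candidate gene pairs.

    ``requires_ppi`` records whether membership demanded a physical
    interaction (False only for the query x all-brain-genes control).
    """

    name: str
    pairs: set[frozenset[str]]
    requires_ppi: bool = True

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValueError(f"self-pair or malformed pair in universe {self.name}: {set(p)}")


@dataclass
class FractionResult:
    interval: IntervalKey
    universe: str
    n_coexpressed: int
    n_total: int
    n_unmeasurable: int = 0

    @property
    def fraction(self) -> float:
        return self.n_coexpressed / self.n_total

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError(f"universe {self.universe} has no pairs in {self.interval.label}")
        if not 0 <= self.n_coexpressed <= self.n_total:
            raise ValueError("inconsistent pair counts")


@dataclass
class EnrichmentResult:
    interval: IntervalKey
    control: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    q: float = float("nan")


def build_pair_universe(
    kind: str,
    q: QueryGeneSet | None = None,
    hi_be: nx.Graph | None = None,
    brain_genes: Iterable[str] | None = None,
    control_cnv_genes: Iterable[str] | None = None,
) -> PairUniverse:
    """Construct one of the four candidate-pair universes.

    query_ppi        interactome edges with >= 1 endpoint in the query set
    common_cnv_ppi   interactome edges with >= 1 endpoint in the control CNV set
    query_all_brain  every pair {query gene, brain-expressed gene} (no PPI)
    all_ppi          every interactome edge
    """
    if kind not in UNIVERSE_KINDS:
        raise ValueError(f"unknown pair universe kind {kind!r}; expected one of {UNIVERSE_KINDS}")
    if kind == "query_all_brain":
        if q is None or brain_genes is None:
            raise ValueError("query_all_brain needs the query set and brain gene universe")
        pairs = {
            frozenset((g, b))
            for g in q.genes
            for b in brain_genes
            if b != g
        }
        return PairUniverse(kind, pairs, requires_ppi=False)

    if hi_be is None:
        raise ValueError(f"{kind} needs the interactome")
    edges = {frozenset((a, b)) for a, b in hi_be.edges}
    if kind == "all_ppi":
        pairs = edges
    elif kind == "query_ppi":
        if q is None:
            raise ValueError("query_ppi needs the query set")
        pairs = {e for e in edges if e & q.genes}
    else:  # common_cnv_ppi
        if control_cnv_genes is None:
            raise ValueError("common_cnv_ppi needs the control CNV gene list")
        ctrl = set(control_cnv_genes)
        pairs = {e for e in edges if e & ctrl}
    return PairUniverse(kind, pairs, requires_ppi=True)


def coexpressed_fraction(
    u: PairUniverse,
    m: ExpressionMatrix,
    samples: Sequence[str],
    params: CoexpressionParams | None = None,
    key: IntervalKey | None = None,
) -> FractionResult:
    """Fraction of the universe's pairs co-expressed in one interval.

    Pairs with a missing expression row or a constant (rank-degenerate)
    vector stay in the denominator but never count as co-expressed: they
    are candidate pairs that failed to show co-expression.
    """
    params = params or CoexpressionParams()
    key = key or IntervalKey("P?", "R?")
    if not u.pairs:
        raise ValueError(f"pair universe {u.name} is empty")
    if len(samples) < MIN_COEXPRESSION_N:
        raise ValueError(f"interval {key.label}: need >= {MIN_COEXPRESSION_N} samples")

    gene_index = {g: i for i, g in enumerate(m.genes)}
    pair_list = [tuple(sorted(p)) for p in u.pairs]
    ia, ib, measurable = [], [], []
    for a, b in pair_list:
        if a in gene_index and b in gene_index:
            ia.append(gene_index[a])
            ib.append(gene_index[b])
            measurable.append(True)
        else:
            measurable.append(False)

    n_coexp = 0
    n_unmeasurable = len(pair_list) - len(ia)
    if ia:
        sub = m.values.loc[:, list(samples)].to_numpy(dtype=float)
        z = rank_zscores(sub)
        rhos = np.einsum("ij,ij->i", z[np.array(ia)], z[np.array(ib)])
        n_unmeasurable += int(np.isnan(rhos).sum())
        with np.errstate(invalid="ignore"):
            if params.strict:
                n_coexp = int((rhos > params.rho_threshold).sum())
            else:
                n_coexp = int((rhos >= params.rho_threshold).sum())
    if n_unmeasurable:
        logger.debug("interval %s universe %s: %d pairs unmeasurable",
                     key.label, u.name, n_unmeasurable)
    return FractionResult(interval=key, universe=u.name, n_coexpressed=n_coexp,
                          n_total=len(pair_list), n_unmeasurable=n_unmeasurable)


def fisher_enrichment(
    test: FractionResult,
    control: FractionResult,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fisher's exact test that the test fraction exceeds the control's.

    The 2x2 table is [[test co-expressed, test not], [control co-expressed,
    control not]]; the default alternative is one-sided 'greater' (the
    question is whether the query set has *more* co-expressed interacting
    pairs than the control universe).
    """
    if test.interval != control.interval:
        raise ValueError(
            f"interval mismatch: {test.interval.label} vs {control.interval.label}"
        )
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    table = (
        (test.n_coexpressed, test.n_total - test.n_coexpressed),
        (control.n_coexpressed, control.n_total - control.n_coexpressed),
    )
    scipy_alt = "greater" if alternative == "greater" else "two-sided"
    odds, p = stats.fisher_exact(np.array(table), alternative=scipy_alt)
    return EnrichmentResult(interval=test.interval, control=control.universe,
                            table=table, odds_ratio=float(odds), p=float(p))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped to
    [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_enrichment_scan(
    intervals: Mapping[IntervalKey, Sequence[str]],
    query_universe: PairUniverse,
    control_universes: Sequence[PairUniverse],
    m: ExpressionMatrix,
    params: CoexpressionParams | None = None,
    alpha: float = 0.05,
    fdr_family: str = "per_control",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test every retained interval against every control universe.

    Returns one row per (interval, control) with counts, fractions, odds
    ratio, p and BH q.  The FDR family is the set of intervals within one
    control comparison by default (``fdr_family='joint'`` corrects across
    all interval x control tests at once).  A row is marked significant at
    ``q < alpha``; interval-level calls (significant vs all controls, or vs
    all but one) are derived downstream with :func:`significant_intervals`.
    """
    params = params or CoexpressionParams()
    if fdr_family not in ("per_control", "joint"):
        raise ValueError("fdr_family must be 'per_control' or 'joint'")
    for u in control_universes:
        if not u.pairs:
            raise ValueError(f"control universe {u.name} is empty")
    if not query_universe.pairs:
        raise ValueError("query universe is empty")

    keys = sorted(intervals, key=lambda k: (k.period, k.region))
    rows = []
    for key in keys:
        samples = intervals[key]
        test_fr = coexpressed_fraction(query_universe, m, samples, params, key)
        for u in control_universes:
            ctrl_fr = coexpressed_fraction(u, m, samples, params, key)
            res = fisher_enrichment(test_fr, ctrl_fr, alternative=alternative)
            rows.append({
                "interval": key.label,
                "control": u.name,
                "n_test_coexp": test_fr.n_coexpressed,
                "n_test_total": test_fr.n_total,
                "n_ctrl_coexp": ctrl_fr.n_coexpressed,
                "n_ctrl_total": ctrl_fr.n_total,
                "fraction_test": test_fr.fraction,
                "fraction_ctrl": ctrl_fr.fraction,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df
    if fdr_family == "per_control":
        df["q"] = np.nan
        for name, idx in df.groupby("control").groups.items():
            df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"].to_numpy())
    else:
        df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df


def significant_intervals(
    scan: pd.DataFrame, alpha: float = 0.05, min_controls: int | None = None
) -> list[IntervalKey]:
    """Intervals significant (q < alpha) against every control universe.

    ``min_controls`` relaxes the rule to "significant vs at least that many
    controls" — the 2-of-3 case is reported separately by callers, never
    silently merged with the strict call.
    """
    if scan.empty:
        return []
    n_controls = scan["control"].nunique()
    need = n_controls if min_controls is None else min_controls
    hits = (
        scan[scan["q"] < alpha]
        .groupby("interval")["control"]
        .nunique()
    )
    labels = sorted(hits[hits >= need].index)
    return [IntervalKey.parse(l) for l in labels]
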