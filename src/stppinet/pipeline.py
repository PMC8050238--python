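"""End-to-end orchestration: config handling, the run pipeline, validation.

Stages: ingest (expression filter, interactome, query set) -> partition ->
per-interval enrichment scan vs the three control pair universes ->
characterisation of the significant networks (overlap, partner-ratio
ANOVA, radiality/driver, gene-set enrichment).  All outputs are plain TSV
plus a flat-text run report so reruns are diffable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .datatypes import (CoexpressionParams, ExpressionFilterParams, IntervalKey,
                        QueryGeneSet)
from . import ingest, partition as part, networks as nets, enrichment as enr
from . import topology as topo, genesets as gs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression: Path
    metadata: Path
    interactions: Path
    query_genes: Path
    common_cnv_genes: Path
    gene_sets: Path | None = None
    scheme: Path | None = None
    query_exclusions: dict[str, str] = field(default_factory=dict)
    filter_params: ExpressionFilterParams = field(default_factory=ExpressionFilterParams)
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    min_samples: int = 6
    alpha: float = 0.05
    fdr_family: str = "per_control"
    background_n: int | None = None  # defaults to the brain-expressed gene count
    include_partner_partner: bool = False
    out: Path = Path("stppinet_out")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        def p(key, required=True):
            v = doc.get(key)
            if v is None:
                if required:
                    raise ValueError(f"config missing required path {key!r}")
                return None
            q = Path(v)
            return q if q.is_absolute() else base / q
        kwargs: dict[str, Any] = dict(
            expression=p("expression"), metadata=p("metadata"),
            interactions=p("interactions"), query_genes=p("query_genes"),
            common_cnv_genes=p("common_cnv_genes"),
            gene_sets=p("gene_sets", required=False),
            scheme=p("scheme", required=False),
        )
        kwargs["query_exclusions"] = dict(doc.get("query_exclusions", {}))
        if "filter" in doc:
            kwargs["filter_params"] = ExpressionFilterParams(**doc["filter"])
        if "coexpression" in doc:
            kwargs["coexpression"] = CoexpressionParams(**doc["coexpression"])
        for key in ("min_samples", "alpha", "fdr_family", "background_n",
                    "include_partner_partner", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        if "out" in doc:
            kwargs["out"] = Path(doc["out"])
        return cls(**kwargs)


@dataclass
class RunResult:
    """In-memory result of a pipeline run (everything also lands on disk)."""

    scan: pd.DataFrame
    significant: list[IntervalKey]
    significant_2of3: list[IntervalKey]
    subnetworks: dict[str, nets.QuerySubnetwork]
    overlap: topo.OverlapSummary | None
    anova: pd.DataFrame
    centrality: pd.DataFrame
    driver: tuple[str, float] | None
    geneset_results: pd.DataFrame
    query_set: QueryGeneSet
    report: dict[str, Any]


def _load_scheme(config: RunConfig):
    if config.scheme is not None:
        return part.load_scheme(config.scheme)
    return list(part.DEFAULT_PERIODS), list(part.DEFAULT_REGIONS)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the output tree."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stppinet_version": __version__, "seed": config.seed}

    # -- ingest ------------------------------------------------------------
    m_raw = ingest.read_expression(config.expression, config.metadata)
    report["n_genes_raw"] = m_raw.shape[0]
    report["n_samples"] = m_raw.shape[1]
    m, removed = ingest.filter_brain_expressed(m_raw, config.filter_params)
    report["n_brain_genes"] = m.shape[0]
    brain_genes = set(m.genes)

    table = ingest.read_interactions(config.interactions, physical_only=True)
    hi_be = ingest.build_brain_interactome(table, brain_genes)
    report["n_interactome_nodes"] = hi_be.number_of_nodes()
    report["n_interactome_edges"] = hi_be.number_of_edges()

    query = ingest.load_query_genes(
        config.query_genes, exclusions=list(config.query_exclusions.items()),
        brain_genes=brain_genes,
    )
    report["n_query_genes"] = len(query.genes)
    report["n_query_excluded"] = len(query.excluded)
    common_cnv = set(ingest.read_gene_list(config.common_cnv_genes)) & brain_genes

    # -- partition ---------------------------------------------------------
    periods, regions = _load_scheme(config)
    assigned = part.assign_samples(m.sample_meta(), periods, regions)
    report["n_interval_keys"] = len(assigned.intervals)
    retained = part.exclude_sparse_intervals(assigned, config.min_samples)
    report["n_retained_intervals"] = len(retained.intervals)
    report["excluded_intervals"] = ",".join(
        k.label for k in sorted(retained.excluded)) or "none"

    # -- enrichment scan ---------------------------------------------------
    query_u = enr.build_pair_universe("query_ppi", q=query, hi_be=hi_be)
    controls = [
        enr.build_pair_universe("common_cnv_ppi", hi_be=hi_be, control_cnv_genes=common_cnv),
        enr.build_pair_universe("query_all_brain", q=query, brain_genes=brain_genes),
        enr.build_pair_universe("all_ppi", hi_be=hi_be),
    ]
    scan = enr.run_enrichment_scan(
        retained.intervals, query_u, controls, m,
        params=config.coexpression, alpha=config.alpha, fdr_family=config.fdr_family,
    )
    scan.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    significant = enr.significant_intervals(scan, alpha=config.alpha)
    sig_2of3 = [k for k in enr.significant_intervals(scan, alpha=config.alpha, min_controls=2)
                if k not in significant]
    report["significant_intervals"] = ",".join(k.label for k in significant) or "none"
    report["significant_2of3_intervals"] = ",".join(k.label for k in sig_2of3) or "none"

    # -- networks for significant intervals --------------------------------
    netdir = out / "networks"
    netdir.mkdir(exist_ok=True)
    subnetworks: dict[str, nets.QuerySubnetwork] = {}
    central_frames = []
    for key in significant:
        net = nets.build_interval_network(hi_be, m, retained.intervals[key],
                                          config.coexpression, key=key)
        nets.write_edge_list(net, netdir / f"{key.label}.tsv")
        sub = nets.extract_query_subnetwork(net, query,
                                            include_partner_partner=config.include_partner_partner)
        subnetworks[key.label] = sub
        if sub.query_nodes or sub.partner_nodes:
            g = sub.graph
            g.remove_nodes_from(list(n for n in g if g.degree(n) == 0))
            if g.number_of_nodes():
                cent = topo.radiality(g)
                cent.insert(0, "interval", key.label)
                central_frames.append(cent.reset_index())

    centrality = (pd.concat(central_frames, ignore_index=True)
                  if central_frames else
                  pd.DataFrame(columns=["gene", "interval", "radiality", "degree", "component"]))
    centrality.to_csv(out / "topology.tsv", sep="\t", index=False)

    driver = None
    if not centrality.empty:
        pooled = (centrality.groupby("gene")[["radiality", "degree"]].max())
        present_queries = [g for g in query.genes if g in pooled.index]
        if present_queries:
            driver = topo.identify_driver(pooled, present_queries)
            report["driver_gene"] = driver[0]
            report["driver_radiality"] = f"{driver[1]:.6f}"

    # -- overlap + ANOVA ---------------------------------------------------
    overlap = None
    if len(subnetworks) >= 2:
        overlap = topo.network_overlap(list(subnetworks.values()))
        k_all, union, frac = overlap.shared_by_all("query")
        pk_all, punion, pfrac = overlap.shared_by_all("partner")
        rows = [
            {"category": "query", "shared_by_all": k_all, "union": union, "fraction": frac},
            {"category": "partner", "shared_by_all": pk_all, "union": punion, "fraction": pfrac},
        ]
        pd.DataFrame(rows).to_csv(out / "overlap.tsv", sep="\t", index=False)
        report["query_shared_by_all"] = f"{k_all}/{union}"
        report["partner_shared_by_all"] = f"{pk_all}/{punion}"

    anova_rows = []
    for la, lb in itertools.combinations(sorted(subnetworks), 2):
        try:
            res = topo.partner_ratio_anova(subnetworks[la], subnetworks[lb], query)
        except ValueError as exc:
            logger.warning("ANOVA %s vs %s skipped: %s", la, lb, exc)
            continue
        anova_rows.append({"comparison": f"{la}_vs_{lb}", "F": res.F,
                           "df_between": res.df_between, "df_within": res.df_within,
                           "p": res.p})
    anova = pd.DataFrame(anova_rows, columns=["comparison", "F", "df_between", "df_within", "p"])
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)

    # -- gene-set enrichment ----------------------------------------------
    geneset_results = pd.DataFrame()
    if config.gene_sets is not None and subnetworks:
        network_genes = set().union(
            *[s.query_nodes | s.partner_nodes for s in subnetworks.values()])
        if network_genes:
            collection = gs.read_gmt(config.gene_sets)
            bg = config.background_n or len(brain_genes)
            geneset_results = gs.set_enrichment(network_genes, collection, background_n=bg)
            geneset_results.to_csv(out / "genesets.tsv", sep="\t", index=False)
            report["n_network_genes"] = len(network_genes)

    with open(out / "report.txt", "w") as fh:
        for k, v in report.items():
            fh.write(f"{k}={v}\n")

    return RunResult(scan=scan, significant=significant, significant_2of3=sig_2of3,
                     subnetworks=subnetworks, overlap=overlap, anova=anova,
                     centrality=centrality, driver=driver,
                     geneset_results=geneset_results, query_set=query, report=report)


def validate(config: RunConfig) -> list[str]:
    """Dry-run checks; returns a list of problems (empty = OK)."""
    problems: list[str] = []
    for key in ("expression", "metadata", "interactions", "query_genes", "common_cnv_genes"):
        path = getattr(config, key)
        if not Path(path).is_file():
            problems.append(f"{key}: file not found: {path}")
    if config.gene_sets is not None and not Path(config.gene_sets).is_file():
        problems.append(f"gene_sets: file not found: {config.gene_sets}")
    if problems:
        return problems

    try:
        periods, regions = _load_scheme(config)
        part._check_disjoint(periods, "stages", "period")
        part._check_disjoint(regions, "structures", "region")
    except ValueError as exc:
        problems.append(f"scheme: {exc}")
        return problems

    try:
        m = ingest.read_expression(config.expression, config.metadata)
    except ValueError as exc:
        problems.append(f"expression: {exc}")
        return problems
    try:
        m_f, _ = ingest.filter_brain_expressed(m, config.filter_params)
    except ValueError as exc:
        problems.append(f"filter: {exc}")
        return problems

    try:
        ingest.read_interactions(config.interactions)
    except ValueError as exc:
        problems.append(f"interactions: {exc}")

    try:
        ingest.load_query_genes(config.query_genes,
                                exclusions=list(config.query_exclusions.items()),
                                brain_genes=set(m_f.genes))
    except ValueError as exc:
        problems.append(f"query_genes: {exc}")

    assigned = part.assign_samples(m.sample_meta(), periods, regions)
    retained = part.exclude_sparse_intervals(assigned, config.min_samples)
    if not retained.intervals:
        problems.append("partition: no interval retains enough samples")
    return problems
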