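"""Simulation studies over the pipeline: calibration, recovery, power.

Each study runs the full in-memory analysis path (filter -> interactome ->
partition -> enrichment scan -> networks/driver) on fresh synthetic bundles
across many seeds and summarises recovery of the planted structure.  These
are the package's own benchmark experiments; they are deliberately cheap
enough to run routinely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import enrichment as enr
from . import ingest
from . import networks as nets
from . import topology as topo
from .datatypes import QueryGeneSet
from .genesets import set_enrichment
from .partition import assign_samples, exclude_sparse_intervals
from .simulate import SimBundle, SimConfig, generate_expression, generate_gene_sets, simulate_bundle


@dataclass
class ScanContext:
    """One simulated dataset taken through the enrichment scan."""

    bundle: SimBundle
    matrix: "object"
    interactome: "object"
    query: QueryGeneSet
    partition: "object"
    scan: pd.DataFrame

    @property
    def significant_labels(self) -> set[str]:
        return {k.label for k in enr.significant_intervals(self.scan)}

    @property
    def planted_labels(self) -> set[str]:
        return {k.label for k in self.bundle.truth.planted_intervals}


def scan_simulated(config: SimConfig, min_samples: int = 6) -> ScanContext:
    """Simulate a bundle and run it through ingest, partition and the scan."""
    bundle = simulate_bundle(config)
    m, _ = ingest.filter_brain_expressed(bundle.expression)
    phys = bundle.interactions[bundle.interactions["system_type"] == "physical"]
    hi = ingest.build_brain_interactome(phys, set(m.genes))
    truth = bundle.truth
    query = QueryGeneSet(
        "query", set(truth.query_genes),
        excluded={g: "not brain-expressed" for g in truth.nonexpressed_genes},
    )
    part = exclude_sparse_intervals(assign_samples(m.sample_meta()), min_samples)
    query_u = enr.build_pair_universe("query_ppi", q=query, hi_be=hi)
    controls = [
        enr.build_pair_universe("common_cnv_ppi", hi_be=hi,
                                control_cnv_genes=truth.common_cnv_genes),
        enr.build_pair_universe("query_all_brain", q=query, brain_genes=set(m.genes)),
        enr.build_pair_universe("all_ppi", hi_be=hi),
    ]
    scan = enr.run_enrichment_scan(part.intervals, query_u, controls, m)
    return ScanContext(bundle=bundle, matrix=m, interactome=hi, query=query,
                       partition=part, scan=scan)


def driver_for(ctx: ScanContext) -> str | None:
    """Identify the driver gene over the significant interval networks."""
    frames = []
    for key in enr.significant_intervals(ctx.scan):
        net = nets.build_interval_network(ctx.interactome, ctx.matrix,
                                          ctx.partition.intervals[key], key=key)
        sub = nets.extract_query_subnetwork(net, ctx.query)
        g = sub.graph
        g.remove_nodes_from([n for n in g if g.degree(n) == 0])
        if g.number_of_nodes():
            cent = topo.radiality(g)
            frames.append(cent)
    if not frames:
        return None
    pooled = pd.concat(frames).groupby(level=0)[["radiality", "degree"]].max()
    present = [q for q in ctx.query.genes if q in pooled.index]
    if not present:
        return None
    return topo.identify_driver(pooled, present)[0]


def null_calibration(n_seeds: int = 50, base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I behaviour of the scan with no planted signal (beta = 0).

    Returns the pooled fraction of (interval x control) tests with p < alpha,
    the number of tests, and the fraction of seeds in which no interval is
    called significant against all three controls.
    """
    n_small_p = n_tests = n_clean_seeds = 0
    for i in range(n_seeds):
        ctx = scan_simulated(SimConfig(seed=base_seed + i, beta=0.0))
        n_small_p += int((ctx.scan["p"] < alpha).sum())
        n_tests += len(ctx.scan)
        if not ctx.significant_labels:
            n_clean_seeds += 1
    return {
        "p_lt_alpha_rate": n_small_p / n_tests,
        "n_tests": n_tests,
        "no_significant_seed_rate": n_clean_seeds / n_seeds,
        "n_seeds": n_seeds,
    }


def recovery_study(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Planted-interval recovery and hub-driver identification rates."""
    n_exact = n_driver = 0
    for i in range(n_seeds):
        ctx = scan_simulated(SimConfig(seed=base_seed + i))
        if ctx.significant_labels == ctx.planted_labels:
            n_exact += 1
        if driver_for(ctx) == ctx.bundle.truth.hub_gene:
            n_driver += 1
    return {
        "interval_recovery_rate": n_exact / n_seeds,
        "driver_recovery_rate": n_driver / n_seeds,
        "n_seeds": n_seeds,
    }


def geneset_study(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Power on the planted gene set and null-set p-value uniformity.

    The tested gene list is the planted module (query genes + partners);
    null sets are uniform draws from the full expressed universe, so under
    the no-association null the overlap is exactly hypergeometric.
    """
    null_ps: list[float] = []
    n_power = 0
    for i in range(n_seeds):
        c = SimConfig(seed=base_seed + i)
        _, truth = generate_expression(c)
        coll = generate_gene_sets(c, truth)
        res = set_enrichment(truth.module_genes, coll, background_n=c.n_genes)
        null_ps.extend(res.loc[res.set_name.str.startswith("NULL"), "p"])
        if float(res.loc[res.set_name == "ENRICHED_SET", "q"].iloc[0]) < 0.05:
            n_power += 1
    ks = stats.kstest(null_ps, "uniform")
    return {
        "enriched_q_lt_05_rate": n_power / n_seeds,
        "null_ks_stat": float(ks.statistic),
        "null_ks_p": float(ks.pvalue),
        "n_null_p": len(null_ps),
        "n_seeds": n_seeds,
    }


def structural_counts(seed: int = 0) -> dict:
    """Design-level counts from one default-condition run over real files.

    Writes a default-condition bundle to a temporary directory and runs the
    full disk pipeline: an 8 x 4 period/region grid gives 32 interval keys;
    the data-poor interval drops out leaving 31 networks; the written locus
    list (query genes plus 2 non-expressed decoys) reduces to the expressed
    query set.
    """
    import tempfile
    from pathlib import Path

    from .pipeline import RunConfig, run
    from .simulate import write_fixture_bundle

    cfg = SimConfig(seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fixture_bundle(cfg, tmp)
        result = run(RunConfig(
            expression=tmp / "expression.tsv", metadata=tmp / "samples.tsv",
            interactions=tmp / "interactions.tsv",
            query_genes=tmp / "query_genes.txt",
            common_cnv_genes=tmp / "common_cnv_genes.txt",
            gene_sets=tmp / "gene_sets.gmt", scheme=tmp / "scheme.yaml",
            out=tmp / "results", seed=seed,
        ))
    rep = result.report
    return {
        "n_interval_keys": rep["n_interval_keys"],
        "n_retained_networks": rep["n_retained_intervals"],
        "n_query_listed": rep["n_query_genes"] + rep["n_query_excluded"],
        "n_query_genes": rep["n_query_genes"],
        "n_samples": rep["n_samples"],
        "significant_intervals": rep["significant_intervals"],
        "driver_gene": rep.get("driver_gene", ""),
    }
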