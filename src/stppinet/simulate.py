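"""Synthetic data with planted spatiotemporal co-expression structure.

The generator emulates the full input bundle the pipeline consumes: a
developmental expression matrix over a period x region sample grid, a
physical interactome, query / control CNV gene lists and gene-set
collections — with known ground truth so recovery can be tested.

The expression model is a single shared latent factor per planted
interval: on the log2 scale,

    x_gs = baseline_g + beta * f_s * m_g + eps_gs

with ``f_s ~ N(0,1)`` drawn per sample only inside planted intervals,
``m_g = 1`` for module genes (query genes and their planted partners) and 0
otherwise, and ``eps_gs ~ N(0, noise_sd)``.  Values are exported on the
linear scale (2**x).  The factor induces block co-expression among module
genes confined to the planted intervals, which is exactly the signal the
fraction statistic is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection, IntervalKey
from .partition import DEFAULT_PERIODS, DEFAULT_REGIONS, write_scheme


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the scale of a real locus analysis where it matters for the
    statistics: 21 expressed query genes (plus 2 non-expressed decoys in
    the written list), an 8 x 4 period/region grid with one data-poor
    interval, 6 samples per interval, co-expression planted in two
    intervals via a strong shared factor (beta = 3, noise sd = 0.3).
    """

    n_genes: int = 600              # expressed genes incl. query + partners
    n_query: int = 21
    n_query_nonexpressed: int = 2   # decoy locus genes with all-zero expression
    n_partners_per_query: int = 4
    periods: int = 8
    regions: int = 4
    samples_per_interval: int = 6
    sparse_interval: str = "P3R4"   # forced below min_samples
    sparse_samples: int = 1
    n_unassigned_samples: int = 2   # samples at a stage outside the scheme
    planted_intervals: tuple[str, ...] = ("P1R1", "P1R3")
    beta: float = 3.0
    noise_sd: float = 0.3
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    background_edge_prob: float = 0.02
    common_cnv_size: int = 21
    # interaction-table dirt to exercise the cleaning paths
    n_duplicate_rows: int = 3
    n_swapped_rows: int = 3
    n_self_loops: int = 2
    n_nonphysical_rows: int = 3
    # gene-set collection; null-set sizes vary so the discrete hypergeometric
    # p-value support mixes across sets (see docs/methods.md on calibration)
    n_null_sets: int = 4
    null_set_size: tuple[int, int] = (50, 300)
    enriched_fraction: float = 0.5
    enriched_set_size: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        n_module = self.n_query * (1 + self.n_partners_per_query)
        if n_module > self.n_genes:
            raise ValueError("query genes + planted partners exceed n_genes")
        if not (0 <= self.background_edge_prob <= 1):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.periods > len(DEFAULT_PERIODS) or self.regions > len(DEFAULT_REGIONS):
            raise ValueError(
                f"grid at most {len(DEFAULT_PERIODS)} periods x {len(DEFAULT_REGIONS)} regions"
            )
        grid = {
            IntervalKey(p.label, r.label).label
            for p in DEFAULT_PERIODS[: self.periods]
            for r in DEFAULT_REGIONS[: self.regions]
        }
        for label in self.planted_intervals:
            if label not in grid:
                raise ValueError(f"planted interval {label} outside the {len(grid)}-cell grid")

    def scheme(self):
        return list(DEFAULT_PERIODS[: self.periods]), list(DEFAULT_REGIONS[: self.regions])


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted_intervals: list[IntervalKey]
    planted_pairs: set[frozenset[str]]
    query_genes: list[str]
    partner_genes: list[str]
    hub_gene: str
    nonexpressed_genes: list[str]
    common_cnv_genes: list[str] = field(default_factory=list)
    dirt_rows: dict[str, int] = field(default_factory=dict)

    @property
    def module_genes(self) -> set[str]:
        return set(self.query_genes) | set(self.partner_genes)


def _gene_names(c: SimConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    n_partners = c.n_query * c.n_partners_per_query
    query = [f"Q{i+1:03d}" for i in range(c.n_query)]
    partners = [f"T{i+1:04d}" for i in range(n_partners)]
    n_bg = c.n_genes - c.n_query - n_partners
    background = [f"B{i+1:04d}" for i in range(n_bg)]
    decoys = [f"NX{i+1:02d}" for i in range(c.n_query_nonexpressed)]
    return query, partners, background, decoys


def _sample_grid(c: SimConfig) -> pd.DataFrame:
    """Sample metadata over the period x region grid.

    Stages/structures are drawn from the default scheme's code sets; the
    sparse interval gets ``sparse_samples`` samples and a few samples are
    placed at a stage outside all periods to exercise the unassigned path.
    """
    periods, regions = c.scheme()
    rows = []
    i = 0
    for p in periods:
        for r in regions:
            key = IntervalKey(p.label, r.label)
            n = c.sparse_samples if key.label == c.sparse_interval else c.samples_per_interval
            stages = sorted(p.stages)
            structures = sorted(r.structures)
            for j in range(n):
                i += 1
                rows.append({
                    "sample_id": f"S{i:04d}",
                    "stage": stages[j % len(stages)],
                    "structure": structures[j % len(structures)],
                    "interval": key.label,
                })
    for j in range(c.n_unassigned_samples):
        i += 1
        rows.append({"sample_id": f"S{i:04d}", "stage": 13,
                     "structure": "AMY", "interval": ""})
    return pd.DataFrame(rows)


def generate_expression(c: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Latent-factor expression matrix plus the planted ground truth."""
    rng = np.random.default_rng([c.seed, 0])
    query, partners, background, decoys = _gene_names(c)
    genes = query + partners + background
    grid = _sample_grid(c)

    n_g, n_s = len(genes), len(grid)
    baseline = rng.normal(c.baseline_log2_mean, c.baseline_log2_sd, size=n_g)
    module_mask = np.zeros(n_g)
    module_mask[: c.n_query + len(partners)] = 1.0

    factor = np.zeros(n_s)
    planted = set(c.planted_intervals)
    in_planted = grid["interval"].isin(planted).to_numpy()
    factor[in_planted] = rng.normal(0.0, 1.0, size=int(in_planted.sum()))

    eps = rng.normal(0.0, c.noise_sd, size=(n_g, n_s))
    log2x = baseline[:, None] + c.beta * np.outer(module_mask, factor) + eps
    values = np.power(2.0, log2x)

    if decoys:
        values = np.vstack([values, np.zeros((len(decoys), n_s))])
    df = pd.DataFrame(values, index=genes + decoys, columns=grid["sample_id"].tolist())
    meta = grid.set_index("sample_id")[["stage", "structure"]]

    # planted query-partner edges; the first query gene is the module hub,
    # wired to every partner so it sits centrally in the recovered network
    planted_pairs: set[frozenset[str]] = set()
    for qi, qg in enumerate(query):
        own = partners[qi * c.n_partners_per_query: (qi + 1) * c.n_partners_per_query]
        for pg in own:
            planted_pairs.add(frozenset((qg, pg)))
    hub = query[0]
    for pg in partners:
        planted_pairs.add(frozenset((hub, pg)))

    truth = GroundTruth(
        planted_intervals=[IntervalKey.parse(l) for l in c.planted_intervals],
        planted_pairs=planted_pairs,
        query_genes=query,
        partner_genes=partners,
        hub_gene=hub,
        nonexpressed_genes=decoys,
    )
    return ExpressionMatrix(df, meta), truth


def generate_interactome(c: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Interaction table: background random edges + planted edges + dirt.

    Background: every unordered gene pair is an edge independently with
    ``background_edge_prob``.  Planted query-partner edges are always
    present.  Dirt rows (exact duplicates, swapped-orientation duplicates,
    self-loops, non-"physical" rows) exercise the reader/cleaner and are
    counted in ``truth.dirt_rows``.
    """
    rng = np.random.default_rng([c.seed, 1])
    query, partners, background, _ = _gene_names(c)
    genes = query + partners + background
    n = len(genes)

    pairs: list[tuple[str, str]] = []
    if c.background_edge_prob > 0:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < c.background_edge_prob
        pairs = [(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])]
    present = {frozenset(p) for p in pairs}
    for pair in sorted(truth.planted_pairs, key=sorted):
        if pair not in present:
            a, b = sorted(pair)
            pairs.append((a, b))
            present.add(pair)

    rows = [{"gene_a": a, "gene_b": b, "system_type": "physical"} for a, b in pairs]
    # choose dirt rows from the real edges so cleaning is observable
    base = rows[: max(c.n_duplicate_rows, c.n_swapped_rows)]
    dirt = {"duplicate": 0, "swapped": 0, "self_loop": 0, "nonphysical": 0}
    for r in base[: c.n_duplicate_rows]:
        rows.append(dict(r))
        dirt["duplicate"] += 1
    for r in base[: c.n_swapped_rows]:
        rows.append({"gene_a": r["gene_b"], "gene_b": r["gene_a"], "system_type": "physical"})
        dirt["swapped"] += 1
    loop_genes = rng.choice(genes, size=c.n_self_loops, replace=False)
    for g in loop_genes:
        rows.append({"gene_a": g, "gene_b": g, "system_type": "physical"})
        dirt["self_loop"] += 1
    for k in range(c.n_nonphysical_rows):
        a, b = rng.choice(genes, size=2, replace=False)
        rows.append({"gene_a": a, "gene_b": b, "system_type": "genetic"})
        dirt["nonphysical"] += 1
    truth.dirt_rows = dirt

    common = rng.choice(background, size=min(c.common_cnv_size, len(background)), replace=False)
    truth.common_cnv_genes = sorted(common)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "system_type"])


def generate_gene_sets(c: SimConfig, truth: GroundTruth) -> GeneSetCollection:
    """One planted "enriched" set plus null sets.

    The enriched set holds ``enriched_fraction`` of the partner genes,
    padded with random fillers.  Null sets are uniform draws from the whole
    expressed-gene universe (sizes drawn from ``null_set_size``), so their
    overlap with any fixed gene list follows the hypergeometric null
    exactly.
    """
    rng = np.random.default_rng([c.seed, 2])
    query, partners, background, _ = _gene_names(c)
    genes = query + partners + background
    non_module = background

    n_core = int(round(c.enriched_fraction * len(partners)))
    core = list(rng.choice(partners, size=n_core, replace=False))
    n_fill = max(c.enriched_set_size - n_core, 0)
    fill = list(rng.choice(non_module, size=min(n_fill, len(non_module)), replace=False))
    sets: dict[str, set[str]] = {"ENRICHED_SET": set(core + fill)}

    lo, hi = c.null_set_size
    for i in range(c.n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"NULL_SET_{i+1:02d}"] = set(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection(name="simulated_sets", sets=sets, source="simulated")


@dataclass
class SimBundle:
    """Everything the pipeline consumes, in memory."""

    config: SimConfig
    expression: ExpressionMatrix
    interactions: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: GroundTruth

    @property
    def query_list(self) -> list[str]:
        return self.truth.query_genes + self.truth.nonexpressed_genes


def simulate_bundle(c: SimConfig) -> SimBundle:
    expr, truth = generate_expression(c)
    interactions = generate_interactome(c, truth)
    gene_sets = generate_gene_sets(c, truth)
    return SimBundle(config=c, expression=expr, interactions=interactions,
                     gene_sets=gene_sets, truth=truth)


def write_fixture_bundle(c: SimConfig, outdir: str | Path) -> dict:
    """Write the full input bundle and a flat ground-truth manifest.

    Files: expression.tsv, samples.tsv, interactions.tsv, query_genes.txt,
    common_cnv_genes.txt, gene_sets.gmt, scheme.yaml, ground_truth.txt.
    Returns the manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(c)

    bundle.expression.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
    bundle.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    (outdir / "query_genes.txt").write_text(
        "# simulated CNV locus gene list\n" + "\n".join(bundle.query_list) + "\n"
    )
    (outdir / "common_cnv_genes.txt").write_text(
        "\n".join(bundle.truth.common_cnv_genes) + "\n"
    )
    from .genesets import write_gmt
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    periods, regions = c.scheme()
    write_scheme(periods, regions, outdir / "scheme.yaml")

    manifest = {
        "seed": c.seed,
        "n_genes": c.n_genes,
        "n_query": c.n_query,
        "planted_intervals": ",".join(k.label for k in bundle.truth.planted_intervals),
        "hub_gene": bundle.truth.hub_gene,
        "n_planted_pairs": len(bundle.truth.planted_pairs),
        "nonexpressed_genes": ",".join(bundle.truth.nonexpressed_genes),
        "common_cnv_genes": ",".join(bundle.truth.common_cnv_genes),
        "enriched_set": "ENRICHED_SET",
    }
    with open(outdir / "ground_truth.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    return manifest
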