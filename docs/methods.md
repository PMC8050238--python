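# Methods

## The analysis

`stppinet` asks where, in a developing brain, a fixed set of genes (a CNV
locus such as 7q11.23) acts as a coherent protein module. The inputs are a
linear-scale (RPKM-like) expression matrix over samples annotated with a
developmental stage (codes 1–13) and an anatomical structure (16 codes), a
physical protein–protein interaction table, the query gene list, a control
CNV gene list, and optional gene-set collections.

The pipeline proceeds in five stages.

1. **Brain-expression filtering.** A gene is dropped if its log2 intensity
   (log2(x + 1) by default) stays below 0.4 in every sample, or if the
   coefficient of variation of its linear values (population sd / mean)
   falls below 0.07. The two floors are combined with OR by default: both
   are filters for uninformative rows, and either one firing is enough to
   make downstream rank correlations unreliable; the AND combination is
   available as `filter_logic: and`. The pseudo-count (1.0) is the
   standard RPKM convention and is configurable.

2. **Interactome construction (HI_BE).** Non-"physical" interaction rows
   are discarded, symbols upper-cased, self-loops and duplicate /
   orientation-swapped rows collapsed, and edges restricted to pairs of
   brain-expressed genes. The result is a simple undirected graph.

3. **Spatiotemporal partition.** Stages merge into eight periods (P1–P8)
   and structures into four regions (R1–R4), giving a 32-cell grid.
   The shipped stage→period map is a *surrogate*: the authoritative
   mapping for real BrainSpan runs lives in a study-specific scheme file
   (`--scheme`). The default regions group the 16 structure codes by anatomy
   (R1 parietal/temporal/occipital cortex, R3 amygdala/hippocampus/
   striatum, R4 mediodorsal thalamus + cerebellar cortex, R2 the remaining
   frontal/sensorimotor cortex). Intervals with fewer than `min_samples`
   samples (default 6) are excluded as a rule rather than by name:
   Spearman correlation on fewer than six observations has too coarse a
   support to clear a 0.5 threshold meaningfully. Data-poor intervals
   (P3R4 in the default grid) therefore drop out by rule, not as a
   hard-coded special case.

4. **Per-interval enrichment scan.** Within each retained interval, a gene
   pair is *co-expressed* iff the Spearman correlation (midranks for ties)
   of the two genes across that interval's samples is strictly greater
   than 0.5. The test statistic is the co-expressed fraction of the query
   pair universe (interactome edges touching a query gene), compared with
   three control universes: (i) edges touching the control CNV genes,
   (ii) all query × brain-gene pairs (no interaction required), and
   (iii) all interactome edges. Each comparison is a one-sided Fisher's
   exact test ("greater": the question is whether the query module has
   *more* co-expressed interacting pairs), BH-corrected across intervals
   within each control comparison (family size = number of retained
   intervals; a joint family over all interval × control tests is
   available via `fdr_family: joint`). An interval is *significant* when
   q < alpha against all three controls; the 2-of-3 relaxation is reported
   separately and never silently merged. Pairs with a missing or constant
   expression vector stay in the denominator and never count as
   co-expressed — they are candidate pairs that failed to show
   co-expression. Spearman is rank-based, so computing on linear rather
   than log values changes nothing; edges are evaluated via centred,
   normalised rank vectors so that a pair's correlation is a single dot
   product.

5. **Network characterisation.** For each significant interval the
   co-expression-filtered network is built, the query-centred subnetwork
   extracted (partners = non-query neighbours of query genes;
   partner–partner edges optional, for functional-module views), and:
   - **overlap**: counts of query genes / partners shared by exactly k of
     the significant networks (Venn-style), with the shared-by-all
     fraction over each category's union;
   - **partner turnover**: per query gene with partners in either of two
     networks, the unique-to-A, unique-to-B and shared partner ratios over
     the union of the two partner sets (so the three ratios sum to 1); a
     one-way ANOVA compares the three ratio groups (one observation per
     query gene). The two-group variant (unique pooled vs shared) is
     available; either grouping is a defensible reading of unique-vs-shared
     partner turnover.
   - **driver gene**: diameter-normalised radiality. Within a connected
     component with unweighted diameter D, Rad(v) = (D + 1 − mean
     shortest-path distance from v) / D; singleton components get 0. The
     driver is the query gene with maximal radiality, ties broken by
     degree then symbol, so the call is deterministic. Radiality is
     computed per component; comparing values across components is
     flagged in the output rather than hidden.
   - **gene-set enrichment**: network proteins vs each curated set by
     one-sided Fisher over a fixed background universe N (default 20,240;
     for simulated data the simulated universe size). Term enrichment uses
     the cumulative hypergeometric upper tail with the triple filter
     p < 0.01, overlap ≥ 3, enrichment factor (observed/expected
     overlap) > 1.5 (strict). Query genes absent from the annotation
     universe are dropped from n with a logged count. Term clustering by
     membership similarity is out of scope; results are flat.

Headline numbers from full-scale BrainSpan/BioGRID analyses (specific
p-values, Venn counts) depend on the particular data releases and interval
scheme used and are not desk-scale targets; the test suite
instead verifies the machinery against oracles and planted ground truth.

## The synthetic-data generator

The generator emulates the full input bundle with known structure. On the
log2 scale, gene g in sample s has

    x_gs = baseline_g + beta · f_s · m_g + eps_gs

with baseline_g ~ N(3, 1), f_s ~ N(0, 1) drawn only for samples in the
planted intervals (0 elsewhere), m_g = 1 for module genes (query genes and
their planted partners), and eps_gs ~ N(0, noise_sd). Values are exported
linear (2^x). A single shared factor per planted interval produces block
co-expression — exactly what the fraction statistic detects — with one
interpretable strength knob (beta).

Default conditions mirror the scale of a real locus analysis where it matters for
the statistics: 21 query genes plus 2 all-zero decoy genes in the written
locus list (so ingest reproduces the 23 → 21 reduction), an 8 × 4 grid
with 6 samples per interval and one interval (P3R4) forced to a single
sample to exercise the sparse-interval rule, two planted intervals (P1R1,
P1R3), beta = 3 and noise sd = 0.3 (planted-pair correlations near 1, null
pairs centred at 0), 600 expressed genes, background edge probability 0.02
(~3,600 edges), 4 planted partners per query gene, and the first query
gene wired to every partner as the module hub. The interaction table also
carries counted "dirt" (duplicate, swapped, self-loop and non-physical
rows) so the cleaning paths are observable. All randomness flows from one
seed through independent named streams; outputs are bit-reproducible.

What the generator does **not** emulate: BrainSpan's age/structure
metadata beyond the codes, realistic expression marginals (library-size
effects, zero inflation), degree-heterogeneous (scale-free) interactomes,
or correlated background co-expression. Passing recovery tests therefore
shows the machinery is correct and well calibrated under a clean factor
model, not that real-data conclusions are reproduced.

## Calibration notes

- **Fisher null behaviour.** With beta = 0, the pooled fraction of raw
  p < 0.05 across interval × control tests is ≈ 0.03, not 0.05. Two causes,
  both structural: the exact one-sided test is conservative
  (P(p ≤ 0.05) < 0.05 for discrete tables at these universe sizes,
  ~200–3,700 pairs), and the query pair universe is by definition a subset
  of two of the three control universes, so test and control counts are
  positively correlated, which further depresses small p-values. The scan
  therefore never inflates type-I error (no null seed calls a significant
  interval), but its raw p-values are not uniform. This is a property of
  the prescribed test and control definitions, not an implementation
  defect — the Fisher p-values match exhaustive hypergeometric enumeration
  to 1e-12.

- **Gene-set null uniformity.** Null sets are uniform draws from the whole
  expressed universe (not from non-module genes only: a set disjoint from
  the tested list by construction has overlap identically zero and p = 1,
  which makes any uniformity check meaningless). Under uniform draws the
  overlap is exactly hypergeometric, so the tail p-values are valid but
  discrete; the pooled empirical CDF sits below the diagonal by up to
  ≈ 0.05 regardless of how set sizes are spread (computed exactly from the
  atom structure at N = 602, n = 105). A KS uniformity check at the 1%
  level is therefore only meaningful when its critical value 1.63/sqrt(m)
  comfortably exceeds that intrinsic bias; the default collection carries
  4 null sets per dataset so that pooling 50 datasets gives m = 200
  (critical value 0.115 ≈ 2.3 × the bias). Set sizes vary uniformly in
  [50, 300] so the discrete support mixes across sets.

- **Numerical conventions.** Spearman uses midranks (the standard
  definition; makes tied data well-defined); constant vectors give an
  undefined correlation which counts as "not co-expressed" rather than
  aborting a run. Edge retention is strictly `rho > 0.5` as printed
  (`strict: false` switches to ≥ for sensitivity checks). BH q-values use
  the step-up formula with clipping to [0, 1] and are returned in input
  order. CV uses the population standard deviation on linear values; the
  CV of an all-zero gene is defined as 0 (such genes are removed by the
  intensity floor anyway). Duplicate expression rows for one gene keep the
  highest-mean row. ANOVA is the classical fixed-effects F with an exact
  F-distribution tail; F = 0 reports p = 1.

## Problem sizes

Unit tests run on an 80-gene bundle; the calibration, recovery and
gene-set studies and the acceptance script use the default 600-gene
conditions with 50 seeds per study (a full study takes well under a minute
per batch on one core). Oracle-equivalence checks cover all 2×2 tables
with margins ≤ 12 (exact rational enumeration), 1,000 random vectors for
Spearman, 100 random graphs (≤ 50 nodes) for radiality, and 500 random
p-vectors for BH.

## Known limitations

- The default stage→period scheme is a surrogate; real-data runs must
  supply the study's own mapping.
- The background universe for gene-set enrichment (20,240 by default) and
  the brain-expressed count are independent configuration values; the
  relation between the two universes depends on the data release and is
  deliberately not guessed.
- `query_all_brain` is computed exactly; at real-data scale this is ~21 ×
  15,000 pairs per interval, which is vectorised but memory-resident. A
  seeded `max_pairs` subsampling guard is not implemented; constrained
  machines should restrict the brain-gene universe instead.
- Partner–partner edges are only included in functional-module views;
  radiality on query subnetworks otherwise reflects the bipartite-ish
  query-centred topology.
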