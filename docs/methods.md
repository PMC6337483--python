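# Methods

## The integration model

Direct data integration treats each microarray/expression study as a block
of columns of one big genes × samples matrix. The only cross-study
adjustment is per-array standardization: every array (sample column) is
replaced by `(x − mean) / sd`, mean and SD taken over all genes measured on
that array. After the transform every array has mean 0 and SD 1 (enforced
to 1e-9 in tests), so array-level location and scale differences between
platforms — and any per-array multiplicative factor — are removed exactly.
The SD uses the n−1 (sample) denominator by default; this is a convention,
switchable with `ddof=0`, and immaterial beyond a constant factor per
array.

What the transform does **not** remove is structure that varies by gene
within a study: a per-(study, gene) additive shift survives z-scoring
almost unchanged (it only gets divided by the array SD). This matters; see
*Known limitations*.

Order of operations per study: optional outlier-array screening → probe
collapse (arithmetic mean of a gene's probes, per sample) → per-array
z-score → merge on the exact intersection of gene ids. Collapsing before
standardization is a documented choice: the standardization is defined
over "all genes on the array", which after collapse means the gene-level
universe the downstream analysis actually sees.

Outlier screening (off by default) is a single-pass rule: a sample is
flagged when its mean Pearson correlation with the other arrays falls
below `mean − k·SD` (k = 2) of the per-sample mean correlations. The
original procedure this emulates was unspecified; removals are logged with
their statistic so they are auditable.

## Differential expression

Per gene, a two-group linear model on the standardized scale: `logFC` is
the case-mean minus control-mean (the conventional column name is kept
although, after z-scoring, it is a standardized mean difference rather
than a literal log fold change), with pooled residual variance `s2` on
`df = n_case + n_control − 2` degrees of freedom. Variances are shrunk
toward a prior estimated from all genes by the standard method of moments
on `log s2` (digamma/trigamma inversion; Newton solve for the trigamma
inverse, tolerance 1e-10). If the observed log-variance dispersion does
not exceed its sampling expectation the prior degrees of freedom are
infinite and the prior variance is the plain mean of the sample variances;
the total t degrees of freedom are then capped at the pooled
`n_genes × df` rather than taken to the normal limit. Genes with zero
sample variance are excluded from prior estimation and given the prior
variance in the posterior (logged). The implementation reproduces the
reference empirical-Bayes fit (limma 3.58.1) to ~1e-13 in t and p on the
frozen fixtures under `tests/data/`.

Multiple testing uses self-implemented Benjamini–Hochberg step-up
(validated against a brute-force literal-definition oracle on 1000 random
vectors). A gene is a marker when `|logFC| > log2(1.5)` **and** adjusted
p < 0.05; both thresholds are parameters. Output ordering is fully
deterministic: (p_adj, p, −|logFC|, gene id).

## Robustness protocol

Ten stratified subsamples, each keeping `floor(2/3 · n)` of the cases and
of the controls (minimum 2 per group; groups of < 3 samples are rejected),
drawn without replacement with one RNG stream per iteration. The 45
pairwise overlap values use `|A∩B| / min(|A|,|B|)` by default (symmetric,
in [0,1]; an empty list contributes 0 with a warning); Jaccard and mean
containment are options because the originating literature does not pin
the formula. Co-discovery is reported for N from 10 down to 6, as counts
and as fractions of the union (fractions rounded half-up to 2 decimals in
reports only). The 45 values share subsamples and are therefore not
independent; the Welch t-test offered by `compare_strategies` mirrors
common practice and the report carries a `dependent_pairs_caveat` flag.

## Classification validation

A linear-kernel SVM (C = 1; kernel, C, and the whole classifier are
pluggable behind a fit/predict/decision-function contract) is trained on
the discovery matrix restricted to the marker genes and applied to a
validation dataset integrated with the same per-array transform. `case` is
the positive class. ACC/SEN/SPE/MCC are computed from first principles;
any zero denominator yields 0 with an explicit flag. AUC is the
Mann–Whitney statistic with ties half-weighted; the ROC curve is a
threshold sweep over unique scores, and its trapezoidal area equals the
Mann–Whitney value to 1e-12 (property-tested). Rounding for comparison
against printed tables is decimal half-up (binary round-half-even would
turn 5/8 = 0.625 into 0.62).

## Enrichment and network stages

Over-representation p-values are exact hypergeometric upper tails computed
by log-space binomial summation (validated against exhaustive enumeration
for universes ≤ 12). The universe defaults to the genes of the integrated
dataset — not the genome — because that is the population markers were
drawn from; it is a parameter. One BH family covers all tested sets.
Immune annotation is database-free: a case-insensitive pattern (default
`immune`) on set names of the user-supplied GMT collection.

Network edges are kept when confidence is **strictly** greater than the
threshold (default 0.7; scores on [0,1] or the 0–1000 convention divided
by 1000). Hub degree is computed within the marker-induced subgraph by
default — mirroring a display in which only markers are drawn — with a
`global_degree` option counting edges to any network node, since either
reading of "connectivity to other proteins" is defensible.

## The synthetic world

`simulate_collection` emulates a seven-study case/control collection with
sizes (cases:controls) 4:1, 13:0, 14:9, 4:3, 10:0, 16:0, 7:3 — 68 cases
and 16 controls, three studies case-only. Per gene: baseline log2
intensity ~ N(7, 2²) (a typical log-intensity range; its exact shape is
immaterial because arrays are z-scored); per (study, gene) batch shift
~ N(0, batch_sd²), default 1.0; true markers (default 5% of 2000 genes)
get a ±2.0 log2 shift in case samples only, signs split 50/50; residual
noise ~ N(0, 1). Optional per-array scale factors uniform on [0.8, 1.25]
exercise the claim that standardization removes array-level scale. One RNG
stream per study is derived from the master seed by stable label hashing
(CRC32 of a label into a seed sequence), so appending a study never
perturbs earlier ones.

What the generator does **not** emulate: platform-specific probe behaviour
and nonlinear intensity response, missing values, correlated gene modules,
and — critically — any platform heterogeneity beyond additive per-gene
shifts and per-array scale. A green simulation test therefore establishes
arithmetic and statistical correctness of the pipeline under this stated
world, not performance on real cross-platform data.

Companion fixtures: `simulate_genesets` writes one `immune system process`
set whose members are drawn from the true markers with a stated enrichment
fraction (default 0.9) plus uniform background sets (20 sets of 15 genes);
`simulate_network` draws uniform-confidence random edges (default 2000
edges over 2000 genes, about one edge per gene — sparse relative to real
interaction databases) with optional exact-degree hub genes.

## Known limitations (and two deliberately red acceptance checks)

**Gene-specific batch effects confound the integrated contrast.** With
three case-only studies and 9 of the 16 controls concentrated in one
study, the group-mean difference picks up a weighted difference of
per-(study, gene) batch shifts. On the standardized scale that spurious
logFC component has SD ≈ `sqrt(Σ(n_s/N_case)² + Σ(n_s/N_ctrl)²) ·
batch_sd / array_sd` ≈ 0.27 at the default settings — the same order as
the 0.585 marker threshold. Measured over 10 seeds at the stated recovery
settings the integrated analysis attains median sensitivity 0.79 and
median FDR 0.245; the acceptance bound (sensitivity ≥ 0.8, FDR ≤ 0.1) is
therefore not met and the corresponding test is intentionally left
failing rather than weakened. This is a property of the integration
strategy itself: per-array standardization provably cannot remove
per-gene batch structure, and the pooled t sees the within-study
correlation as neither noise nor signal. The same mechanism inflates the
raw type-I fraction to ≈ 0.21 under a global null with batch_sd = 1;
calibration of the test under its own assumptions (batch_sd = 0) is
accurate (0.049 ± 0.005 over 20 seeds), which is what the null-calibration
test asserts.

**Held-out AUC saturates in the synthetic world.** In this generator a
single study's marker list is underpowered but unbiased (within-study
batch shifts cancel in its own contrast), so at the moderate-effect
comparison world (effect 1.5, noise 1.0) both the integrated and the
single-study classifiers frequently reach AUC 1.0 on the 12-sample
validation set. The integrated model is never worse (10/10 seeds at ≥) but
strictly better in only ~6/10; the strict-superiority acceptance check is
asserted as stated and left failing. Reproducing the real-data AUC gap
would require platform heterogeneity the generator intentionally does not
model. A strategy that calls no markers is scored as an uninformative
model (AUC 0.5).

**Other notes.** Expression values are assumed already log-scale
(`log2(x+1)` available on read); gene identifiers are opaque strings with
no symbol conversion; subsampling is without replacement only; the
experiment manifest records inputs, seeds and counts but no wall-clock
timestamps, so a rerun with the same config and seed is byte-identical.
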