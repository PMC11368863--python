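# Methods

## Design and contrasts

The pipeline assumes a four-condition design with a single shared baseline:
non-injured + vehicle (baseline), non-injured + drug (NC), injured + vehicle
(IV) and injured + drug (IC). All differential expression is computed
treated-vs-baseline — including IC, which is injured + drug versus the
non-injured vehicle baseline, not versus injured + vehicle. This keeps the
three state calls per gene on a common reference, which is what makes the
triple (s_NC, s_IV, s_IC) interpretable as a co-expression path: `(0,+,0)`
literally reads "unchanged by the drug alone, induced by injury, back at
baseline when injured animals receive the drug".

## Quantile normalization

Each sample's value multiset is mapped onto the reference distribution
defined as the per-rank mean of the sorted sample columns. Tied values
within a sample receive the mean of the reference values spanning their tied
ranks (the convention used by limma's `normalizeQuantiles`). Two caveats
follow directly from the tie rule and are worth stating precisely:

* the "every sorted column equals the reference" postcondition and exact
  idempotence hold exactly only for tie-free columns; with ties both hold up
  to the within-span averaging. The property tests therefore exercise them
  on continuous matrices (tie-free with probability one) and a separate
  hand-computed test pins the tie behaviour.
* the grand mean of the matrix is always preserved, ties or not, because
  within-span averaging redistributes but does not change column sums.

Normalization **replaces** size-factor estimation: the downstream NB model
consumes the normalized values directly with unit size factors. Applying
both quantile normalization and median-of-ratios scaling would correct the
same technical variation twice.

The default expression filter drops only all-zero genes (`min_total = 1`);
the surviving genes define the enrichment universe.

## Negative-binomial Wald test

Counts in group *g* are modelled as NB with mean μ_g and gene-wise
dispersion α, variance μ + αμ². For a two-group comparison with a log link
and one free mean per group, the MLE of each group mean is the group sample
mean (the score equation reduces to Σ(y_i − μ) = 0), and the Fisher
information gives Var(ln μ̂_g) ≈ (1/μ_g + α)/n_g. The Wald statistic for
the contrast is

    z = ln((μ̂_c + c₀)/(μ̂_b + c₀)) / sqrt((1/(μ̂_c + c₀) + α̂)/n_c + (1/(μ̂_b + c₀) + α̂)/n_b)

with pseudocount c₀ = 0.5 guarding against zero means (negligible at the
expression levels tested; it also keeps reported log2 fold changes finite).
p-values are two-sided normal; adjustment is Benjamini–Hochberg **within
each contrast** (states are called per contrast, so pooling would couple
the three calls through the adjustment). With α = 0 and large counts the
test agrees with a Poisson GLM Wald test to |Δp| < 0.01, which the suite
verifies against statsmodels as an independent oracle.

Dispersion estimation is deliberately simple: per gene, within-group
variances are pooled across all four conditions,
α̂_raw = max(0, (s²_pooled − μ̄)/μ̄²), a lowess trend of α̂_raw against
log10(mean + 1) (frac = 0.4) is fitted over expressed genes, and the final
estimate is the even blend 0.5·α̂_raw + 0.5·trend. The blend trades a small
bias toward the trend for a large variance reduction at 4 replicates; full
empirical-Bayes machinery (exact per-gene likelihood fits, prior-width
estimation, outlier handling) is intentionally out of scope. Genes with
zero counts everywhere get α̂ = 0 and an `all_zero` flag. Under a
2,000-gene null simulation (α = 0.1, 4 vs 4) the empirical type-I error at
p ≤ 0.05 stays within [0.03, 0.07] and the p-value distribution is uniform
to KS distance < 0.05; both are asserted in the suite at exactly those
bounds.

## State calling and the path catalog

A gene's state in a contrast is `+` if q ≤ 0.05 and log2FC ≥ 1, `−` if
q ≤ 0.05 and log2FC ≤ −1, else `0`. Both thresholds are conventional
defaults, are inclusive, and sit in the run configuration
(`q_threshold`, `lfc_threshold`) precisely because they are a choice, not a
derived quantity.

The catalog enumerates all 3³ − 1 = 26 non-null triples in lexicographic
order over the state order `+ < 0 < −`, with stable ids `path01`…`path26`.
The four anchor triples additionally carry their conventional aliases
(path2/4/5/7 as in the README) rather than forcing that numbering onto the
whole catalog. A generic alphabet hook (`enumerate_events(alphabet=...)`)
exists for testing the combinatorial identity, not as a supported analysis
mode.

The default ligand-informative selection contains 8 paths: the six triples
with s_NC = 0 and s_IV ≠ s_IC (the drug changes the injury response while
doing nothing in healthy tissue) plus (+,0,+) and (−,0,−) (consistent
injury-independent drug response). This membership is a reconstruction — a
defensible reading, not ground truth; only the four anchor paths are fixed
by their descriptions. The rule is therefore configurable: a named rule, a
predicate, or an explicit triple list in the YAML config all work, and the
selected set is recorded in the run manifest.

Path assignment is a partition by construction (each gene's triple maps to
exactly one path, null triples to the `unchanged` bucket) and the partition
identity is asserted at runtime on every call.

## Enrichment

Per path, each gene set is scored by the hypergeometric upper tail
P(X ≥ k) with N = expressed genes present in the analysis, K = set size in
that universe, n = path size, k = overlap; sets overlapping in fewer than
`min_overlap = 2` genes are not reported (singleton overlaps are noise at
typical path sizes). BH adjustment is applied across sets within each path;
the confidence score −10·log10(p) uses the raw p-value, matching the usual
axis convention for such plots. p-values are floored at 1e-300 before the
log. This is a plain hypergeometric test, not a web-service EASE-style
variant: the universe here is explicit and reproducible (the expressed-gene
background), which is the property the test suite relies on.

## Synthetic data

The generator emulates the design's essential statistics: four conditions ×
`n_reps_per_condition` replicates, per-gene baseline means log-uniform over
a range, NB noise at a common dispersion, and planted gene blocks whose
means are multiplied by 2^(±log2FC) in the conditions named by their triple.
Defaults — 2,000 genes, 4 replicates per condition (the per-group
sequencing depth of such designs is rarely published; 4 is an assumption,
stated here), means in [20, 2000], α = 0.1, |log2FC| = 2, anchor blocks of
99/82/58/23 genes — define the study conditions used throughout the tests
and the acceptance script. It does **not** emulate read-level artefacts
(GC/length bias, batch effects, library-composition skews), per-gene
dispersion trends, or correlated genes; passing tests therefore demonstrate
statistical correctness of the pipeline under its own model, not robustness
to real-data pathologies.

Planted blocks occupy leading gene indices (g00001…) — position carries no
information for any downstream stage, so shuffling would only obscure the
truth table.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale:
2,000-gene simulations with 16 samples for calibration and recovery, a
600-gene end-to-end pipeline fixture, and the exhaustive hypergeometric
oracle on the full N ≤ 12 grid. The planted-recovery condition uses
baseline means in [100, 2000] (the ≥ 90% recovery bound is a property of
adequately expressed genes; below ~20 counts the Wald test loses power, as
expected). Every stochastic stage is driven by an explicit seed; the
pipeline itself is deterministic, and re-running it on identical inputs
produces byte-identical outputs, which the manifest's input digests and the
suite both check.

## Real-data validation (optional)

Published per-path gene counts for this kind of design (e.g. 99/82/58/23
genes in the four anchor paths of the rat spinal-cord avulsion study
deposited as GEO accession GSE268237) depend on the original aligner,
counting, DE tool versions and unpublished thresholds, and are not
reproducible from simulation. Applying `copath run` to that accession's
count matrix is an optional validation exercise; path-level qualitative
agreement, not exact counts, is the realistic expectation. The synthetic
defaults plant those published sizes so the desk-scale run exercises the
same regime.

## Known limitations

* The Wald test with plug-in moment dispersions is slightly anticonservative
  at 4 replicates (empirically ~0.05–0.065 at nominal 0.05); it is
  calibrated enough for state calling with an additional |log2FC| ≥ 1
  requirement, but q-values near the threshold should not be over-read.
* No lfc shrinkage or independent filtering; low-count genes rely on the
  fold-change threshold to avoid spurious ± calls.
* BH within contrast controls FDR per contrast, not over the 3-way triple.
* The 8-path selection is a documented reconstruction (see above).
* TMM / median-of-ratios normalization are not provided; quantile
  normalization is the method, by design.
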