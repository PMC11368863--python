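# copath — multi-condition co-expression path analysis

`copath` analyses replicated RNA-seq count data from a four-condition injury /
treatment design — a shared baseline (non-injured, vehicle-treated), a
non-injured + drug group, an injured + vehicle group and an injured + drug
group — and classifies every gene by its *co-expression path*: the triple of
discrete expression states it takes across the three treated-vs-baseline
contrasts. It was written for transcriptomics analyses of drug effects in
injured spinal cord, where the question is not "which genes move" but *in
which conditions* they move: which injury-induced genes a drug returns to
baseline, and which genes respond to the drug only in injured tissue.

## The model

1. **Normalization.** Inter-sample quantile normalization: every sample's
   values are replaced by the per-rank mean of the sorted sample columns,
   ties receiving the mean reference value over their tied rank span.
2. **Differential expression.** Per gene, counts in each group are modelled
   as negative binomial with mean μ and dispersion α (variance μ + αμ²).
   Dispersions are estimated by the method of moments on pooled within-group
   residuals, α̂ = max(0, (s² − μ̄)/μ̄²), and shrunk halfway toward a lowess
   mean–dispersion trend. Each treated condition is tested against the
   baseline with a Wald test on the log mean ratio,

       z = ln(μ̂_c / μ̂_b) / sqrt((1/μ̂_c + α̂)/n_c + (1/μ̂_b + α̂)/n_b),

   with two-sided normal p-values and Benjamini–Hochberg adjustment within
   each contrast.
3. **State triples and paths.** A gene is *induced* (`+`) in a contrast when
   q ≤ 0.05 and log2FC ≥ 1, *repressed* (`−`) when q ≤ 0.05 and
   log2FC ≤ −1, else *non-DE* (`0`). Over the three contrasts
   (NC, IV, IC) this gives one of 3³ = 27 triples; excluding the all-null
   triple leaves **26 combinatorial co-expression events**. A configurable
   selection rule flags the **8 ligand-informative paths** from which a drug
   effect in injured tissue can be read, including the four anchor paths:
   `path2` = (0,0,+) drug-specific induction, `path4` = (0,+,0) return to
   baseline after injury induction, `path5` = (0,−,0) return to baseline
   after injury repression, `path7` = (0,0,−) drug-specific repression.
4. **Enrichment.** Each path's gene list is tested for over-representation
   of every gene set (GMT) by the hypergeometric upper tail against the
   expressed-gene universe; the reported confidence is −10·log10(p).

A seeded synthetic generator (`copath.simulate`) produces NB counts with
genes planted into chosen state triples plus a truth table, so the whole
pipeline is testable end to end without external data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `analysis/01_simulate.py` plants the four anchor paths in blocks of
99/82/58/23 genes (|log2FC| = 2, α = 0.1, 4 replicates per condition) among
2,000 genes; `analysis/02_run_pipeline.py` runs the pipeline and prints the
per-path summary:

```
  path_id triple alias  selected  n_genes
   path11    0+0 path4      True       82
   path13    00+ path2      True       98
   path14    00- path7      True       27
   path16    0-0 path5      True       62
   path17    0--            False        1
unchanged    000            False     1730
```

The four planted anchor paths dominate the called paths at close to their
planted sizes; one gene leaks into a neighbouring path and the remaining
nulls stay `unchanged`. `analysis/03_score_recovery.py` scores the calls
against the truth table:

```
   path  n_true  n_predicted   tp  precision   recall       f1  accuracy
    0+0      82           82   80   0.975610 0.975610 0.975610
    0-0      58           62   56   0.903226 0.965517 0.933333
    00+      99           98   96   0.979592 0.969697 0.974619
    00-      23           27   23   0.851852 1.000000 0.920000
overall    2000         2000 1979                                 0.9895
```

i.e. mean anchor-path recall 0.978 and overall state-triple accuracy 0.990.
`analysis/04_null_calibration.py` checks the Wald test on a null simulation:
the fraction of raw p ≤ 0.05 is 0.052–0.064 across the three contrasts
(nominal 0.05) and no gene passes q ≤ 0.05.

The same steps are available as a CLI:

```bash
copath simulate --out data/ --seed 1
copath run --counts data/counts.tsv --samples data/samples.csv \
           --gmt data/gene_sets.gmt --out run/
copath score --assignments run/gene_paths.tsv --truth data/truth.tsv
```

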