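#!/usr/bin/env python
"""Generate the synthetic study dataset.

Four conditions (baseline, non-injured+drug, injured+vehicle, injured+drug),
4 replicates each, 2,000 NB genes with the four anchor co-expression paths
planted at |log2FC| = 2 in blocks of 99/82/58/23 genes.  Large files go to
scratch/data/; the truth-table composition is summarised on stdout.
"""

from pathlib import Path

from copath import SimulationConfig, simulate_counts
from copath import io as cio
from copath.simulate import make_gene_sets

SEED = 20240901
OUT = Path("scratch/data")


def main() -> None:
    config = SimulationConfig(baseline_mean_range=(100.0, 2000.0), seed=SEED)
    counts, design, truth = simulate_counts(config)
    OUT.mkdir(parents=True, exist_ok=True)
    cio.write_counts(counts, OUT / "counts.tsv")
    cio.write_sample_sheet(design, OUT / "samples.csv")
    cio.write_truth(truth, OUT / "truth.tsv")
    cio.write_gmt(make_gene_sets(truth, seed=SEED + 1), OUT / "gene_sets.gmt")

    triples = truth.groupby(["state_NC", "state_IV", "state_IC"]).size()
    print(f"wrote {counts.shape[0]} genes x {counts.shape[1]} samples under {OUT}")
    print("planted composition (state_NC, state_IV, state_IC -> n genes):")
    print(triples.to_string())


if __name__ == "__main__":
    main()
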