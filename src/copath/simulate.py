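"""Synthetic replicated RNA-seq counts with planted co-expression paths.

Counts are negative-binomial with the DESeq-style parameterisation
``variance = mu + alpha * mu**2``; ``alpha = 0`` degenerates to Poisson.
Genes are planted into specified state triples ``(s_NC, s_IV, s_IC)`` at a
given |log2 fold change| relative to the baseline condition; the remaining
genes are null with triple ``(0, 0, 0)``.  A machine-readable truth table
records every gene's true triple and per-condition log2 fold change, so
downstream state calling and path assignment can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from copath.design import CONDITIONS, CONTRAST_CONDITIONS, CONTRASTS, SampleDesign

Triple = tuple[str, str, str]

#: The four anchor paths the drug's effect is read from: drug-specific
#: induction (0,0,+), return-to-basal after injury induction (0,+,0),
#: return-to-basal after injury repression (0,-,0), drug-specific
#: repression (0,0,-).  Default block sizes (99 / 82 / 58 / 23) emulate
#: anchor-path sizes typical of the target application.
DEFAULT_PLANTED: tuple["PlantedPath", ...] = ()  # filled in after the class


@dataclass(frozen=True)
class PlantedPath:
    """A block of genes sharing one true state triple.

    ``log2fc`` is the magnitude applied with the sign of each non-zero state
    in the triple; it must be positive whenever the triple is non-null.
    """

    triple: Triple
    n_genes: int
    log2fc: float = 2.0

    def __post_init__(self) -> None:
        if len(self.triple) != 3 or any(s not in {"+", "0", "-"} for s in self.triple):
            raise ValueError(f"invalid state triple {self.triple!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.triple != ("0", "0", "0") and not self.log2fc > 0:
            raise ValueError("log2fc magnitude must be > 0 for a non-null triple")

    def lfc_vector(self) -> dict[str, float]:
        """Per-contrast signed log2 fold change implied by the triple."""
        sign = {"+": 1.0, "0": 0.0, "-": -1.0}
        return {c: sign[s] * self.log2fc for c, s in zip(CONTRASTS, self.triple)}


DEFAULT_PLANTED = (
    PlantedPath(("0", "0", "+"), 99),
    PlantedPath(("0", "+", "0"), 82),
    PlantedPath(("0", "-", "0"), 58),
    PlantedPath(("0", "0", "-"), 23),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 2,000 genes, 4 replicates per condition,
    baseline means log-uniform in [20, 2000], dispersion 0.1, planted
    |log2FC| 2."""

    n_genes: int = 2000
    n_reps_per_condition: int = 4
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.1
    planted_paths: tuple[PlantedPath, ...] = DEFAULT_PLANTED
    library_size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_reps_per_condition <= 0:
            raise ValueError("n_reps_per_condition must be positive")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ValueError("baseline_mean_range must satisfy 0 < lo <= hi")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_planted = sum(p.n_genes for p in self.planted_paths)
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        n_samples = len(CONDITIONS) * self.n_reps_per_condition
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != n_samples:
                raise ValueError(
                    f"need {n_samples} size factors, got {len(self.library_size_factors)}"
                )
            if any(s <= 0 for s in self.library_size_factors):
                raise ValueError("size factors must be positive")

    @property
    def n_samples(self) -> int:
        return len(CONDITIONS) * self.n_reps_per_condition


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha  # NB 'number of successes' parameter
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame]:
    """Simulate counts, the sample design, and the truth table.

    Returns
    -------
    counts
        genes x samples integer DataFrame.
    design
        :class:`SampleDesign` over the four conditions.
    truth
        One row per gene: true state triple and per-contrast log2FC.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_reps = config.n_genes, config.n_reps_per_condition

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    sample_ids, conditions = [], []
    for cond in CONDITIONS:
        for r in range(1, n_reps + 1):
            sample_ids.append(f"{cond}_{r}")
            conditions.append(cond)
    design = SampleDesign(dict(zip(sample_ids, conditions)))

    lo, hi = config.baseline_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))

    # per-gene per-contrast signed log2FC (planted blocks occupy leading genes)
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=list(CONTRASTS))
    states = pd.DataFrame("0", index=gene_ids, columns=[f"state_{c}" for c in CONTRASTS])
    cursor = 0
    for planted in config.planted_paths:
        block = gene_ids[cursor : cursor + planted.n_genes]
        cursor += planted.n_genes
        for contrast, value in planted.lfc_vector().items():
            lfc.loc[block, contrast] = value
        for contrast, s in zip(CONTRASTS, planted.triple):
            states.loc[block, f"state_{contrast}"] = s

    size_factors = (
        np.ones(config.n_samples)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )

    counts = np.empty((n_genes, config.n_samples), dtype=np.int64)
    cond_of_contrast = {v: k for k, v in CONTRAST_CONDITIONS.items()}
    for j, (sample, cond) in enumerate(zip(sample_ids, conditions)):
        gene_lfc = (
            np.zeros(n_genes)
            if cond == design.baseline
            else lfc[cond_of_contrast[cond]].to_numpy()
        )
        mu = base_mean * np.exp2(gene_lfc) * size_factors[j]
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "state_NC": states["state_NC"].to_numpy(),
            "state_IV": states["state_IV"].to_numpy(),
            "state_IC": states["state_IC"].to_numpy(),
            "lfc_NC": lfc["NC"].to_numpy(),
            "lfc_IV": lfc["IV"].to_numpy(),
            "lfc_IC": lfc["IC"].to_numpy(),
            "base_mean": base_mean,
        }
    )
    return counts_df, design, truth


def make_gene_sets(
    truth: pd.DataFrame,
    seed: int,
    n_random_sets: int = 40,
    random_set_size: tuple[int, int] = (20, 120),
    background_fraction: float = 0.3,
) -> dict[str, list[str]]:
    """Build synthetic gene sets for over-representation testing.

    One set per planted (non-null) triple containing that block's genes
    diluted with random background genes, plus ``n_random_sets`` sets drawn
    uniformly from the whole universe.  Planted sets should rank at the top
    of their path's enrichment table; random sets should not.
    """
    rng = np.random.default_rng(seed)
    genes = truth["gene_id"].to_numpy()
    triples = list(zip(truth["state_NC"], truth["state_IV"], truth["state_IC"]))
    sets: dict[str, list[str]] = {}

    null = ("0", "0", "0")
    for triple in dict.fromkeys(t for t in triples if t != null):
        members = [g for g, t in zip(genes, triples) if t == triple]
        n_extra = max(1, int(background_fraction * len(members)))
        extra = rng.choice(genes, size=n_extra, replace=False).tolist()
        label = "".join({"+": "p", "0": "z", "-": "m"}[s] for s in triple)
        sets[f"PLANTED_{label}"] = list(dict.fromkeys(members + extra))

    lo, hi = random_set_size
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{i + 1:03d}"] = rng.choice(genes, size=size, replace=False).tolist()
    return sets
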