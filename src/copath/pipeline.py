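"""One-command orchestration: normalize -> DE -> classify -> enrich.

``run_pipeline`` reads a raw count matrix, a sample sheet and a GMT file,
and writes into the output directory:

* ``normalized_counts.tsv`` -- quantile-normalized, filtered matrix
* ``de_NC.tsv``, ``de_IV.tsv``, ``de_IC.tsv`` -- per-contrast Wald results
* ``gene_paths.tsv`` -- per-gene state triple and path assignment
* ``path_summary.tsv`` -- per-path gene counts and selection flags
* ``enrichment.tsv`` -- per-path gene-set over-representation
* ``manifest.json`` -- config snapshot, input digests, per-stage row counts

Everything is deterministic given the inputs, so re-running reproduces
byte-identical outputs; the manifest digests detect any input edit.
``score_recovery`` compares path assignments against a simulation truth
table.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import copath
from copath import io as cio
from copath.de import estimate_dispersion, test_all_contrasts
from copath.design import CONTRASTS, SampleDesign
from copath.enrich import enrich_all_paths
from copath.normalize import filter_unexpressed, quantile_normalize
from copath.paths import (
    UNCHANGED,
    PathCatalog,
    StateCallConfig,
    assign_genes,
    call_states,
    enumerate_events,
    select_ligand_paths,
    summarize_paths,
)

log = logging.getLogger("copath")


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level knobs, all surfaced in the manifest.

    ``selection_rule`` is a named rule or an explicit list of triples (each
    a 3-character string over ``+0-``), so alternative readings of the
    ligand-informative subset are one config edit away.
    """

    q_threshold: float = 0.05
    lfc_threshold: float = 1.0
    min_total: float = 1.0
    min_overlap: int = 2
    shrink_weight: float = 0.5
    selection_rule: str | tuple[str, ...] = "default"

    def state_call_config(self) -> StateCallConfig:
        return StateCallConfig(self.q_threshold, self.lfc_threshold)

    def resolve_rule(self):
        if isinstance(self.selection_rule, str):
            return self.selection_rule
        return [tuple(t) for t in self.selection_rule]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if isinstance(raw.get("selection_rule"), list):
            raw["selection_rule"] = tuple(raw["selection_rule"])
        return cls(**raw)


def build_catalog(config: PipelineConfig) -> PathCatalog:
    return select_ligand_paths(enumerate_events(), config.resolve_rule())


def run_pipeline(
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    gmt_path: str | os.PathLike | None,
    out_dir: str | os.PathLike,
    config: PipelineConfig = PipelineConfig(),
) -> Path:
    """Run the full analysis; returns the output directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = cio.read_counts(counts_path)
    design = cio.read_sample_sheet(samples_path)
    design.require_complete()
    missing = [s for s in design.samples if s not in counts.columns]
    if missing:
        raise ValueError(f"sample sheet names samples absent from counts: {missing}")
    counts = counts.loc[:, design.samples]
    gene_sets = cio.read_gmt(gmt_path) if gmt_path is not None else None

    stage_counts: dict[str, int] = {"input_genes": int(counts.shape[0])}
    log.info("input: %d genes x %d samples", *counts.shape)

    filtered = filter_unexpressed(counts, config.min_total)
    stage_counts["filtered_genes"] = int(filtered.shape[0])
    log.info("filter_unexpressed(min_total=%s): %d genes kept", config.min_total, len(filtered))

    normalized = quantile_normalize(filtered)
    cio.write_counts(normalized, out / "normalized_counts.tsv", decimals=6)

    dispersions = estimate_dispersion(normalized, design, config.shrink_weight)
    de = test_all_contrasts(normalized, design, dispersions)
    for c in CONTRASTS:
        de[c].drop(columns=["contrast"]).to_csv(
            out / f"de_{c}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        stage_counts[f"de_{c}_genes"] = int(len(de[c]))

    catalog = build_catalog(config)
    calls = call_states(de, config.state_call_config())
    assignments = assign_genes(calls, catalog)
    summary = summarize_paths(assignments, catalog)
    assignments.to_csv(out / "gene_paths.tsv", sep="\t", index=False)
    summary.to_csv(out / "path_summary.tsv", sep="\t", index=False)
    stage_counts["assigned_genes"] = int(len(assignments))
    stage_counts["unchanged_genes"] = int((assignments["path_id"] == UNCHANGED).sum())
    log.info(
        "paths: %d genes in %d non-null paths, %d unchanged",
        stage_counts["assigned_genes"] - stage_counts["unchanged_genes"],
        int((summary["n_genes"] > 0).sum() - (stage_counts["unchanged_genes"] > 0)),
        stage_counts["unchanged_genes"],
    )

    if gene_sets is not None:
        universe = normalized.index.astype(str)
        enrichment = enrich_all_paths(
            assignments, gene_sets, universe, config.min_overlap
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        stage_counts["enrichment_rows"] = int(len(enrichment))

    manifest = {
        "tool": "copath",
        "version": copath.__version__,
        "config": {**asdict(config), "selection_rule": list(np.atleast_1d(config.selection_rule))
                   if not isinstance(config.selection_rule, str) else config.selection_rule},
        "inputs": {
            "counts": {"path": str(counts_path), "sha256": cio.file_sha256(counts_path)},
            "samples": {"path": str(samples_path), "sha256": cio.file_sha256(samples_path)},
            **(
                {"gmt": {"path": str(gmt_path), "sha256": cio.file_sha256(gmt_path)}}
                if gmt_path is not None
                else {}
            ),
        },
        "stage_counts": stage_counts,
        "selected_paths": ["".join(t) for t in catalog.selected_events()],
    }
    # conservation check: genes survive filtering through every stage intact
    for key in ("de_NC_genes", "de_IV_genes", "de_IC_genes", "assigned_genes"):
        if stage_counts[key] != stage_counts["filtered_genes"]:
            raise AssertionError(f"stage row counts inconsistent at {key}")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


# ---------------------------------------------------------------------------
# truth-table scoring


def score_recovery(assignments: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-path precision/recall/F1 of assignments against a truth table.

    Paths are compared as state triples.  The final row ``overall`` reports
    triple accuracy over all genes (fraction of genes whose called triple
    equals the true one).  Metrics undefined for a path (no truth genes, or
    no predicted genes) are NA.
    """
    a_cols = [f"state_{c}" for c in CONTRASTS]
    pred = assignments.set_index("gene_id")[a_cols]
    true = truth.set_index("gene_id")[a_cols]
    only_pred = pred.index.difference(true.index)
    only_true = true.index.difference(pred.index)
    if len(only_pred) or len(only_true):
        ex = list(only_pred[:3]) + list(only_true[:3])
        raise ValueError(f"gene ids do not match between assignments and truth: {ex}")
    true = true.loc[pred.index]

    pred_t = pred.apply(tuple, axis=1)
    true_t = true.apply(tuple, axis=1)
    null = ("0",) * len(a_cols)

    rows = []
    for triple in sorted(set(true_t) | set(pred_t)):
        if triple == null:
            continue
        tp = int(((pred_t == triple) & (true_t == triple)).sum())
        n_pred = int((pred_t == triple).sum())
        n_true = int((true_t == triple).sum())
        precision = tp / n_pred if n_pred else np.nan
        recall = tp / n_true if n_true else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if n_pred and n_true and (precision + recall) > 0
            else np.nan
        )
        rows.append(
            {
                "path": "".join(triple),
                "n_true": n_true,
                "n_predicted": n_pred,
                "tp": tp,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    accuracy = float((pred_t == true_t).mean())
    rows.append(
        {
            "path": "overall",
            "n_true": len(true_t),
            "n_predicted": len(pred_t),
            "tp": int((pred_t == true_t).sum()),
            "precision": np.nan,
            "recall": np.nan,
            "f1": np.nan,
            "accuracy": accuracy,
        }
    )
    out = pd.DataFrame(rows)
    if "accuracy" not in out.columns:
        out["accuracy"] = np.nan
    return out
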