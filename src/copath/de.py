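"""Per-gene negative-binomial Wald tests of each condition against baseline.

Model: counts in group g are NB with mean ``mu_g`` and shared per-gene
dispersion ``alpha`` (variance ``mu + alpha * mu**2``).  For a two-group
contrast with a log link and one free mean per group, the maximum-likelihood
estimate of each group mean is the group sample mean, and the Wald statistic
for the log ratio follows from the Fisher information:

    Var(log mu_hat_g) ~= (1/mu_g + alpha) / n_g

Dispersions are estimated per gene by the method of moments on pooled
within-group residuals and shrunk toward a lowess mean-dispersion trend.
This is a deliberately compact stand-in for DESeq2-style machinery: Wald
test, no likelihood-ratio test, no independent filtering, no fold-change
shrinkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from copath.design import CONTRAST_CONDITIONS, SampleDesign

#: pseudocount used when reporting log2 fold changes and stabilising the
#: Wald variance at very low means
PSEUDOCOUNT = 0.5


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Raises on NaN input; values must lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_dispersion(
    m: pd.DataFrame,
    design: SampleDesign,
    shrink_weight: float = 0.5,
    lowess_frac: float = 0.4,
) -> pd.DataFrame:
    """Method-of-moments dispersion per gene, shrunk toward the mean trend.

    The raw estimate pools within-group variances across all conditions:
    ``alpha_raw = max(0, (s2_pooled - mean) / mean**2)``.  A lowess trend of
    ``alpha_raw`` against log10 mean is fitted over expressed genes and the
    final estimate is ``(1 - w) * alpha_raw + w * trend`` with
    ``w = shrink_weight``.  Genes with zero mean everywhere get alpha 0 and
    are flagged ``all_zero``.

    Returns a DataFrame indexed by gene with columns ``alpha_raw``,
    ``alpha_trend``, ``alpha``, ``all_zero``.
    """
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    groups = [design.samples_for(c) for c in design.conditions_present()]
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("dispersion estimation needs >= 2 replicates in >= 1 group")

    values = m.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(m.columns)}

    ss = np.zeros(m.shape[0])  # pooled within-group sum of squares
    df = 0
    total = np.zeros(m.shape[0])
    n_total = 0
    for samples in groups:
        idx = [cols[s] for s in samples]
        sub = values[:, idx]
        gmean = sub.mean(axis=1)
        total += sub.sum(axis=1)
        n_total += len(idx)
        if len(idx) >= 2:
            ss += ((sub - gmean[:, None]) ** 2).sum(axis=1)
            df += len(idx) - 1
    s2 = ss / df
    mean = total / n_total

    all_zero = mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(all_zero, 0.0, np.maximum(0.0, (s2 - mean) / mean**2))

    # trend over expressed genes; constant fallback for tiny matrices
    expressed = ~all_zero
    if expressed.sum() >= 10:
        x = np.log10(mean[expressed] + 1.0)
        fitted = lowess(
            alpha_raw[expressed], x, frac=lowess_frac, return_sorted=False
        )
        trend = np.zeros_like(alpha_raw)
        trend[expressed] = np.maximum(0.0, fitted)
    else:
        trend = np.full_like(alpha_raw, alpha_raw[expressed].mean() if expressed.any() else 0.0)
        trend[all_zero] = 0.0

    alpha = (1 - shrink_weight) * alpha_raw + shrink_weight * trend
    return pd.DataFrame(
        {
            "alpha_raw": alpha_raw,
            "alpha_trend": trend,
            "alpha": alpha,
            "all_zero": all_zero,
        },
        index=m.index,
    )


def test_contrast(
    m: pd.DataFrame,
    design: SampleDesign,
    contrast: str,
    dispersions: pd.DataFrame | pd.Series,
) -> pd.DataFrame:
    """Wald test of one treated condition against the baseline.

    Parameters
    ----------
    m
        genes x samples matrix (raw or normalized; the model consumes the
        values as-is, so a normalized matrix implies unit size factors).
    contrast
        One of ``NC``, ``IV``, ``IC``.
    dispersions
        Per-gene alpha as returned by :func:`estimate_dispersion` (the
        ``alpha`` column is used) or a plain Series aligned to ``m``.

    Returns a DataFrame with columns ``gene_id``, ``contrast``,
    ``baseMean_baseline``, ``baseMean_condition``, ``log2FC``, ``pvalue``,
    ``padj``, ``dispersion``.
    """
    if contrast not in CONTRAST_CONDITIONS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {list(CONTRAST_CONDITIONS)}")
    condition = CONTRAST_CONDITIONS[contrast]
    base_samples = design.samples_for(design.baseline)
    cond_samples = design.samples_for(condition)
    if not cond_samples:
        raise ValueError(f"design has no samples for condition {condition!r}")
    if len(base_samples) < 2 or len(cond_samples) < 2:
        raise ValueError(
            f"contrast {contrast}: baseline and condition each need >= 2 samples"
        )

    alpha = (
        dispersions["alpha"] if isinstance(dispersions, pd.DataFrame) else dispersions
    )
    alpha = alpha.reindex(m.index).to_numpy(dtype=float)
    if np.isnan(alpha).any():
        raise ValueError("dispersions missing for some genes in the matrix")

    mu_b = m.loc[:, base_samples].to_numpy(dtype=float).mean(axis=1)
    mu_c = m.loc[:, cond_samples].to_numpy(dtype=float).mean(axis=1)
    n_b, n_c = len(base_samples), len(cond_samples)

    c0 = PSEUDOCOUNT
    beta = np.log((mu_c + c0) / (mu_b + c0))  # natural-log ratio
    var_beta = (1.0 / (mu_c + c0) + alpha) / n_c + (1.0 / (mu_b + c0) + alpha) / n_b
    z = beta / np.sqrt(var_beta)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)

    return pd.DataFrame(
        {
            "gene_id": m.index.astype(str),
            "contrast": contrast,
            "baseMean_baseline": mu_b,
            "baseMean_condition": mu_c,
            "log2FC": beta / np.log(2.0),
            "pvalue": p,
            "padj": bh_adjust(p),
            "dispersion": alpha,
        }
    ).set_index(m.index)


def test_all_contrasts(
    m: pd.DataFrame, design: SampleDesign, dispersions: pd.DataFrame | pd.Series
) -> dict[str, pd.DataFrame]:
    """Run all three contrasts against the shared baseline."""
    return {c: test_contrast(m, design, c, dispersions) for c in CONTRAST_CONDITIONS}


# these are statistical tests, not pytest tests; keep collectors away
test_contrast.__test__ = False  # type: ignore[attr-defined]
test_all_contrasts.__test__ = False  # type: ignore[attr-defined]
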