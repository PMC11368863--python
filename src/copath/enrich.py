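"""Per-path gene-set over-representation with a confidence transform.

For a path of ``n`` genes drawn from a universe of ``N`` annotatable genes,
a set of size ``K`` overlapping the path in ``k`` genes is scored by the
hypergeometric upper tail P(X >= k).  The reported confidence is
``-10 * log10(p)`` of the raw p-value; BH adjustment is applied across sets
within each path.  This is a local, fully reproducible replacement for a
web-service enrichment step (plain hypergeometric, not the EASE variant),
with the expressed-gene background as the universe.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from copath.de import bh_adjust

#: floor for p-values before the log transform
P_FLOOR = 1e-300


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` set size, ``n`` path (sample) size,
    ``k`` observed overlap.
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"need 0 <= n, K <= N; got n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    # sf(k-1) = P(X >= k); exact at k = 0 (upper tail from zero is 1)
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def harmonize_sets(
    sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> tuple[dict[str, set[str]], set[str]]:
    """Restrict set members to the universe; drop sets emptied by that."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    out = {}
    for name, members in sets.items():
        kept = set(members) & uni
        if kept:
            out[name] = kept
    return out, uni


def enrich_path(
    path_genes: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_overlap: int = 2,
    path_id: str = "",
) -> pd.DataFrame:
    """Over-representation of every gene set in one path's gene list.

    Path genes outside the universe are dropped (their number is recorded in
    the ``n_dropped`` attribute of the result).  Sets overlapping the path in
    fewer than ``min_overlap`` genes are not reported.  Results are BH
    adjusted across the reported sets and sorted by confidence descending.
    """
    harmonized, uni = harmonize_sets(sets, universe)
    genes = set(path_genes)
    dropped = len(genes - uni)
    genes &= uni
    N, n = len(uni), len(genes)

    rows = []
    for name, members in harmonized.items():
        k = len(genes & members)
        if k < min_overlap:
            continue
        p = hypergeom_test(k, n, len(members), N)
        rows.append((path_id, name, k, n, len(members), N, p))
    result = pd.DataFrame(
        rows, columns=["path_id", "set_name", "k", "n", "K", "N", "pvalue"]
    )
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result["confidence"] = -10.0 * np.log10(np.maximum(result["pvalue"], P_FLOOR))
        result = result.sort_values(
            ["confidence", "set_name"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    else:
        result["padj"] = pd.Series(dtype=float)
        result["confidence"] = pd.Series(dtype=float)
    result.attrs["n_dropped"] = dropped
    return result


def enrich_all_paths(
    assignments: pd.DataFrame,
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_overlap: int = 2,
    selected_only: bool = False,
) -> pd.DataFrame:
    """Enrichment tables for every path with assigned genes, concatenated."""
    frames = []
    grouped = assignments[assignments["path_id"] != "unchanged"]
    if selected_only:
        grouped = grouped[grouped["selected"]]
    for pid, sub in grouped.groupby("path_id", sort=True):
        table = enrich_path(sub["gene_id"], sets, universe, min_overlap, path_id=pid)
        if len(table):
            frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["path_id", "set_name", "k", "n", "K", "N", "pvalue", "padj", "confidence"]
        )
    return pd.concat(frames, ignore_index=True)
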