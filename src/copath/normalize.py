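"""Inter-sample quantile normalization and expression filtering.

Quantile normalization forces every sample to share one reference
distribution: the per-rank mean of the sorted sample columns.  Ties within a
column receive the mean of the reference values spanning their tied ranks,
so the map is well defined and idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    pass


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes x samples matrix.

    After normalization every column holds the same multiset of values (the
    per-rank mean of the sorted input columns); gene and sample ordering is
    preserved.  A single-sample matrix is returned unchanged with a warning,
    an empty matrix is an error.
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise NormalizationError("cannot normalize an empty matrix")
    if m.shape[1] == 1:
        warnings.warn("single sample: quantile normalization is the identity")
        return m.astype(float)

    values = m.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = reference
        # ties share the mean reference value over their tied rank span
        out[:, j] = pd.Series(ranked).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def filter_unexpressed(m: pd.DataFrame, min_total: float = 1) -> pd.DataFrame:
    """Drop genes whose total count across samples is below ``min_total``.

    The default removes only all-zero genes.  Row order of survivors is
    preserved.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = m.sum(axis=1) >= min_total
    return m.loc[keep]
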