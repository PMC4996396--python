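"""Quantile normalization: force every array onto the common quantile profile."""

from __future__ import annotations

import numpy as np
import pandas as pd


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map each array's values onto the across-array mean of sorted columns.

    Ties within an array receive the mean of the reference values over the
    tied rank span, so the result is invariant to input row permutations.
    Requires a complete matrix (impute first).
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; run knn_impute first")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference over spans of tied values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [col.size]])
        for s, e in zip(starts, ends):
            if e - s > 1:
                ranked[order[s:e]] = reference[s:e].mean()
        out[:, j] = ranked
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
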