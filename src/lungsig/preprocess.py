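"""Preprocessing of spot tables into a complete log2 intensity matrix.

The fixed pipeline order is: intensity floor -> log2 -> duplicate-spot
averaging -> flagged-feature exclusion -> KNN imputation.  Flags act at the
spot level: a flagged spot is dropped before averaging, so a feature becomes
missing on an array only when both duplicates are unusable.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

#: Study constants: minimum-intensity threshold, flag-exclusion fraction,
#: imputation neighborhood.
INTENSITY_FLOOR = 100.0
MAX_FLAG_FRACTION = Fraction(1, 2)
KNN_NEIGHBORS = 10


def floor_and_log2(intensity, floor: float = INTENSITY_FLOOR) -> np.ndarray:
    """Clamp raw intensities below ``floor`` (including non-positives left by
    background subtraction) to ``floor``, then log2-transform."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    values = np.asarray(intensity, dtype=float)
    return np.log2(np.maximum(values, floor))


def average_duplicates(spot_table: pd.DataFrame, floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Collapse duplicate spots into a features x arrays log2 matrix.

    Flagged spots are treated as missing before averaging; a feature/array
    cell with one usable duplicate keeps that value, with none becomes NaN.
    Control spots are excluded.  A feature printed more than twice on an
    array violates the duplicate design and raises.
    """
    spots = spot_table[spot_table["control_type"] == "none"].copy()
    counts = spots.groupby(["feature_id", "array_id"], sort=False).size()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise ValueError(
            f"feature {bad[0]!r} has {counts.loc[bad]} spots on array {bad[1]!r}; "
            "duplicate printing allows at most 2"
        )
    spots["log2"] = floor_and_log2(spots["intensity"].to_numpy(), floor)
    spots.loc[spots["flag"].astype(bool), "log2"] = np.nan
    matrix = spots.pivot_table(
        index="feature_id", columns="array_id", values="log2", aggfunc="mean"
    )
    # preserve first-appearance feature order and array order of the table
    feature_order = spots["feature_id"].drop_duplicates().to_numpy()
    array_order = spots["array_id"].drop_duplicates().to_numpy()
    return matrix.reindex(index=feature_order, columns=array_order)


def filter_flagged_features(
    matrix: pd.DataFrame, max_flag_frac: Fraction | float = MAX_FLAG_FRACTION
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features missing on at least ``max_flag_frac`` of the arrays.

    The threshold wording is "at least", hence an inclusive comparison, done
    on exact rationals so e.g. 2 missing of 4 arrays at 1/2 drops the feature.
    """
    frac = Fraction(max_flag_frac).limit_denominator(10**6)
    if not 0 < frac <= 1:
        raise ValueError("max_flag_frac must lie in (0, 1]")
    n_arrays = matrix.shape[1]
    n_missing = matrix.isna().sum(axis=1)
    dropped = [
        f
        for f, m in n_missing.items()
        if Fraction(int(m), n_arrays) >= frac
    ]
    return matrix.drop(index=dropped), dropped


def knn_impute(matrix: pd.DataFrame, k: int = KNN_NEIGHBORS) -> pd.DataFrame:
    """Feature-wise K-nearest-neighbour imputation (the microarray convention).

    A missing cell (g, j) is replaced by the mean over array j of the k
    features nearest to g in Euclidean distance computed on the arrays where
    both features are observed (distances scaled to the per-pair overlap).
    Candidate neighbours must themselves be observed on array j.  Distance
    ties break by feature order, k clamps to the available candidates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float)
    missing = np.isnan(values)
    if not missing.any():
        return matrix.copy()
    entirely_missing = missing.all(axis=1)
    if entirely_missing.any():
        bad = matrix.index[entirely_missing][0]
        raise ValueError(
            f"feature {bad!r} has no observed values; filter it before imputing"
        )
    out = values.copy()
    observed = ~missing
    filled = np.where(missing, 0.0, values)
    n_features = values.shape[0]
    for g in np.flatnonzero(missing.any(axis=1)):
        # mean squared difference over co-observed arrays, for all features at once
        co = observed & observed[g]
        n_co = co.sum(axis=1)
        diff = (filled - filled[g]) * co
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(n_co > 0, (diff**2).sum(axis=1) / n_co, np.inf)
        dist[g] = np.inf
        for j in np.flatnonzero(missing[g]):
            candidates = np.flatnonzero(observed[:, j] & np.isfinite(dist))
            if candidates.size == 0:
                out[g, j] = np.nanmean(values[:, j])
                continue
            order = candidates[np.lexsort((candidates, dist[candidates]))]
            nearest = order[: min(k, order.size)]
            out[g, j] = values[nearest, j].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def drop_constant_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove features with zero variance across arrays.

    A feature whose every observed value sits at the intensity floor (a dead
    antigen censored on all arrays) carries no information and breaks any
    scale-modelling downstream, so it is excluded alongside flag-filtered
    features.
    """
    values = matrix.to_numpy(float)
    with np.errstate(invalid="ignore"):
        # tolerance absorbs float dust left by duplicate averaging
        constant = np.nanvar(values, axis=1) <= 1e-20
    dropped = matrix.index[constant].tolist()
    return matrix.drop(index=dropped), dropped


def preprocess_spot_table(
    spot_table: pd.DataFrame,
    floor: float = INTENSITY_FLOOR,
    max_flag_frac: Fraction | float = MAX_FLAG_FRACTION,
    k: int = KNN_NEIGHBORS,
) -> tuple[pd.DataFrame, list[str]]:
    """Full pipeline: floor -> log2 -> average duplicates -> filter -> impute.

    Returns the complete matrix and the list of excluded feature ids
    (flag-filtered plus zero-variance features).
    """
    matrix = average_duplicates(spot_table, floor=floor)
    matrix, dropped = filter_flagged_features(matrix, max_flag_frac)
    matrix, constant = drop_constant_features(matrix)
    return knn_impute(matrix, k=k), dropped + constant


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x arrays matrix as TSV with 'NA' for missing cells."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id", na_values="NA")
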