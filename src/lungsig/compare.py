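"""Class comparison, significant-antigen concordance, and sample size.

The study's criterion for ranking pre-processing strategies is not the raw
count of significant antigens but their stability: the overlap between the
significant list from a single processing run and the list from the
combined (cross-run) analysis of the same histology.  A batch-adjustment
method that works should make findings survive the merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CROSS_RUN_PAIRS, HISTOLOGIES

ALPHA = 0.001  # study-wide class-comparison significance threshold


@dataclass
class ComparisonResult:
    """Per-feature two-sample test results and the significant list."""

    table: pd.DataFrame  # feature, diff, t, df, p (NaN where undefined)
    alpha: float
    significant: list[str]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["significant"] = out.index.isin(self.significant)
        out.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def class_comparison(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = ALPHA,
    equal_var: bool = True,
) -> ComparisonResult:
    """Per-feature two-sample t-test, case vs. control.

    ``labels`` holds 'case'/'control' per array.  The pooled-variance test is
    the default (the era's class-comparison convention); ``equal_var=False``
    switches to Welch.  Features whose pooled within-group variance is zero
    get p = NA and never enter the significant list.
    """
    labels = labels.reindex(matrix.columns)
    case = matrix.loc[:, (labels == "case").to_numpy()].to_numpy(float)
    ctrl = matrix.loc[:, (labels == "control").to_numpy()].to_numpy(float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError(
            f"both groups need >= 2 arrays (got {case.shape[1]} cases, "
            f"{ctrl.shape[1]} controls)"
        )
    n1, n2 = case.shape[1], ctrl.shape[1]
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full(diff.shape, float(n1 + n2 - 2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # features constant within the analyzed subset (e.g. floored antigens)
    # leave only float dust in the variance; their t is undefined, not huge
    undefined = se <= 1e-10
    t[undefined] = np.nan
    p[undefined] = np.nan
    df[undefined] = np.nan
    table = pd.DataFrame(
        {"diff": diff, "t": t, "df": df, "p": p}, index=matrix.index
    )
    significant = table.index[(table["p"] < alpha).fillna(False)].tolist()
    return ComparisonResult(table=table, alpha=alpha, significant=significant)


def overlap_percent(list_a, list_b) -> float:
    """Relative overlap of two feature sets: 100*|A∩B|/|A∪B|, one decimal.

    Both sets empty is defined as 0.  The union denominator reproduces the
    printed worked example: |A|=340, |B|=392, |A∩B|=318 -> 76.8%.
    """
    a, b = set(list_a), set(list_b)
    union = a | b
    if not union:
        return 0.0
    return round(100.0 * len(a & b) / len(union), 1)


@dataclass
class ConcordanceReport:
    """Single-run vs cross-run overlaps per method/histology, plus counts
    and all pairwise method overlaps per analysis."""

    overlap: pd.DataFrame  # methods x histologies, overlap %
    counts: pd.DataFrame  # significant-antigen counts per analysis
    method_pairwise: dict[str, dict[str, float]]  # analysis -> "m1|m2" -> %
    notes: list[str]


def _analysis_arrays(
    annotation: pd.DataFrame, histology: str, runs: tuple[int, ...]
) -> pd.Series:
    """Case/control labels for one histology's analysis over given runs."""
    ann = annotation[annotation["run"].isin(runs)]
    keep = (ann["histology"] == histology) | (ann["class"] == "control")
    return ann.loc[keep, "class"]


def concordance_table(
    matrix_by_method: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    design: dict[str, tuple[int, tuple[int, ...]]] | None = None,
    alpha: float = ALPHA,
) -> ConcordanceReport:
    """Single-run vs cross-run concordance for every method and histology.

    ``design`` maps histology -> (single run, cross-run tuple); the default
    is the six-run layout (SCLC: 1 vs 1+5, SqLC: 2 vs 2+5, LCLC: 3 vs 3+6,
    AdCa: 4 vs 4+6).
    """
    if design is None:
        design = {h: (CROSS_RUN_PAIRS[h][0], CROSS_RUN_PAIRS[h]) for h in HISTOLOGIES}
    methods = list(matrix_by_method)
    feature_sets = {m: tuple(matrix_by_method[m].index) for m in methods}
    if len(set(feature_sets.values())) > 1:
        raise ValueError("per-method matrices must share the same feature set")
    notes: list[str] = []
    overlap = pd.DataFrame(index=methods, columns=list(design), dtype=float)
    counts = []
    lists: dict[tuple[str, str, str], set] = {}
    for hist, (single_run, cross_runs) in design.items():
        labels_single = _analysis_arrays(annotation, hist, (single_run,))
        labels_cross = _analysis_arrays(annotation, hist, tuple(cross_runs))
        if not (labels_single == "case").any():
            raise ValueError(f"histology {hist!r} absent from run {single_run}")
        for m in methods:
            mat = matrix_by_method[m]
            single = class_comparison(mat[labels_single.index], labels_single, alpha)
            cross = class_comparison(mat[labels_cross.index], labels_cross, alpha)
            if not single.significant and not cross.significant:
                notes.append(f"{m}/{hist}: empty lists in both analyses")
            overlap.loc[m, hist] = overlap_percent(single.significant, cross.significant)
            lists[(m, hist, "single")] = set(single.significant)
            lists[(m, hist, "cross")] = set(cross.significant)
            counts.append(
                {
                    "method": m,
                    "histology": hist,
                    "single_run": len(single.significant),
                    "cross_run": len(cross.significant),
                }
            )
    method_pairwise: dict[str, dict[str, float]] = {}
    for hist in design:
        for kind in ("single", "cross"):
            key = f"{hist}_{kind}"
            method_pairwise[key] = {}
            for i, m1 in enumerate(methods):
                for m2 in methods[i + 1:]:
                    method_pairwise[key][f"{m1}|{m2}"] = overlap_percent(
                        lists[(m1, hist, kind)], lists[(m2, hist, kind)]
                    )
    return ConcordanceReport(
        overlap=overlap,
        counts=pd.DataFrame(counts),
        method_pairwise=method_pairwise,
        notes=notes,
    )


def required_sample_size(
    sigma: float,
    alpha: float = ALPHA,
    power: float = 0.9,
    delta_log2: float = 0.585,
) -> int:
    """Per-class n for a two-sided two-sample comparison (normal approximation).

    n = ceil( 2 * (z_{1-alpha/2} + z_power)^2 * sigma^2 / delta^2 ),
    the calculation behind the study's "25 per histology suffices" argument
    (sigma = 0.414, the 50th percentile of the variance distribution, gives
    n = 21 at delta = log2(1.5) ~ 0.585).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = int(np.ceil(2.0 * z**2 * sigma**2 / delta_log2**2))
    return max(n, 2)
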