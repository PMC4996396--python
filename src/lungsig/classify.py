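"""Class prediction with complete leave-one-out cross-validation.

"Complete" means feature selection happens inside every fold: the held-out
array influences neither the ranked t-scores, the greedy-pairs loop, nor
the RFE eliminations of its own fold.  Model families mirror the era's
class-prediction toolbox: compound covariate predictor (CCP), diagonal
linear discriminant analysis (DLDA), k-nearest neighbours, nearest
centroid, linear support vector machine, and the Bayesian compound
covariate predictor (BCCP).  Prediction ties resolve to 'control'
(deterministic and conservative for a diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

CASE, CONTROL = "case", "control"
MODELS = ("CCP", "DLDA", "NN", "NC", "SVM", "BCCP")


@dataclass
class CvSpec:
    """One cross-validated classifier configuration.

    ``selected_size`` counts pairs for greedy-pairs (n pairs -> 2n features)
    and features for RFE.  ``k`` is the neighbour count for NN (odd, so
    votes cannot tie on binary labels).
    """

    feature_selection: str = "greedy_pairs"  # or "rfe"
    selected_size: int = 25
    model: str = "DLDA"
    k: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.feature_selection not in ("greedy_pairs", "rfe"):
            raise ValueError(f"unknown feature selection {self.feature_selection!r}")
        if self.selected_size < 1:
            raise ValueError("selected_size must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; pick from {MODELS}")
        if self.model == "NN" and self.k % 2 == 0:
            raise ValueError("k must be odd for NN")


@dataclass
class CvPerformance:
    spec: CvSpec
    predictions: pd.Series  # per-array predicted class
    correct_rate: float
    sensitivity: float
    specificity: float
    fold_features: dict[str, list[str]]
    consensus_features: list[str]

    def summary(self) -> dict:
        return {
            "selection": self.spec.feature_selection,
            "size": self.spec.selected_size,
            "model": self.spec.model,
            "cc": self.correct_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _split(matrix: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(matrix.columns)
    case = matrix.loc[:, (labels == CASE).to_numpy()].to_numpy(float)
    ctrl = matrix.loc[:, (labels == CONTROL).to_numpy()].to_numpy(float)
    return case, ctrl


def _pooled_t(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature pooled-variance t statistic and the pooled variance."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    sp2 = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(np.isfinite(t), t, 0.0), sp2


def tscore_rank(matrix: pd.DataFrame, labels: pd.Series) -> list[str]:
    """Features ordered by decreasing |t|; ties break by feature order."""
    case, ctrl = _split(matrix, labels)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each class needs >= 2 arrays to rank by t")
    t, _ = _pooled_t(case, ctrl)
    order = np.lexsort((np.arange(len(t)), -np.abs(t)))
    return [matrix.index[i] for i in order]


def greedy_pairs_select(
    matrix: pd.DataFrame, labels: pd.Series, n_pairs: int
) -> list[str]:
    """Greedy-pairs feature selection.

    Repeat n_pairs times: take the best-ranked remaining gene by |t|, pair
    it with the remaining gene maximizing the two-sample |t| of the
    projection onto the pair's diagonal linear-discriminant direction
    (weights (mean difference)/pooled variance per gene), remove both.
    """
    if n_pairs == 0:
        return []
    if 2 * n_pairs > matrix.shape[0]:
        raise ValueError(
            f"{n_pairs} pairs need {2 * n_pairs} features, matrix has {matrix.shape[0]}"
        )
    case, ctrl = _split(matrix, labels)
    t, sp2 = _pooled_t(case, ctrl)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    w = diff / np.maximum(sp2, 1e-12)
    n1, n2 = case.shape[1], ctrl.shape[1]
    remaining = list(range(matrix.shape[0]))
    chosen: list[int] = []
    abs_t = np.abs(t)
    for _ in range(n_pairs):
        rem = np.array(remaining)
        g1 = rem[np.lexsort((rem, -abs_t[rem]))[0]]
        others = rem[rem != g1]
        # projections of every candidate pair (g1, h) at once
        zc = w[g1] * case[g1][None, :] + w[others][:, None] * case[others]
        zk = w[g1] * ctrl[g1][None, :] + w[others][:, None] * ctrl[others]
        dz = zc.mean(axis=1) - zk.mean(axis=1)
        s2 = ((n1 - 1) * zc.var(axis=1, ddof=1) + (n2 - 1) * zk.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tz = np.abs(dz) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        tz = np.where(np.isfinite(tz), tz, 0.0)
        g2 = others[np.lexsort((others, -tz))[0]]
        chosen += [g1, int(g2)]
        remaining = [i for i in remaining if i not in (g1, g2)]
    return [matrix.index[i] for i in chosen]


def svm_rfe_select(
    matrix: pd.DataFrame, labels: pd.Series, target_size: int = 100
) -> list[str]:
    """Recursive feature elimination with a linear soft-margin SVM.

    Train, drop the half of features with smallest |weight| (never crossing
    ``target_size``), repeat; the final round trims exactly to size.
    Returns the surviving features in matrix order.
    """
    if target_size > matrix.shape[0]:
        raise ValueError("target_size exceeds the feature count")
    labels = labels.reindex(matrix.columns)
    classes = set(labels.unique())
    if classes != {CASE, CONTROL}:
        raise ValueError(f"labels must be binary case/control, got {sorted(classes)}")
    y = (labels == CASE).to_numpy(int)
    current = np.arange(matrix.shape[0])
    x = matrix.to_numpy(float).T
    while current.size > target_size:
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(x[:, current], y)
        weights = np.abs(np.asarray(clf.coef_).ravel())
        n_drop = min(current.size // 2, current.size - target_size)
        order = np.lexsort((np.arange(current.size), weights))
        keep_local = np.setdiff1d(np.arange(current.size), order[:n_drop])
        current = current[keep_local]
    return [matrix.index[i] for i in sorted(current)]


def _ccp_scores(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return t @ x


def fit_predict(
    train: pd.DataFrame,
    labels: pd.Series,
    test: pd.Series | np.ndarray,
    model: str,
    k: int = 3,
) -> tuple[str, float]:
    """Train one classifier and predict a single held-out array.

    Returns (predicted class, score); the score is the model's natural
    discriminant value (CCP/BCCP compound score or posterior, DLDA/NC
    discriminant difference, NN vote fraction, SVM decision value).
    """
    labels = labels.reindex(train.columns)
    case, ctrl = _split(train, labels)
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ValueError("training set must contain both classes")
    xt = np.asarray(test, dtype=float)
    if model in ("CCP", "BCCP"):
        t, _ = _pooled_t(case, ctrl)
        c_case = _ccp_scores(case, t)
        c_ctrl = _ccp_scores(ctrl, t)
        c = float(t @ xt)
        if model == "CCP":
            threshold = (c_case.mean() + c_ctrl.mean()) / 2.0
            if c_case.mean() > c_ctrl.mean():
                return (CASE, c) if c > threshold else (CONTROL, c)
            return (CASE, c) if c < threshold else (CONTROL, c)
        # BCCP: two-Gaussian model on the compound score, priors = class freq
        n1, n2 = c_case.size, c_ctrl.size
        var = (
            (n1 - 1) * c_case.var(ddof=1) + (n2 - 1) * c_ctrl.var(ddof=1)
        ) / (n1 + n2 - 2)
        var = max(var, 1e-300)
        log_like_case = -0.5 * (c - c_case.mean()) ** 2 / var + np.log(n1 / (n1 + n2))
        log_like_ctrl = -0.5 * (c - c_ctrl.mean()) ** 2 / var + np.log(n2 / (n1 + n2))
        post = 1.0 / (1.0 + np.exp(log_like_ctrl - log_like_case))
        return (CASE, float(post)) if post > 0.5 else (CONTROL, float(post))
    if model == "DLDA":
        n1, n2 = case.shape[1], ctrl.shape[1]
        s2 = (
            (n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)
        ) / (n1 + n2 - 2)
        s2 = np.maximum(s2, 1e-12)
        d_case = (((xt - case.mean(axis=1)) ** 2) / s2).sum()
        d_ctrl = (((xt - ctrl.mean(axis=1)) ** 2) / s2).sum()
        return (CASE, d_ctrl - d_case) if d_case < d_ctrl else (CONTROL, d_ctrl - d_case)
    if model == "NC":
        d_case = np.linalg.norm(xt - case.mean(axis=1))
        d_ctrl = np.linalg.norm(xt - ctrl.mean(axis=1))
        return (CASE, d_ctrl - d_case) if d_case < d_ctrl else (CONTROL, d_ctrl - d_case)
    if model == "NN":
        x = train.to_numpy(float).T
        if k >= x.shape[0]:
            raise ValueError(f"k={k} must be smaller than the training size {x.shape[0]}")
        dist = np.linalg.norm(x - xt[None, :], axis=1)
        order = np.lexsort((np.arange(dist.size), dist))[:k]
        votes = (labels.to_numpy() == CASE)[order].mean()
        return (CASE, float(votes)) if votes > 0.5 else (CONTROL, float(votes))
    if model == "SVM":
        y = (labels.to_numpy() == CASE).astype(int)
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(train.to_numpy(float).T, y)
        value = float(clf.decision_function(xt[None, :])[0])
        return (CASE, value) if value > 0 else (CONTROL, value)
    raise ValueError(f"unknown model {model!r}")


def _select(matrix: pd.DataFrame, labels: pd.Series, spec: CvSpec) -> list[str]:
    if spec.feature_selection == "greedy_pairs":
        return greedy_pairs_select(matrix, labels, spec.selected_size)
    return svm_rfe_select(matrix, labels, spec.selected_size)


def loocv_class_prediction(
    matrix: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    spec: CvSpec,
) -> CvPerformance:
    """Complete LOOCV: per fold, re-select features and re-fit on the rest.

    ``labels`` may be the annotation table (its 'class' column is used) or a
    case/control Series.  Also fits the consensus panel on all arrays for
    reporting (never used for the performance estimate).
    """
    spec.validate()
    if isinstance(labels, pd.DataFrame):
        labels = labels["class"]
    labels = labels.reindex(matrix.columns)
    n_case = int((labels == CASE).sum())
    n_ctrl = int((labels == CONTROL).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need >= 2 arrays per class for LOOCV")
    predictions = {}
    fold_features = {}
    for array_id in matrix.columns:
        train = matrix.drop(columns=[array_id])
        train_labels = labels.drop(index=array_id)
        if train_labels.nunique() < 2:
            raise ValueError(f"fold {array_id!r} leaves a single-class training set")
        features = _select(train, train_labels, spec)
        pred, _ = fit_predict(
            train.loc[features], train_labels, matrix.loc[features, array_id],
            spec.model, k=spec.k,
        )
        predictions[array_id] = pred
        fold_features[array_id] = features
    predictions = pd.Series(predictions).reindex(matrix.columns)
    correct = predictions == labels
    sens = float(correct[(labels == CASE).to_numpy()].mean())
    specf = float(correct[(labels == CONTROL).to_numpy()].mean())
    return CvPerformance(
        spec=spec,
        predictions=predictions,
        correct_rate=float(correct.mean()),
        sensitivity=sens,
        specificity=specf,
        fold_features=fold_features,
        consensus_features=_select(matrix, labels, spec),
    )


def classifier_overlap_venn(panels: dict[str, list[str]]) -> dict[str, int]:
    """Exclusive region counts of the n-set Venn diagram over feature panels.

    Keys are '&'-joined sorted panel names; a 4-panel input yields all 15
    non-empty-membership regions (some possibly 0).
    """
    names = sorted(panels)
    sets = {n: set(panels[n]) for n in names}
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            outside = [n for n in names if n not in inside]
            members = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                members -= sets[n]
            regions["&".join(inside)] = len(members)
    return regions
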