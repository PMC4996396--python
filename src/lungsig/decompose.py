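"""PCA score plots and principal variance components analysis (PVCA).

PVCA attributes total data variance to known experimental factors: retain
the leading principal components up to a cumulative-variance threshold
(default 60%), fit each retained PC score vector with a random-effects
model holding one variance component per factor and per pairwise factor
interaction, convert each PC's components to proportions, and average the
proportions weighted by the PCs' eigenvalue shares.

The per-PC variance components are estimated by REML.  The covariance of a
score vector y under the model y = 1*mu + sum_k u_k + e (u_k grouped by
factor k) is V = sum_k s2_k K_k + s2_e I, where K_k is the block kernel
Z_k Z_k' (ones for array pairs sharing factor level, and the elementwise
product of the parents' kernels for an interaction).  The restricted
log-likelihood is maximized by L-BFGS over log-variances with analytic
gradients; a non-negative least squares fit of the empirical covariance on
the kernels (a method-of-moments estimator) supplies starting values and
the fallback on optimizer failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

DEFAULT_FACTORS = ("run", "type", "sex", "age", "smoking")

#: Annotation columns behind the canonical factor names.
FACTOR_COLUMNS = {
    "run": "run",
    "type": "class",
    "sex": "sex",
    "age": "age_group",
    "smoking": "smoking",
}


@dataclass
class PcaResult:
    scores: pd.DataFrame  # arrays x components
    eigenvalues: np.ndarray
    proportions: np.ndarray
    warnings: list[str] = field(default_factory=list)


@dataclass
class PvcaResult:
    proportions: dict[str, float]  # factor/interaction/resid -> weighted proportion
    n_components: int
    threshold: float
    estimator: dict[str, str] = field(default_factory=dict)  # per-PC fit route

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": list(self.proportions), "proportion": list(self.proportions.values())}
        )


def pca_scores(matrix: pd.DataFrame, n_components: int = 10) -> PcaResult:
    """Feature-centered PCA; arrays are the observations (one score row each)."""
    x = matrix.to_numpy(float).T  # arrays x features
    x = x - x.mean(axis=0, keepdims=True)
    n_arrays = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n_arrays - 1)
    total = eigenvalues.sum()
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    notes = []
    k = min(n_components, rank)
    if k < n_components:
        notes.append(
            f"requested {n_components} components but rank is {rank}; returning {k}"
        )
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eigenvalues[:k],
        proportions=eigenvalues[:k] / total if total > 0 else eigenvalues[:k],
        warnings=notes,
    )


def _factor_kernels(
    annotation: pd.DataFrame, factors: tuple[str, ...]
) -> tuple[list[str], list[np.ndarray]]:
    """Block kernels for each factor and each pairwise interaction."""
    cols = {}
    for f in factors:
        column = FACTOR_COLUMNS.get(f, f)
        if column not in annotation.columns:
            raise KeyError(f"factor {f!r}: column {column!r} not in annotation")
        cols[f] = annotation[column].astype(str).to_numpy()
    # confounded single factors (identical groupings) are inestimable:
    # partitions coincide iff the observed (a, b) level pairs are a bijection
    for a, b in combinations(factors, 2):
        na = len(np.unique(cols[a]))
        nb = len(np.unique(cols[b]))
        pairs = len(set(zip(cols[a], cols[b])))
        if na == nb == pairs and na > 1:
            raise ValueError(f"factors {a!r} and {b!r} are confounded")
    names, kernels = [], []
    base = {}
    for f in factors:
        k = (cols[f][:, None] == cols[f][None, :]).astype(float)
        base[f] = k
        names.append(f)
        kernels.append(k)
    for a, b in combinations(factors, 2):
        names.append(f"{a}:{b}")
        kernels.append(base[a] * base[b])
    return names, kernels


def _nnls_components(y: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments: NNLS fit of the centered outer product on the kernels."""
    n = y.size
    yc = y - y.mean()
    target = np.outer(yc, yc)
    iu = np.triu_indices(n)
    design = np.column_stack(
        [k[iu] for k in kernels] + [np.eye(n)[iu]]
    )
    coef, _ = nnls(design, target[iu])
    return coef


def _reml_components(
    y: np.ndarray, kernels: list[np.ndarray]
) -> tuple[np.ndarray, bool]:
    """REML variance components; returns (variances incl. residual, converged)."""
    n = y.size
    scale = y.var(ddof=1)
    if scale <= 0:
        return np.concatenate([np.zeros(len(kernels)), [1.0]]), True
    ys = y / np.sqrt(scale)
    ks = kernels + [np.eye(n)]
    m = len(ks)
    X = np.ones((n, 1))

    def neg_reml_and_grad(log_s2):
        s2 = np.exp(np.clip(log_s2, -40.0, 40.0))
        V = np.zeros((n, n))
        for s, K in zip(s2, ks):
            V += s * K
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(m)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        Vi = np.linalg.inv(V)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        P = Vi - ViX @ np.linalg.solve(XtViX, ViX.T)
        Py = P @ ys
        nll = 0.5 * (logdet + np.log(XtViX[0, 0]) + ys @ Py)
        grad = np.array(
            [0.5 * s2[k] * ((P * ks[k]).sum() - Py @ ks[k] @ Py) for k in range(m)]
        )
        return nll, grad

    start = _nnls_components(ys, kernels)
    x0 = np.log(np.maximum(start, 1e-4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            neg_reml_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-30.0, 10.0)] * m,
            options={"maxiter": 500},
        )
    s2 = np.exp(res.x) * scale
    return s2, bool(res.success)


def pvca(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    var_threshold: float = 0.60,
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> PvcaResult:
    """Weighted variance-component attribution over the leading PCs.

    Steps: (1) keep the first k PCs whose cumulative variance reaches
    ``var_threshold``; (2) fit each PC's scores with the random-effects model
    over ``factors`` and their pairwise interactions; (3) per PC, normalize
    components to proportions; (4) average, weighting by eigenvalue share;
    (5) renormalize so the reported proportions (including 'resid') sum to 1.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    annotation = annotation.loc[matrix.columns]
    n_arrays = matrix.shape[1]
    full = pca_scores(matrix, n_components=min(n_arrays - 1, matrix.shape[0]))
    cum = np.cumsum(full.proportions)
    k = int(np.searchsorted(cum, var_threshold) + 1)
    k = min(k, full.scores.shape[1])
    names, kernels = _factor_kernels(annotation, factors)
    labels = names + ["resid"]
    weights = full.eigenvalues[:k] / full.eigenvalues[:k].sum()
    avg = np.zeros(len(labels))
    routes: dict[str, str] = {}
    for i in range(k):
        y = full.scores.iloc[:, i].to_numpy(float)
        s2, ok = _reml_components(y, kernels)
        if not ok:
            s2 = _nnls_components(y, kernels)
            routes[f"PC{i+1}"] = "moments"
        else:
            routes[f"PC{i+1}"] = "reml"
        props = s2 / s2.sum() if s2.sum() > 0 else np.eye(len(labels))[-1]
        avg += weights[i] * props
    avg = avg / avg.sum()
    return PvcaResult(
        proportions=dict(zip(labels, avg)),
        n_components=k,
        threshold=var_threshold,
        estimator=routes,
    )
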