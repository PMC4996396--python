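"""Distance-weighted discrimination (DWD) batch merging.

DWD finds the direction w (||w|| <= 1) and intercept beta minimizing the sum
of inverse margins sum_i 1/r_i + C sum_i xi_i with r_i = y_i(x_i'w + beta)
+ xi_i > 0, xi_i >= 0, labelling the two batches y = +/-1.  Optimizing the
slack variables out analytically turns the cone program into smooth convex
loss minimization with

    V(u) = 1/u                     if u >= 1/sqrt(C)
    V(u) = 2*sqrt(C) - C*u         otherwise,

minimized over the span of the data (any component of w orthogonal to all
arrays wastes norm budget without changing any margin), which reduces the
problem to at most n_arrays + 1 variables regardless of feature count.
Batches are then merged by translating each batch along w so that its mean
projection lands on the pooled mean projection; within-batch geometry is
untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orth
from scipy.optimize import NonlinearConstraint, minimize
from scipy.spatial.distance import pdist


@dataclass
class DwdDirection:
    """Unit separating direction between two batches plus bookkeeping."""

    w: np.ndarray  # unit direction over features
    beta: float
    C: float
    mean_projection_a: float
    mean_projection_b: float
    solver_status: str


def default_penalty(x: np.ndarray) -> float:
    """Scale-aware default penalty: 100 / median^2 of pairwise distances."""
    d = pdist(x)
    med = np.median(d[d > 0]) if (d > 0).any() else 1.0
    return 100.0 / med**2


def _dwd_loss_grad(u: np.ndarray, C: float) -> tuple[float, np.ndarray]:
    thresh = 1.0 / np.sqrt(C)
    big = u >= thresh
    loss = np.where(big, 1.0 / np.where(big, u, 1.0), 2.0 * np.sqrt(C) - C * u)
    grad = np.where(big, -1.0 / np.where(big, u, 1.0) ** 2, -C)
    return loss.sum(), grad


def dwd_direction(
    batch_a: pd.DataFrame,
    batch_b: pd.DataFrame,
    C: float | None = None,
) -> DwdDirection:
    """Solve DWD between two batches given as features x arrays frames."""
    if batch_a.shape[1] < 2 or batch_b.shape[1] < 2:
        raise ValueError("each batch needs at least 2 arrays")
    xa = batch_a.to_numpy(float).T
    xb = batch_b.to_numpy(float).T
    x = np.vstack([xa, xb])
    y = np.concatenate([np.ones(len(xa)), -np.ones(len(xb))])
    if C is None:
        C = default_penalty(x)

    # orthonormal basis of the span of the arrays (+ mean offset direction)
    basis = orth(x.T)  # features x r
    s = x @ basis  # arrays x r
    r = s.shape[1]

    def objective(params):
        v, beta = params[:r], params[r]
        margins = y * (s @ v + beta)
        loss, grad_u = _dwd_loss_grad(margins, C)
        grad_v = s.T @ (grad_u * y)
        grad_beta = float(grad_u @ y)
        return loss, np.concatenate([grad_v, [grad_beta]])

    def norm_constraint(params):
        v = params[:r]
        return 1.0 - v @ v

    def norm_jac(params):
        jac = np.zeros_like(params)
        jac[:r] = -2.0 * params[:r]
        return jac

    v0 = s[y > 0].mean(axis=0) - s[y < 0].mean(axis=0)
    nv0 = np.linalg.norm(v0)
    v0 = v0 / nv0 if nv0 > 0 else np.ones(r) / np.sqrt(r)
    beta0 = -float(s @ v0 @ np.ones(len(y)) / len(y))
    x0 = np.concatenate([0.9 * v0, [beta0]])
    with warnings.catch_warnings():
        # quasi-Newton updates warn when the loss is locally linear (flat V')
        warnings.simplefilter("ignore", UserWarning)
        res = minimize(
            objective,
            x0,
            jac=True,
            method="trust-constr",
            constraints=[
                NonlinearConstraint(
                    norm_constraint, 0.0, np.inf, jac=lambda p: norm_jac(p)[None, :]
                )
            ],
            options={"maxiter": 2000, "gtol": 1e-10, "xtol": 1e-12},
        )
    if res.status not in (1, 2):  # gtol / xtol termination
        raise RuntimeError(f"DWD solver failed: {res.message}")
    v = res.x[:r]
    nv = np.linalg.norm(v)
    if nv == 0:
        raise RuntimeError("DWD solver returned a zero direction")
    w = basis @ (v / nv)
    proj_a = float((xa @ w).mean())
    proj_b = float((xb @ w).mean())
    return DwdDirection(
        w=w,
        beta=float(res.x[r] / nv),
        C=C,
        mean_projection_a=proj_a,
        mean_projection_b=proj_b,
        solver_status=res.message,
    )


def dwd_merge_pair(
    matrix: pd.DataFrame,
    arrays_a: list,
    arrays_b: list,
    direction: DwdDirection,
) -> pd.DataFrame:
    """Translate both batches along w onto the pooled mean projection."""
    if direction.w.shape[0] != matrix.shape[0]:
        raise ValueError("direction dimension does not match the matrix")
    out = matrix.copy()
    w = direction.w
    xa = matrix[arrays_a].to_numpy(float)
    xb = matrix[arrays_b].to_numpy(float)
    pa = (xa.T @ w).mean()
    pb = (xb.T @ w).mean()
    pooled = (pa * len(arrays_a) + pb * len(arrays_b)) / (
        len(arrays_a) + len(arrays_b)
    )
    out[arrays_a] = xa + np.outer(w, np.full(len(arrays_a), pooled - pa))
    out[arrays_b] = xb + np.outer(w, np.full(len(arrays_b), pooled - pb))
    return out


#: Default stepwise plan: merge within each processing session first
#: (runs 1-3, then runs 4-6), and join the two sessions last.
DEFAULT_MERGE_PLAN = (((1, 2), 3), ((4, 5), 6))


def _plan_runs(plan) -> list:
    if isinstance(plan, (int, np.integer)):
        return [int(plan)]
    left, right = plan
    return _plan_runs(left) + _plan_runs(right)


def dwd_stepwise_merge(
    matrix: pd.DataFrame,
    runs: pd.Series,
    merge_plan=DEFAULT_MERGE_PLAN,
    C: float | None = None,
) -> pd.DataFrame:
    """Apply DWD pairwise along a binary merge tree over runs.

    ``merge_plan`` is a nested 2-tuple over run labels; previously merged
    sets are treated as a single batch in later steps.  The plan must cover
    every run present in ``runs``.
    """
    runs = runs.reindex(matrix.columns)
    plan_runs = set(_plan_runs(merge_plan))
    present = set(int(r) for r in runs.unique())
    if plan_runs != present:
        raise ValueError(
            f"merge plan covers runs {sorted(plan_runs)} but data has {sorted(present)}"
        )
    if len(present) == 1:
        return matrix.copy()

    arrays_of = {
        run: [c for c in matrix.columns if int(runs[c]) == run] for run in present
    }

    def merge(node, mat: pd.DataFrame) -> tuple[list, pd.DataFrame]:
        if isinstance(node, (int, np.integer)):
            return arrays_of[int(node)], mat
        left, right = node
        cols_a, mat = merge(left, mat)
        cols_b, mat = merge(right, mat)
        direction = dwd_direction(mat[cols_a], mat[cols_b], C=C)
        mat = dwd_merge_pair(mat, cols_a, cols_b, direction)
        return cols_a + cols_b, mat

    _, merged = merge(merge_plan, matrix)
    return merged
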