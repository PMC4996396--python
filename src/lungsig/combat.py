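"""Parametric empirical-Bayes batch adjustment (ComBat).

Location/scale model on log2 intensities: for feature g, array j in batch i,

    Y_gj = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_gj,

with eps ~ N(0, sigma_g^2).  Per-batch location estimates gamma_hat are
shrunk toward a batch-level normal prior N(gamma_bar_i, tau2_bar_i) and the
scale estimates delta2_hat toward an inverse-gamma prior (lambda_i,
theta_i), both priors fitted by method of moments across features.  The
posterior (EB) estimates solve a coupled fixed point iterated to
convergence; the adjusted data are

    Y*_gj = sigma_g / delta*_ig * (Z_gj - gamma*_ig) + alpha_g + X_j beta_g.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ComBatModel:
    """Fitted ComBat parameters, per feature and per batch."""

    feature_ids: list[str]
    batch_levels: list
    alpha: np.ndarray  # grand mean per feature
    sigma2: np.ndarray  # pooled residual variance per feature
    beta: np.ndarray | None  # covariate coefficients (n_cov x features)
    covariate_columns: list[str] | None
    gamma_hat: np.ndarray  # raw batch locations (batch x feature)
    delta2_hat: np.ndarray  # raw batch scales (batch x feature)
    gamma_star: np.ndarray  # EB-shrunken locations
    delta2_star: np.ndarray  # EB-shrunken scales
    gamma_bar: np.ndarray  # normal prior mean per batch
    tau2_bar: np.ndarray  # normal prior variance per batch
    lambda_: np.ndarray  # inverse-gamma prior shape per batch
    theta: np.ndarray  # inverse-gamma prior scale per batch

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "batch_levels": [str(b) for b in self.batch_levels],
            "covariate_columns": self.covariate_columns,
        }
        for name in (
            "alpha", "sigma2", "gamma_hat", "delta2_hat", "gamma_star",
            "delta2_star", "gamma_bar", "tau2_bar", "lambda_", "theta",
        ):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        payload["beta"] = None if self.beta is None else self.beta.tolist()
        Path(path).write_text(json.dumps(payload))


def _inverse_gamma_moments(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma prior (shape, scale) for batch scales."""
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1)
    shape = (2.0 * s2 + m**2) / s2
    scale = (m * s2 + m**3) / s2
    return shape, scale


def _eb_fixed_point(
    z_batch: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    gamma_bar: float,
    tau2_bar: float,
    lam: float,
    theta: float,
    conv: float = 1e-8,
    max_iter: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled EB posterior equations for one batch.

    z_batch: standardized data restricted to the batch (features x arrays).
    """
    n = z_batch.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2_bar * gamma_hat + d_old * gamma_bar) / (
            n * tau2_bar + d_old
        )
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (theta + 0.5 * sum2) / (n / 2.0 + lam - 1.0)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-30)).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _design_matrix(
    batches: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list, np.ndarray | None]:
    levels = list(pd.unique(batches))
    batch_design = np.column_stack(
        [(batches == lv).to_numpy(float) for lv in levels]
    )
    cov = None
    if covariates is not None and covariates.shape[1] > 0:
        cov = pd.get_dummies(covariates, drop_first=True).to_numpy(float)
    return batch_design, levels, cov


def combat_fit(
    matrix: pd.DataFrame,
    batches: pd.Series,
    covariates: pd.DataFrame | None = None,
    conv: float = 1e-8,
) -> ComBatModel:
    """Fit the parametric EB batch model.

    Parameters
    ----------
    matrix : complete features x arrays log2 matrix.
    batches : per-array batch labels, indexed like the matrix columns.
    covariates : optional per-array covariates to protect (e.g. the class
        label); dummy-coded internally.  The default (None) is the plain
        batch-only model.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute before ComBat")
    batches = batches.reindex(matrix.columns)
    if batches.isna().any():
        raise ValueError("every array needs a batch label")
    if covariates is not None:
        covariates = covariates.reindex(matrix.columns)
    batch_design, levels, cov = _design_matrix(batches, covariates)
    if len(levels) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    n_per_batch = batch_design.sum(axis=0)
    if (n_per_batch < 2).any():
        lone = levels[int(np.argmin(n_per_batch))]
        raise ValueError(f"batch {lone!r} has fewer than 2 arrays")

    y = matrix.to_numpy(float)
    n_features, n_arrays = y.shape
    design = batch_design if cov is None else np.hstack([batch_design, cov])
    # per-feature OLS of Y on [batch dummies, covariates]
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    batch_coef = coef[: len(levels)]
    alpha = (n_per_batch / n_arrays) @ batch_coef
    beta = None if cov is None else coef[len(levels):]
    fitted = design @ coef
    resid = y.T - fitted
    sigma2 = (resid**2).mean(axis=0)
    # exact-constant features leave only float dust in the residuals
    sigma2 = np.where(sigma2 <= 1e-20, 0.0, sigma2)
    if (sigma2 <= 0).any():
        bad = matrix.index[int(np.argmin(sigma2))]
        raise ValueError(f"feature {bad!r} has zero residual variance")

    stand_mean = alpha[None, :] + (cov @ beta if cov is not None else 0.0)
    z = (y.T - stand_mean) / np.sqrt(sigma2)[None, :]
    z = z.T  # features x arrays

    gamma_hat = np.empty((len(levels), n_features))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    gamma_bar = np.empty(len(levels))
    tau2_bar = np.empty(len(levels))
    lambda_ = np.empty(len(levels))
    theta = np.empty(len(levels))
    for i, lv in enumerate(levels):
        in_batch = batch_design[:, i] == 1
        zb = z[:, in_batch]
        gamma_hat[i] = zb.mean(axis=1)
        delta2_hat[i] = zb.var(axis=1, ddof=1)
        gamma_bar[i] = gamma_hat[i].mean()
        tau2_bar[i] = gamma_hat[i].var(ddof=1)
        lambda_[i], theta[i] = _inverse_gamma_moments(delta2_hat[i])
        gamma_star[i], delta2_star[i] = _eb_fixed_point(
            zb, gamma_hat[i], delta2_hat[i],
            gamma_bar[i], tau2_bar[i], lambda_[i], theta[i], conv=conv,
        )
    return ComBatModel(
        feature_ids=list(matrix.index),
        batch_levels=levels,
        alpha=alpha,
        sigma2=sigma2,
        beta=beta,
        covariate_columns=(
            None if covariates is None else list(pd.get_dummies(covariates, drop_first=True).columns)
        ),
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2_bar=tau2_bar,
        lambda_=lambda_,
        theta=theta,
    )


def combat_transform(
    matrix: pd.DataFrame,
    model: ComBatModel,
    batches: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply a fitted ComBat model: remove EB batch locations and scales."""
    if list(matrix.index) != model.feature_ids:
        raise ValueError("feature set differs from the fitted model")
    batches = batches.reindex(matrix.columns)
    y = matrix.to_numpy(float)
    cov = None
    if model.beta is not None:
        if covariates is None:
            raise ValueError("model was fitted with covariates; pass them")
        cov = pd.get_dummies(covariates.reindex(matrix.columns), drop_first=True).to_numpy(float)
    stand_mean = model.alpha[None, :] + (cov @ model.beta if cov is not None else 0.0)
    z = (y.T - stand_mean) / np.sqrt(model.sigma2)[None, :]
    z = z.T
    out = np.empty_like(z)
    sigma = np.sqrt(model.sigma2)
    for i, lv in enumerate(model.batch_levels):
        in_batch = (batches == lv).to_numpy()
        if not in_batch.any():
            continue
        adj = (z[:, in_batch] - model.gamma_star[i][:, None]) / np.sqrt(
            model.delta2_star[i]
        )[:, None]
        out[:, in_batch] = adj * sigma[:, None] + (
            stand_mean[in_batch].T if cov is not None else model.alpha[:, None]
        )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def combat_adjust(
    matrix: pd.DataFrame,
    batches: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convenience fit-and-transform on the same data."""
    model = combat_fit(matrix, batches, covariates)
    return combat_transform(matrix, model, batches, covariates)
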