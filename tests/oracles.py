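"""Independent brute-force oracles used by the equivalence tests.

Each oracle is a direct, unoptimized transcription of the operation's
definition (exhaustive enumeration, closed forms, step-by-step loops) and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def quantile_normalize_oracle(values: np.ndarray) -> np.ndarray:
    """Rank / row-mean construction executed by hand, one column at a time."""
    n, m = values.shape
    ref = np.zeros(n)
    for j in range(m):
        ref += np.sort(values[:, j])
    ref /= m
    out = np.empty_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        for rank, i in enumerate(order):
            span = [r for r in range(n) if col[order[r]] == col[i]]
            out[i, j] = np.mean([ref[r] for r in span])
    return out


def knn_impute_oracle(values: np.ndarray, k: int) -> np.ndarray:
    """Enumerate all feature distances per missing cell; average the k nearest."""
    out = values.copy()
    n, m = values.shape
    for g in range(n):
        for j in range(m):
            if not np.isnan(values[g, j]):
                continue
            dists = []
            for h in range(n):
                if h == g or np.isnan(values[h, j]):
                    continue
                co = [
                    a
                    for a in range(m)
                    if not np.isnan(values[g, a]) and not np.isnan(values[h, a])
                ]
                if not co:
                    continue
                d = np.mean([(values[g, a] - values[h, a]) ** 2 for a in co])
                dists.append((d, h))
            dists.sort()
            nearest = [h for _, h in dists[: min(k, len(dists))]]
            out[g, j] = np.mean([values[h, j] for h in nearest])
    return out


def combat_eb_oracle(y: np.ndarray, batch: np.ndarray, conv: float = 1e-12):
    """Step-by-step transcription of the parametric EB batch model.

    y: features x arrays, batch: per-array labels.  Returns a dict with the
    standardized data, raw and shrunken batch effects, and the adjusted data.
    """
    levels = list(dict.fromkeys(batch))
    n_features, n_arrays = y.shape
    n_i = {b: int((batch == b).sum()) for b in levels}
    # per-feature grand mean (size-weighted batch means) and pooled variance
    alpha = np.zeros(n_features)
    for b in levels:
        alpha += n_i[b] / n_arrays * y[:, batch == b].mean(axis=1)
    resid = np.empty_like(y, dtype=float)
    for b in levels:
        cols = batch == b
        resid[:, cols] = y[:, cols] - y[:, cols].mean(axis=1, keepdims=True)
    sigma2 = (resid**2).sum(axis=1) / n_arrays
    z = (y - alpha[:, None]) / np.sqrt(sigma2)[:, None]

    gamma_star, delta2_star, adjusted = {}, {}, np.empty_like(y, dtype=float)
    for b in levels:
        cols = batch == b
        zb = z[:, cols]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        g, d = g_hat.copy(), d_hat.copy()
        for _ in range(100000):
            g_new = (n_i[b] * t2 * g_hat + d * g_bar) / (n_i[b] * t2 + d)
            d_new = (theta + 0.5 * ((zb - g_new[:, None]) ** 2).sum(axis=1)) / (
                n_i[b] / 2 + lam - 1
            )
            done = max(
                np.max(np.abs(g_new - g) / np.maximum(np.abs(g), 1e-30)),
                np.max(np.abs(d_new - d) / np.maximum(np.abs(d), 1e-30)),
            ) < conv
            g, d = g_new, d_new
            if done:
                break
        gamma_star[b], delta2_star[b] = g, d
        adjusted[:, cols] = (zb - g[:, None]) / np.sqrt(d)[:, None] * np.sqrt(sigma2)[
            :, None
        ] + alpha[:, None]
    return {
        "alpha": alpha,
        "sigma2": sigma2,
        "gamma_star": gamma_star,
        "delta2_star": delta2_star,
        "adjusted": adjusted,
    }


def pooled_t_oracle(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (
        n1 + n2 - 2
    )
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def greedy_pairs_oracle(values: np.ndarray, labels: np.ndarray, n_pairs: int):
    """Greedy loop with exhaustive candidate scan, scalar arithmetic only."""
    case = values[:, labels == 1]
    ctrl = values[:, labels == 0]
    n = values.shape[0]
    tt = np.array([pooled_t_oracle(case[g], ctrl[g]) for g in range(n)])
    n1, n2 = case.shape[1], ctrl.shape[1]
    w = (case.mean(axis=1) - ctrl.mean(axis=1)) / np.maximum(
        ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1))
        / (n1 + n2 - 2),
        1e-12,
    )
    remaining = list(range(n))
    chosen = []
    for _ in range(n_pairs):
        g1 = max(remaining, key=lambda g: (abs(tt[g]), -g))
        best, best_score = None, -1.0
        for h in remaining:
            if h == g1:
                continue
            zc = w[g1] * case[g1] + w[h] * case[h]
            zk = w[g1] * ctrl[g1] + w[h] * ctrl[h]
            score = abs(pooled_t_oracle(zc, zk))
            if score > best_score + 1e-12:
                best, best_score = h, score
        chosen += [g1, best]
        remaining = [g for g in remaining if g not in (g1, best)]
    return chosen


def venn_oracle(panels: dict[str, set]) -> dict[str, int]:
    """Exhaustive membership enumeration over the union of all panels."""
    names = sorted(panels)
    universe = set().union(*panels.values())
    counts = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            n = 0
            for item in universe:
                member = {nm for nm in names if item in panels[nm]}
                if member == set(inside):
                    n += 1
            counts["&".join(inside)] = n
    return counts


def noncentral_t_power(n_per_group: int, delta: float, sigma: float, alpha: float) -> float:
    """Closed-form power of the two-sided pooled two-sample t-test."""
    df = 2 * n_per_group - 2
    ncp = delta / (sigma * np.sqrt(2.0 / n_per_group))
    crit = stats.t.ppf(1 - alpha / 2, df)
    # the wrong-sided tail underflows to nan for large ncp; it is negligible
    lower = stats.nct.cdf(-crit, df, ncp)
    return stats.nct.sf(crit, df, ncp) + (0.0 if np.isnan(lower) else lower)
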