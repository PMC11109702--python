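"""Two-way cluster-robust variances for proportions and Wald contrasts.

Panel observations are correlated both within unique household IDs and
within unique individual IDs (people change households, so the two
clusterings cross-cut).  Sandwich variances combine the two one-way
clustered meats and subtract the household-by-individual intersection
(Cameron-Gelbach-Miller): V = V_hh + V_ind - V_hh_x_ind.  With singleton
clusters on both dimensions this collapses to the plain
heteroskedasticity-robust (HC0) variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

Z95 = float(stats.norm.ppf(0.975))


def _meat(X: np.ndarray, resid: np.ndarray, ids) -> np.ndarray:
    """Sum over clusters of the outer product of within-cluster score sums."""
    scores = X * resid[:, None]
    g = pd.DataFrame(scores).groupby(pd.Series(np.asarray(ids, dtype=object))).sum()
    G = g.to_numpy()
    return G.T @ G


def twoway_sandwich(X: np.ndarray, resid: np.ndarray, hh, ind) -> np.ndarray:
    """CGM two-way cluster-robust covariance of OLS coefficients."""
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    hh = np.asarray(hh, dtype=object)
    ind = np.asarray(ind, dtype=object)
    bread = np.linalg.inv(X.T @ X)
    inter = np.array([f"{a}\x1f{b}" for a, b in zip(hh, ind)], dtype=object)
    meat = _meat(X, resid, hh) + _meat(X, resid, ind) - _meat(X, resid, inter)
    V = bread @ meat @ bread
    # the CGM combination is not guaranteed PSD in small samples; clamp the
    # diagonal at the intersection-clustered floor of zero
    d = np.diag(V).copy()
    d[d < 0] = 0.0
    np.fill_diagonal(V, d)
    return V


def clustered_proportion_ci(y, hh, ind, level: float = 0.95):
    """Proportion with a two-way cluster-robust normal CI, truncated to [0, 1].

    Returns (p_hat, lo, hi); all NaN when the denominator is empty.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return (np.nan, np.nan, np.nan)
    p = float(y.mean())
    X = np.ones((n, 1))
    V = twoway_sandwich(X, y - p, hh, ind)
    z = float(stats.norm.ppf(0.5 + level / 2))
    se = float(np.sqrt(V[0, 0]))
    return (p, max(0.0, p - z * se), min(1.0, p + z * se))


def twoway_wald_sex_test(y, is_male, hh, ind) -> dict:
    """Two-sided Wald test of equal proportions by sex.

    Fits the linear-probability contrast y ~ 1 + male and tests the male
    coefficient with the two-way clustered variance.  Returns a dict with
    the difference, its SE, the Wald statistic (z^2, chi-square 1 df) and
    the p-value; a stratum with one sex absent is flagged degenerate with
    no p-value.
    """
    y = np.asarray(y, dtype=float)
    male = np.asarray(is_male, dtype=float)
    if len(np.unique(male)) < 2:
        return {"diff": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
                "degenerate": True}
    X = np.column_stack([np.ones_like(y), male])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    V = twoway_sandwich(X, resid, hh, ind)
    diff = float(beta[1])
    se = float(np.sqrt(V[1, 1]))
    if abs(diff) < 1e-12:
        return {"diff": 0.0, "se": se, "stat": 0.0, "p": 1.0, "degenerate": False}
    if se == 0.0:
        # a perfectly constant outcome cannot differ by chance
        return {"diff": diff, "se": 0.0, "stat": np.inf, "p": 0.0,
                "degenerate": False}
    stat = (diff / se) ** 2
    p = float(stats.chi2.sf(stat, df=1))
    return {"diff": diff, "se": se, "stat": float(stat), "p": p,
            "degenerate": False}
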