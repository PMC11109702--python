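"""Multilevel multinomial logit of move type on family/household structure.

Outcome per person-quarter: no move (baseline) or one of the four move
types.  For non-baseline category k the linear predictor is

    log P(y=k) / P(y=none) = x' beta_k + sigma_k * a_i ,   a_i ~ N(0, 1)

with a single standard-normal individual factor a_i carrying
category-specific loadings sigma_k — i.e. individual-level random
intercepts u_ik = sigma_k a_i with variance sigma_k^2, perfectly correlated
across categories.  The one-factor structure keeps the marginal likelihood
integral one-dimensional; it is evaluated by Gauss-Hermite quadrature and
maximised with analytic gradients.  Household clustering is handled on the
variance side: robust SEs cluster individual scores by (modal) household.
Setting all sigma_k = 0 reduces the estimator to a plain multinomial logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .moves import MOVE_TYPES

OUTCOME_ORDER = ("none",) + MOVE_TYPES
EXCLUDED_COMPOSITIONS = ("other", "no_ids", "external")
SES_FIELDS = ("head_employment_rank", "mother_secondary_edu",
              "father_secondary_edu", "dist_tarmac_km", "pop_density_cat")


class ModelError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Stratum and covariate layout of one regression model."""

    sex: str
    stage: str  # child | adolescent
    composition_baseline: str = "parents_siblings"
    include_own_child: bool | None = None  # default: adolescents only

    def __post_init__(self):
        if self.include_own_child is None:
            self.include_own_child = self.stage == "adolescent"


def build_model_dataset(panel: pd.DataFrame, moves: pd.DataFrame,
                        family_context: pd.DataFrame,
                        spec: ModelSpec) -> tuple[pd.DataFrame, dict]:
    """One row per in-stratum person-quarter with a five-level outcome.

    Exclusions (counts returned in the ledger dict): persons with no parent
    IDs; rows with composition in {other, no_ids, external}; rows missing a
    household socio-economic field; rows whose retained move has an
    unresolved distance.  In-migration moves never enter as outcomes: under
    the exposure-quarter timing the mover has no in-area pre-move record.
    """
    df = panel[(panel["sex"] == spec.sex)
               & (panel["life_stage"] == spec.stage)].copy()
    ledger = {"stratum_rows": len(df)}
    df = df.merge(family_context, on=["person_id", "quarter_date"], how="left")

    usable = moves[moves["direction"] != "in_migration"] if not moves.empty else moves
    if not usable.empty and "move_type" in usable:
        df = df.merge(usable[["person_id", "quarter_date", "move_type", "unresolved"]],
                      on=["person_id", "quarter_date"], how="left")
    else:
        df["move_type"] = None
        df["unresolved"] = False
    bad_move = df["unresolved"].notna() & (df["unresolved"] == True) \
        & df["move_type"].isna()  # noqa: E712 — object column with NaN holes
    ledger["dropped_unresolved_move"] = int(bad_move.sum())
    df = df[~bad_move]
    df["outcome"] = df["move_type"].where(df["move_type"].notna(), "none")

    no_ids = ~df["has_parent_ids"].astype(bool)
    ledger["dropped_no_parent_ids"] = int(no_ids.sum())
    df = df[~no_ids]

    bad_comp = df["composition"].isin(EXCLUDED_COMPOSITIONS) | df["composition"].isna()
    ledger["dropped_composition"] = int(bad_comp.sum())
    df = df[~bad_comp]

    ses_missing = pd.Series(False, index=df.index)
    for f in SES_FIELDS:
        ses_missing |= df[f].isna()
    ledger["dropped_ses_missing"] = int(ses_missing.sum())
    df = df[~ses_missing]

    ledger["rows"] = len(df)
    if df.empty:
        binding = max((k for k in ledger if k.startswith("dropped")),
                      key=lambda k: ledger[k])
        raise ModelError(f"empty model table; binding filter: {binding}")
    return df.reset_index(drop=True), ledger


def design_matrix(table: pd.DataFrame, spec: ModelSpec):
    """Numeric design matrix per the covariate list; returns
    (X DataFrame incl. intercept, y codes, individual ids, household ids)."""
    from .family import AGE_BAND_LABELS

    parts = {"intercept": np.ones(len(table))}
    comp = pd.get_dummies(table["composition"], prefix="comp")
    base = f"comp_{spec.composition_baseline}"
    for c in sorted(comp.columns):
        if c != base:
            parts[c] = comp[c].to_numpy(dtype=float)
    for c in AGE_BAND_LABELS:
        parts[c] = table[c].to_numpy(dtype=float)
    for c in ("nearby_maternal", "nearby_paternal", "nearby_sisters",
              "nearby_brothers", "nearby_nuclear"):
        parts[c] = table[c].to_numpy(dtype=float)
    if spec.include_own_child:
        parts["own_child_present"] = table["own_child_present"].to_numpy(dtype=float)
    for c in ("mother_dead", "father_dead"):
        # "known to be dead": unknown-parent NA counts as not known dead
        parts[c] = table[c].fillna(False).to_numpy(dtype=float)
    for col, prefix, baseline in (("age_subgroup", "agegrp", "youngest"),
                                  ("year_band", "year", None),
                                  ("pop_density_cat", "density", "low"),
                                  ("head_employment_rank", "rank", "low")):
        d = pd.get_dummies(table[col], prefix=prefix)
        cols = sorted(d.columns)
        drop = f"{prefix}_{baseline}" if baseline else cols[0]
        for c in cols:
            if c != drop:
                parts[c] = d[c].to_numpy(dtype=float)
    parts["dist_tarmac_km"] = table["dist_tarmac_km"].to_numpy(dtype=float)
    for c in ("mother_secondary_edu", "father_secondary_edu"):
        parts[c] = table[c].astype(float)
    X = pd.DataFrame(parts, index=table.index)
    # zero-variance columns cannot be identified at this scale; drop, record
    dropped = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    X.attrs["dropped_constant"] = dropped
    y = table["outcome"].map({c: i for i, c in enumerate(OUTCOME_ORDER)}).to_numpy()
    return X, y, table["person_id"].to_numpy(), table["unique_household_id"].to_numpy()


@dataclass
class FitResult:
    """Estimates from the multinomial one-factor random-intercept model."""

    categories: tuple
    terms: list
    beta: np.ndarray           # (K, p)
    se: np.ndarray             # (K, p) model-based
    se_cluster: np.ndarray     # (K, p) household-clustered
    sigma: np.ndarray          # (K,) loadings; variance sigma**2
    sigma_se: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_individuals: int
    n_households: int
    method: str = ("maximum likelihood, 1-D adaptive Gauss-Hermite over a "
                   "shared individual factor; household cluster-robust SEs")
    flags: list = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def random_intercept_variances(self) -> np.ndarray:
        return self.sigma ** 2

    def to_frame(self, robust: bool = True) -> pd.DataFrame:
        rows = []
        se = self.se_cluster if robust else self.se
        with np.errstate(over="ignore"):  # separated terms export OR = inf
            for k, cat in enumerate(self.categories):
                for j, t in enumerate(self.terms):
                    rows.append({"category": cat, "term": t,
                                 "coef": self.beta[k, j], "se": se[k, j],
                                 "odds_ratio": float(np.exp(self.beta[k, j]))})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"categories": list(self.categories), "terms": list(self.terms),
                "beta": self.beta.tolist(), "se": self.se.tolist(),
                "se_cluster": self.se_cluster.tolist(),
                "sigma": self.sigma.tolist(),
                "random_intercept_variances": (self.sigma ** 2).tolist(),
                "loglik": self.loglik, "converged": self.converged,
                "n_obs": self.n_obs, "n_individuals": self.n_individuals,
                "n_households": self.n_households, "method": self.method,
                "flags": self.flags}


def _pack(beta, sigma):
    return np.concatenate([beta.ravel(), sigma])


def _unpack(theta, K, p):
    return theta[:K * p].reshape(K, p), theta[K * p:]


def _loglik_grad(theta, X, Y1, y0mask, ind_idx, n_ind, nodes, logw, K,
                 want_scores=False):
    p = X.shape[1]
    beta, sigma = _unpack(theta, K, p)
    XB = X @ beta.T                                     # (n, K)
    eta = XB[:, :, None] + sigma[None, :, None] * nodes[None, None, :]
    m = np.maximum(0.0, eta.max(axis=1))                # (n, M) log-denom stab.
    log_denom = m + np.log(np.exp(-m) + np.exp(eta - m[:, None, :]).sum(axis=1))
    ll_obs = -log_denom.copy()                          # (n, M)
    sel = ~y0mask
    ll_obs[sel] += np.einsum("nkm,nk->nm", eta[sel], Y1[sel])
    ll_ind = np.zeros((n_ind, ll_obs.shape[1]))
    np.add.at(ll_ind, ind_idx, ll_obs)
    a = ll_ind + logw[None, :]
    ll_i = special.logsumexp(a, axis=1)
    r = np.exp(a - ll_i[:, None])                       # posterior node weights
    robs = r[ind_idx]                                   # (n, M)
    P = np.exp(eta - log_denom[:, None, :])             # (n, K, M)
    resid = Y1[:, :, None] - P
    wr = np.einsum("nkm,nm->nk", resid, robs)           # (n, K)
    gbeta = X.T @ wr                                    # (p, K)
    gsigma = np.einsum("nkm,nm,m->k", resid, robs, nodes)
    nll = -float(ll_i.sum())
    grad = -_pack(gbeta.T, gsigma)
    if not want_scores:
        return nll, grad
    sb = np.zeros((n_ind, K, p))
    np.add.at(sb, ind_idx, wr[:, :, None] * X[:, None, :])
    ss = np.zeros((n_ind, K))
    np.add.at(ss, ind_idx, np.einsum("nkm,nm,m->nk", resid, robs, nodes))
    scores = np.concatenate([sb.reshape(n_ind, K * p), ss], axis=1)
    return nll, grad, scores


def fit_multinomial_multilevel(X, y, individual_ids, household_ids=None,
                               n_quad: int = 15, fix_sigma_zero: bool = False,
                               categories=None, maxiter: int = 500) -> FitResult:
    """Fit the multinomial one-factor random-intercept model by ML.

    Deterministic given the data (no stochastic steps).  Raises ModelError
    on non-convergence (carrying the optimizer message) and flags covariates
    whose coefficients run away (quasi-separation).
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        terms = [f"x{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y)
    cats_present = np.unique(y)
    K = int(cats_present.max())
    if categories is None:
        categories = tuple(OUTCOME_ORDER[1:K + 1])
    if set(range(K + 1)) - set(cats_present):
        raise ModelError("every outcome category must be observed")
    n, p = Xv.shape
    uniq, ind_idx = np.unique(np.asarray(individual_ids, dtype=object),
                              return_inverse=True)
    n_ind = len(uniq)
    Y1 = np.zeros((n, K))
    for k in range(1, K + 1):
        Y1[:, k - 1] = (y == k)
    y0mask = y == 0

    t_nodes, t_weights = np.polynomial.hermite.hermgauss(n_quad)
    nodes = np.sqrt(2.0) * t_nodes
    logw = np.log(t_weights) - 0.5 * np.log(np.pi)

    beta0 = np.zeros((K, p))
    counts = np.array([(y == k).mean() for k in range(K + 1)])
    if "intercept" in terms and counts[0] > 0:
        j = terms.index("intercept")
        beta0[:, j] = np.log(np.maximum(counts[1:], 1e-8) / counts[0])
    sigma0 = np.zeros(K) if fix_sigma_zero else np.full(K, 0.5)

    if fix_sigma_zero:
        nodes_use, logw_use = np.array([0.0]), np.array([0.0])
    else:
        nodes_use, logw_use = nodes, logw

    args = (Xv, Y1, y0mask, ind_idx, n_ind, nodes_use, logw_use, K)

    def fun(theta):
        return _loglik_grad(theta, *args)

    bounds = [(None, None)] * (K * p) + \
             ([(0.0, 0.0)] * K if fix_sigma_zero else [(0.0, 8.0)] * K)
    res = optimize.minimize(fun, _pack(beta0, sigma0), jac=True,
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "maxfun": 4 * maxiter})
    beta, sigma = _unpack(res.x, K, p)
    flags = []
    runaway = np.abs(beta) > 15
    if runaway.any():
        for k, j in zip(*np.nonzero(runaway)):
            flags.append(f"possible separation: {terms[j]} (category {categories[k]})")
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ModelError(f"non-convergence: {res.message}")

    H = _numerical_hessian(fun, res.x)
    free = np.ones(len(res.x), dtype=bool)
    if fix_sigma_zero:
        free[K * p:] = False
    else:
        free[K * p:] = sigma > 1e-8  # boundary sigmas carry no information
    cov = np.full((len(res.x), len(res.x)), np.nan)
    Hf = H[np.ix_(free, free)]
    try:
        cov_f = np.linalg.inv(Hf)
    except np.linalg.LinAlgError:
        cov_f = np.linalg.pinv(Hf)
        flags.append("singular information matrix; pseudo-inverse SEs")
    cov[np.ix_(free, free)] = cov_f
    se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    se = se_all[:K * p].reshape(K, p)
    sigma_se = se_all[K * p:]

    # household cluster-robust covariance on individual-level scores
    _, _, scores = _loglik_grad(res.x, *args, want_scores=True)
    if household_ids is None:
        hh_of_ind = uniq
    else:
        hh = pd.DataFrame({"i": ind_idx,
                           "h": np.asarray(household_ids, dtype=object)})
        hh_of_ind = hh.groupby("i")["h"].agg(
            lambda s: s.value_counts().index[0]).to_numpy()
    meat = np.zeros((len(res.x), len(res.x)))
    gdf = pd.DataFrame(scores)
    gsum = gdf.groupby(pd.Series(hh_of_ind)).sum().to_numpy()
    meat = gsum.T @ gsum
    cov_rob = np.full_like(cov, np.nan)
    cov_rob[np.ix_(free, free)] = cov_f @ meat[np.ix_(free, free)] @ cov_f
    se_rob_all = np.sqrt(np.clip(np.diag(cov_rob), 0, np.inf))
    se_rob = se_rob_all[:K * p].reshape(K, p)

    n_households = (len(np.unique(np.asarray(household_ids, dtype=object)))
                    if household_ids is not None else n_ind)
    return FitResult(categories=tuple(categories), terms=terms, beta=beta,
                     se=se, se_cluster=se_rob, sigma=sigma, sigma_se=sigma_se,
                     loglik=-res.fun, converged=bool(res.success),
                     n_obs=n, n_individuals=n_ind, n_households=n_households,
                     flags=flags)


def _numerical_hessian(fun, theta, h: float = 1e-5) -> np.ndarray:
    """Central differences of the analytic gradient."""
    m = len(theta)
    H = np.zeros((m, m))
    for j in range(m):
        e = np.zeros(m)
        e[j] = h
        _, gp = fun(theta + e)
        _, gm = fun(theta - e)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def predicted_probabilities(X, beta, sigma=None, a=None) -> np.ndarray:
    """Category probabilities (columns: baseline + K) for covariate rows,
    conditional on individual factor values ``a`` (zero by default)."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    beta = np.asarray(beta, dtype=float)
    eta = Xv @ beta.T
    if sigma is not None and a is not None:
        eta = eta + np.asarray(a)[:, None] * np.asarray(sigma)[None, :]
    full = np.column_stack([np.zeros(len(eta)), eta])
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def simulate_from_model(X, beta, sigma, individual_ids, seed: int) -> np.ndarray:
    """Draw outcome categories from the declared model (seeded).

    Individual factors a_i ~ N(0,1) are drawn per unique individual, then
    categories from the conditional multinomial probabilities.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(individual_ids, dtype=object)
    uniq, idx = np.unique(ids, return_inverse=True)
    a = rng.standard_normal(len(uniq))[idx]
    P = predicted_probabilities(X, beta, sigma=sigma, a=a)
    u = rng.random(len(P))
    return (P.cumsum(axis=1) < u[:, None]).sum(axis=1)


def fit_stratum(panel, moves, family_context, spec: ModelSpec,
                **kwargs) -> tuple[FitResult, dict]:
    """End-to-end: dataset construction + design matrix + fit for a stratum."""
    table, ledger = build_model_dataset(panel, moves, family_context, spec)
    X, y, ind, hh = design_matrix(table, spec)
    observed = np.unique(y)
    if len(observed) < 2:
        raise ModelError("outcome is degenerate in this stratum")
    # collapse to observed contiguous codes if some move types are absent
    remap = {c: i for i, c in enumerate(sorted(observed))}
    y2 = np.array([remap[v] for v in y])
    cats = tuple(OUTCOME_ORDER[c] for c in sorted(observed) if c != 0)
    fit = fit_multinomial_multilevel(X, y2, ind, hh, categories=cats, **kwargs)
    ledger["dropped_constant_columns"] = X.attrs.get("dropped_constant", [])
    return fit, ledger
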