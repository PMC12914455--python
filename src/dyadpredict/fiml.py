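"""Full-information maximum likelihood (FIML) regression under missing data.

Each dyad record is modeled as a draw from a multivariate normal whose
likelihood is evaluated on that record's observed variables only; the
saturated mean/covariance MLE is found by EM over missingness patterns.  For
a single linear regression the saturated model is the regression model, so
the ML regression coefficients follow from the estimated joint covariance:

    b = Sigma_xx^{-1} sigma_xy,   beta_j = b_j * sigma_xj / sigma_y

with standardization using the model-implied (full-information) variances.
Standard errors come from the expected (Fisher) information of the
observed-data likelihood conditional on the realized missingness patterns,
mapped to the standardized coefficients by the delta method, with an
n/(n - p - 1) small-sample rescaling and t-distributed Wald tests; a
sandwich variant (expected information bread, per-record analytic score
outer-product filling) provides robust standard errors.  Under MCAR/MAR this
yields unbiased estimates; with no missing data the estimator reduces
exactly to ordinary least squares, coefficients and t tests alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FIMLConvergenceError",
    "RegressionResult",
    "em_mvnorm",
    "mvn_observed_loglik",
    "expected_information",
    "observation_scores",
    "fit_fiml_regression",
]

_LOG2PI = np.log(2.0 * np.pi)


class FIMLConvergenceError(RuntimeError):
    """EM failed to reach the relative log-likelihood tolerance."""


@dataclass
class RegressionResult:
    """Standardized regression estimates from one fitted model."""

    outcome: str
    predictors: list[str]
    standardized_betas: dict[str, float]
    ses: dict[str, float]
    p_values: dict[str, float]
    estimator: str
    n_effective: int
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")
    raw_betas: dict[str, float] = field(default_factory=dict)
    intercept: float = float("nan")
    df_resid: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for term, b in self.standardized_betas.items():
            if np.isfinite(b) and abs(b) > 1.0:
                self.flags.append(f"|beta|>1 for {term}")

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval using the estimator's reference distribution."""
        b, se = self.standardized_betas[term], self.ses[term]
        if self.df_resid > 0:
            crit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        else:
            crit = stats.norm.ppf(0.5 + level / 2)
        return b - crit * se, b + crit * se

    def to_frame(self, model: str = "") -> pd.DataFrame:
        rows = [
            {
                "model": model or self.outcome,
                "outcome": self.outcome,
                "term": t,
                "beta": self.standardized_betas[t],
                "se": self.ses.get(t, np.nan),
                "p": self.p_values.get(t, np.nan),
                "estimator": self.estimator,
                "n": self.n_effective,
            }
            for t in self.predictors
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Observed-data likelihood machinery
# ---------------------------------------------------------------------------

def _pattern_groups(X: np.ndarray):
    """Group rows by missingness pattern; all-missing rows are dropped."""
    obs = ~np.isnan(X)
    keep = obs.any(axis=1)
    X = X[keep]
    obs = obs[keep]
    groups = []
    codes = obs @ (1 << np.arange(X.shape[1], dtype=np.int64))
    for code in np.unique(codes):
        rows = X[codes == code]
        o = np.flatnonzero(obs[codes == code][0])
        groups.append((o, rows[:, o]))
    return groups, int(keep.sum())


def mvn_observed_loglik(groups, mu: np.ndarray, Sigma: np.ndarray) -> float:
    ll = 0.0
    for o, rows in groups:
        Soo = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(Soo)
        if sign <= 0:
            return -np.inf
        resid = rows - mu[o]
        quad = np.einsum("ij,ij->i", resid, np.linalg.solve(Soo, resid.T).T)
        ll += -0.5 * (len(rows) * (len(o) * _LOG2PI + logdet) + quad.sum())
    return float(ll)


def em_mvnorm(
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 2000,
    raise_on_fail: bool = True,
):
    """MLE of (mu, Sigma) from data with missing entries, via EM.

    Convergence is declared when the relative change in the observed-data
    log-likelihood falls below ``tol``.  Returns
    ``(mu, Sigma, loglik, n_iter, converged)``.
    """
    X = np.asarray(X, dtype=float)
    groups, n = _pattern_groups(X)
    if n == 0:
        raise ValueError("no rows with at least one observed value")
    k = X.shape[1]
    col_obs = (~np.isnan(X)).sum(axis=0)
    if np.any(col_obs == 0):
        raise ValueError("every variable needs at least one observed value")

    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[var <= 0] = 1.0
    Sigma = np.diag(var)

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S1 = np.zeros(k)
        S2 = np.zeros((k, k))
        ll = 0.0
        for o, rows in groups:
            m = np.setdiff1d(np.arange(k), o, assume_unique=True)
            n_p = len(rows)
            Soo = Sigma[np.ix_(o, o)]
            sign, logdet = np.linalg.slogdet(Soo)
            resid = rows - mu[o]
            solved = np.linalg.solve(Soo, resid.T).T
            ll += -0.5 * (
                n_p * (len(o) * _LOG2PI + logdet)
                + np.einsum("ij,ij->i", resid, solved).sum()
            )
            full = np.empty((n_p, k))
            full[:, o] = rows
            if len(m):
                B = np.linalg.solve(Soo, Sigma[np.ix_(o, m)]).T  # (m, o)
                full[:, m] = mu[m] + resid @ B.T
                C = Sigma[np.ix_(m, m)] - B @ Sigma[np.ix_(o, m)]
                S2[np.ix_(m, m)] += n_p * C
            S1 += full.sum(axis=0)
            S2 += full.T @ full
        mu = S1 / n
        Sigma = S2 / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        if abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    if not converged and raise_on_fail:
        raise FIMLConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll_prev:.6f})"
        )
    return mu, Sigma, float(ll_prev), it, converged


# ---------------------------------------------------------------------------
# Information matrices in (mu, vech Sigma) coordinates
# ---------------------------------------------------------------------------

def _vech_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i, k)]


def _duplication_matrix(k: int) -> np.ndarray:
    """D such that vec(S) = D @ vech(S) for symmetric S."""
    pairs = _vech_indices(k)
    D = np.zeros((k * k, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        D[i * k + j, col] = 1.0
        D[j * k + i, col] = 1.0
        if i == j:
            D[i * k + j, col] = 1.0
    return D


def expected_information(groups, Sigma: np.ndarray) -> np.ndarray:
    """Fisher information of theta = (mu, vech Sigma), conditional on patterns."""
    k = Sigma.shape[0]
    pairs = _vech_indices(k)
    pair_col = {p: c for c, p in enumerate(pairs)}
    nv = len(pairs)
    I = np.zeros((k + nv, k + nv))
    for o, rows in groups:
        n_p = len(rows)
        lo = len(o)
        Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
        I[np.ix_(o, o)] += n_p * Soo_inv
        D = _duplication_matrix(lo)
        I_local = 0.5 * n_p * (D.T @ np.kron(Soo_inv, Soo_inv) @ D)
        local_pairs = _vech_indices(lo)
        cols = [pair_col[(min(o[a], o[b]), max(o[a], o[b]))] for a, b in local_pairs]
        gcols = k + np.asarray(cols)
        I[np.ix_(gcols, gcols)] += I_local
    return I


def observation_scores(groups, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Per-record analytic score vectors in (mu, vech Sigma) coordinates."""
    k = Sigma.shape[0]
    pairs = _vech_indices(k)
    pair_col = {p: c for c, p in enumerate(pairs)}
    nv = len(pairs)
    out = []
    for o, rows in groups:
        lo = len(o)
        Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
        D = _duplication_matrix(lo)
        local_pairs = _vech_indices(lo)
        cols = [pair_col[(min(o[a], o[b]), max(o[a], o[b]))] for a, b in local_pairs]
        gcols = k + np.asarray(cols)
        for x in rows:
            r = x - mu[o]
            s = np.zeros(k + nv)
            u = Soo_inv @ r
            s[o] = u
            G = 0.5 * (np.outer(u, u) - Soo_inv)
            s[gcols] = D.T @ G.reshape(-1)
            out.append(s)
    return np.asarray(out)


def _vech(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    return np.array([S[i, j] for i, j in _vech_indices(k)])


def _unvech(v: np.ndarray, k: int) -> np.ndarray:
    S = np.zeros((k, k))
    for (i, j), val in zip(_vech_indices(k), v):
        S[i, j] = val
        S[j, i] = val
    return S


# ---------------------------------------------------------------------------
# The regression fit
# ---------------------------------------------------------------------------

def _betas_from_moments(mu: np.ndarray, Sigma: np.ndarray, n_pred: int):
    """Raw slopes, intercept and standardized betas (outcome is last)."""
    Sxx = Sigma[:n_pred, :n_pred]
    sxy = Sigma[:n_pred, -1]
    b = np.linalg.solve(Sxx, sxy)
    intercept = mu[-1] - b @ mu[:n_pred]
    sd_x = np.sqrt(np.diag(Sxx))
    sd_y = np.sqrt(Sigma[-1, -1])
    return b, intercept, b * sd_x / sd_y


def fit_fiml_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors,
    covariates=(),
    robust: bool = False,
    tol: float = 1e-8,
) -> RegressionResult:
    """Fit a linear regression by FIML and report standardized coefficients.

    ``predictors`` and ``covariates`` are concatenated into the model terms;
    the distinction is purely bookkeeping.  With ``robust`` a sandwich
    covariance replaces the inverse expected information.
    """
    terms = list(predictors) + [c for c in covariates if c not in predictors]
    cols = terms + [outcome]
    X = data[cols].to_numpy(dtype=float)
    for j, c in enumerate(cols):
        col = X[:, j]
        if np.nanstd(col[~np.isnan(col)]) == 0:
            raise ValueError(f"variable {c!r} is constant")
    mu, Sigma, ll, n_iter, converged = em_mvnorm(X, tol=tol)
    groups, n_eff = _pattern_groups(X)

    n_pred = len(terms)
    b, intercept, std_beta = _betas_from_moments(mu, Sigma, n_pred)

    k = len(cols)
    I = expected_information(groups, Sigma)
    try:
        cov_theta = np.linalg.inv(I)
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular fallback
        cov_theta = np.linalg.pinv(I)
    if robust:
        S = observation_scores(groups, mu, Sigma)
        bread = cov_theta
        cov_theta = bread @ (S.T @ S) @ bread

    # delta method: standardized betas depend on vech(Sigma) only
    v0 = _vech(Sigma)
    nv = len(v0)
    J = np.zeros((n_pred, k + nv))
    for q in range(nv):
        h = 1e-6 * (1.0 + abs(v0[q]))
        vp, vm = v0.copy(), v0.copy()
        vp[q] += h
        vm[q] -= h
        _, _, bp = _betas_from_moments(mu, _unvech(vp, k), n_pred)
        _, _, bm = _betas_from_moments(mu, _unvech(vm, k), n_pred)
        J[:, k + q] = (bp - bm) / (2.0 * h)
    cov_beta = J @ cov_theta @ J.T
    # small-sample calibration: rescale the ML covariance by n/(n - p - 1)
    # and test against t(n - p - 1); with complete data this makes the Wald
    # test of each coefficient the exact OLS t test
    df_resid = max(n_eff - n_pred - 1, 1)
    cov_beta = cov_beta * (n_eff / df_resid)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, std_beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(tval), df_resid)

    return RegressionResult(
        outcome=outcome,
        predictors=terms,
        standardized_betas=dict(zip(terms, std_beta)),
        ses=dict(zip(terms, se)),
        p_values=dict(zip(terms, p)),
        estimator="fiml_robust" if robust else "fiml",
        n_effective=n_eff,
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
        raw_betas=dict(zip(terms, b)),
        intercept=float(intercept),
        df_resid=df_resid,
    )
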