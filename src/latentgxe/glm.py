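"""Binary-outcome GLM fitting and Wald tests of linear constraints.

The fitter is a Fisher-scoring iteration with step-halving, written for
the small fixed designs of single-SNP association models where the scan
path calls it hundreds of thousands of times.  The covariance reported is
the inverse of the observed Fisher information at the MLE (which for the
canonical logit link coincides with the expected information).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FitResult", "TestResult", "fit_binary_glm", "wald_test"]

#: |coefficient| on the link scale beyond which a non-vanishing score is
#: interpreted as complete or quasi-complete separation.
SEPARATION_BOUND = 15.0
SCORE_TOL = 1e-8
LLF_RTOL = 1e-10
MAX_ITER = 100


@dataclass
class FitResult:
    """MLE of a binary GLM: estimates, observed information, covariance."""

    params: np.ndarray
    information: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    status: str  # ok | separated | nonconverged | inestimable
    n: int
    link: str
    names: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))


@dataclass
class TestResult:
    """A Wald test of H0: L @ beta = 0.

    ``estimates``/``stderrs`` carry the tested coefficients (rows of L
    applied to the MLE) and their standard errors.  ``status`` is ``ok``
    for a clean test; otherwise the statistic and p-value are NaN and the
    flag explains why (``inestimable``, ``separated``, ``nonconverged``,
    or ``additive_fallback`` for a joint test degraded to 1 df).
    """

    statistic: float
    df: int
    p_value: float
    constraint: str
    estimates: np.ndarray
    stderrs: np.ndarray
    status: str = "ok"
    message: str = ""

    @classmethod
    def invalid(cls, status: str, constraint: str, df: int = 0, message: str = ""):
        return cls(
            statistic=float("nan"),
            df=df,
            p_value=float("nan"),
            constraint=constraint,
            estimates=np.array([]),
            stderrs=np.array([]),
            status=status,
            message=message,
        )


def _mu_weights(eta: np.ndarray, y: np.ndarray, link: str):
    """Per-observation mean, working score d l/d eta, and minus-Hessian weight.

    Returns (mu, u, w_obs) where the score is X' u and the observed
    information is X' diag(w_obs) X.
    """
    if link == "logit":
        mu = 1.0 / (1.0 + np.exp(-eta))
        u = y - mu
        w = mu * (1.0 - mu)  # observed == expected for the canonical link
        return mu, u, w
    # probit
    mu = stats.norm.cdf(eta)
    phi = stats.norm.pdf(eta)
    v = np.clip(mu * (1.0 - mu), 1e-300, None)
    u = (y - mu) * phi / v
    # -d u/d eta, from differentiating the per-observation score
    dphi = -eta * phi
    dv = phi * (1.0 - 2.0 * mu)
    w = (phi * phi * v - (y - mu) * (dphi * v - phi * dv)) / (v * v)
    return mu, u, w


def _loglik(eta: np.ndarray, y: np.ndarray, link: str) -> float:
    if link == "logit":
        # numerically stable Bernoulli log-likelihood on the link scale
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    mu = stats.norm.cdf(eta)
    mu = np.clip(mu, 1e-300, 1.0 - 1e-16)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def fit_binary_glm(
    y,
    design,
    link: str = "logit",
    names: list[str] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a binary GLM by Fisher scoring.

    Parameters
    ----------
    y : array of 0/1 outcomes (both classes must be present).
    design : (n, k) matrix including the intercept column.
    link : "logit" or "probit".
    names : optional column names for diagnostics.

    Convergence is declared when the largest score component falls below
    1e-8 or the relative log-likelihood change falls below 1e-10, within
    100 iterations.  Rank-deficient designs are reported as
    ``inestimable`` with the offending column named; diverging
    coefficients with a non-vanishing score are reported as ``separated``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if link not in ("logit", "probit"):
        raise ValueError(f"link must be 'logit' or 'probit', got {link!r}")
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("y must be 1-d and design (n, k) with matching n")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    n, k = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]

    def _invalid(status: str, message: str) -> FitResult:
        nan_mat = np.full((k, k), np.nan)
        return FitResult(
            params=np.full(k, np.nan),
            information=nan_mat,
            cov_params=nan_mat.copy(),
            llf=float("nan"),
            converged=False,
            status=status,
            n=n,
            link=link,
            names=names,
            message=message,
        )

    if y.min() == y.max():
        return _invalid("inestimable", "outcome has a single class")

    # rank check via QR with column pivoting
    _, R, piv = _qr_pivot(X)
    diag = np.abs(np.diag(R))
    if diag.size and (diag < 1e-10 * max(diag[0], 1.0)).any():
        j = int(piv[int(np.argmax(diag < 1e-10 * max(diag[0], 1.0)))])
        return _invalid(
            "inestimable", f"design is rank deficient (column {names[j]!r})"
        )

    beta = np.zeros(k)
    # start from the intercept implied by the sample prevalence
    pbar = y.mean()
    eta0 = (
        np.log(pbar / (1.0 - pbar)) if link == "logit" else stats.norm.ppf(pbar)
    )
    col_norm = np.abs(X).max(axis=0)
    intercept_like = np.isclose(X, X[0], atol=0).all(axis=0) & (col_norm > 0)
    if intercept_like.any():
        j = int(np.argmax(intercept_like))
        beta[j] = eta0 / X[0, j]

    eta = X @ beta
    llf = _loglik(eta, y, link)
    converged = False
    for _ in range(MAX_ITER):
        mu, u, _ = _mu_weights(eta, y, link)
        score = X.T @ u
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        # expected-information weights for the scoring step
        if link == "logit":
            w_exp = mu * (1.0 - mu)
        else:
            phi = stats.norm.pdf(eta)
            w_exp = phi * phi / np.clip(mu * (1.0 - mu), 1e-300, None)
        XtWX = (X * w_exp[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            return _invalid("inestimable", "singular information matrix")
        new_llf = -np.inf
        for _half in range(30):
            cand = beta + step
            cand_eta = X @ cand
            new_llf = _loglik(cand_eta, y, link)
            if new_llf >= llf - 1e-12:
                break
            step *= 0.5
        beta, eta = cand, cand_eta
        if abs(new_llf - llf) < LLF_RTOL * (abs(llf) + 1.0):
            llf = new_llf
            mu, u, _ = _mu_weights(eta, y, link)
            score = X.T @ u
            converged = True
            break
        llf = new_llf
    else:
        mu, u, _ = _mu_weights(eta, y, link)
        score = X.T @ u

    # one extra scoring step past the stopping rule squares the residual
    # score, so equivalent saturated parameterizations agree to ~machine
    # precision rather than to the convergence tolerance
    if converged:
        for _ in range(2):
            mu, u, _ = _mu_weights(eta, y, link)
            score = X.T @ u
            if link == "logit":
                w_exp = mu * (1.0 - mu)
            else:
                phi = stats.norm.pdf(eta)
                w_exp = phi * phi / np.clip(mu * (1.0 - mu), 1e-300, None)
            try:
                step = np.linalg.solve((X * w_exp[:, None]).T @ X, score)
            except np.linalg.LinAlgError:
                break
            cand = beta + step
            cand_eta = X @ cand
            _, u2, _ = _mu_weights(cand_eta, y, link)
            if np.abs(X.T @ u2).max() <= np.abs(score).max():
                beta, eta = cand, cand_eta

    llf = _loglik(eta, y, link)
    mu, u, w_obs = _mu_weights(eta, y, link)
    score = X.T @ u
    # complete separation drives the residuals (and hence the score) to
    # zero while the coefficients diverge, so the diverging-coefficient
    # bound is the operative check in both the complete and quasi cases
    if np.abs(beta).max() > SEPARATION_BOUND:
        return _invalid(
            "separated",
            "coefficients diverging on the link scale: complete or "
            "quasi-complete separation",
        )
    if not converged and np.abs(score).max() >= SCORE_TOL:
        return _invalid("nonconverged", "Fisher scoring did not converge")

    info = (X * w_obs[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return _invalid("inestimable", "observed information is singular")
    return FitResult(
        params=beta,
        information=info,
        cov_params=cov,
        llf=llf,
        converged=True,
        status="ok",
        n=n,
        link=link,
        names=names,
    )


def _qr_pivot(X: np.ndarray):
    """QR with column pivoting via scipy; returns (Q, R, pivot)."""
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def wald_test(fit: FitResult, L, constraint: str = "") -> TestResult:
    """Wald test of H0: L @ beta = 0 using the observed information.

    T = (L b)' (L I^{-1} L')^{-1} (L b), asymptotically chi-square with
    d = rank(L) degrees of freedom under H0.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    d = L.shape[0]
    if fit.status != "ok":
        return TestResult.invalid(fit.status, constraint, df=d, message=fit.message)
    if np.linalg.matrix_rank(L) < d:
        return TestResult.invalid(
            "inestimable", constraint, df=d, message="constraint rows not independent"
        )
    est = L @ fit.params
    mid = L @ fit.cov_params @ L.T
    try:
        sol = np.linalg.solve(mid, est)
    except np.linalg.LinAlgError:
        return TestResult.invalid(
            "inestimable", constraint, df=d, message="singular constraint covariance"
        )
    T = float(est @ sol)
    return TestResult(
        statistic=T,
        df=d,
        p_value=float(stats.chi2.sf(T, d)),
        constraint=constraint,
        estimates=est,
        stderrs=np.sqrt(np.diag(mid)),
    )
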