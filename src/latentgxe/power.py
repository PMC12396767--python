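"""Analytic power of the dominance and joint Wald tests.

Under a probit generative model the induced saturated model is exactly a
probit regression in the orthogonal encoding, so the asymptotic power of
a Wald test of L @ beta* = 0 can be computed without simulation:

1. map the latent parameters to (beta0*, betaA*, betaD*);
2. form the expected per-design Fisher information
   I = n * sum_g HWE(g) * w(eta_g) * x_g x_g',  w = f(eta)^2 / (F(1-F));
3. the non-centrality is lambda = (L b)' (L I^{-1} L')^{-1} (L b);
4. power = 1 - F_{chi2(d, lambda)}(chi2(d)^{-1}(1 - alpha)).

The default significance level is the genome-wide threshold 5e-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .encodings import dominance_values, hwe_frequencies
from .latent import (
    LatentModelParams,
    OrthogonalEffects,
    gammas_from_latent,
    orthogonal_from_gammas,
    solve_intercept_for_prevalence,
)

__all__ = [
    "PowerSpec",
    "expected_information",
    "noncentrality",
    "analytic_power",
    "power_grid",
    "constraint_matrix",
]

GENOME_WIDE_ALPHA = 5e-8

_TESTS = ("nonadditive", "joint", "additive")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of one analytic power evaluation."""

    params: LatentModelParams
    p: float
    n: int
    alpha: float = GENOME_WIDE_ALPHA
    test: str = "nonadditive"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}")


def constraint_matrix(test: str) -> np.ndarray:
    """Rows of L for beta* = (beta0*, betaA*, betaD*)."""
    if test == "nonadditive":
        return np.array([[0.0, 0.0, 1.0]])
    if test == "additive":
        return np.array([[0.0, 1.0, 0.0]])
    if test == "joint":
        return np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    raise ValueError(f"unknown test {test!r}")


def _link_weight(eta: np.ndarray, link: str) -> np.ndarray:
    """GLM information weight w(eta) = f(eta)^2 / (F(eta)(1 - F(eta)))."""
    if link == "probit":
        F = stats.norm.cdf(eta)
        f = stats.norm.pdf(eta)
        return f * f / np.clip(F * (1.0 - F), 1e-300, None)
    mu = 1.0 / (1.0 + np.exp(-np.asarray(eta)))
    return mu * (1.0 - mu)


def expected_information(
    beta_star: OrthogonalEffects | np.ndarray,
    p: float,
    n: int,
    link: str = "probit",
) -> np.ndarray:
    """Expected Fisher information of the orthogonal design under HWE.

    ``beta_star`` may be an :class:`OrthogonalEffects` or a length-3 array
    (beta0*, betaA*, betaD*).  Returns the 3x3 matrix
    n * sum_g HWE(g) w(eta_g) x_g x_g' with x_g = (1, g, G_D(g)).
    """
    b = (
        beta_star.coefficients
        if isinstance(beta_star, OrthogonalEffects)
        else np.asarray(beta_star, dtype=float)
    )
    hwe = hwe_frequencies(p)
    dom = dominance_values(p)
    info = np.zeros((3, 3))
    for g in range(3):
        x = np.array([1.0, float(g), dom[g]])
        eta = float(b @ x)
        info += hwe[g] * float(_link_weight(np.array(eta), link)) * np.outer(x, x)
    return n * info


def noncentrality(beta_star, L, information) -> float:
    """Non-centrality lambda = (L b)' (L I^{-1} L')^{-1} (L b)."""
    b = (
        beta_star.coefficients
        if isinstance(beta_star, OrthogonalEffects)
        else np.asarray(beta_star, dtype=float)
    )
    L = np.atleast_2d(np.asarray(L, dtype=float))
    I_inv = np.linalg.inv(information)
    mid = L @ I_inv @ L.T
    est = L @ b
    try:
        lam = float(est @ np.linalg.solve(mid, est))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "constraint covariance L I^-1 L' is singular"
        ) from exc
    return max(lam, 0.0)


def analytic_power(spec: PowerSpec) -> float:
    """Asymptotic power of the requested Wald test under the latent model.

    The latent parameters must describe a probit truth for the result to
    be exact; a logit truth is accepted with a warning since the induced
    saturated model is then only approximately a logistic regression.
    """
    params = spec.params
    if params.link != "probit":
        warnings.warn(
            "analytic power is exact only under a probit generative model; "
            "logit-based values are approximate",
            stacklevel=2,
        )
    gam = gammas_from_latent(params)
    orth = orthogonal_from_gammas(gam, spec.p)
    info = expected_information(orth, spec.p, spec.n, link=params.link)
    L = constraint_matrix(spec.test)
    lam = noncentrality(orth, L, info)
    d = L.shape[0]
    crit = stats.chi2.ppf(1.0 - spec.alpha, d)
    return float(stats.ncx2.sf(crit, d, lam))


def power_grid(
    betaG_values,
    betaGE_values,
    betaE: float,
    n: int,
    p: float = 0.3,
    target_prevalence: float = 0.1,
    alpha: float = GENOME_WIDE_ALPHA,
    tests: tuple[str, ...] = ("nonadditive", "joint"),
) -> pd.DataFrame:
    """Analytic power over a (betaG, betaGE) mesh at fixed prevalence.

    The intercept is re-solved at every grid point so the population
    prevalence is held at ``target_prevalence``.
    """
    rows = []
    base = LatentModelParams(beta0=0.0, betaE=betaE, link="probit")
    for bG in np.atleast_1d(betaG_values):
        for bGE in np.atleast_1d(betaGE_values):
            par = replace(base, betaG=float(bG), betaGE=float(bGE))
            b0 = solve_intercept_for_prevalence(target_prevalence, par, p)
            par = replace(par, beta0=b0)
            row = {
                "betaG": float(bG),
                "betaGE": float(bGE),
                "betaE": betaE,
                "p": p,
                "n": n,
                "alpha": alpha,
                "beta0": b0,
            }
            for test in tests:
                row[f"power_{test}"] = analytic_power(
                    PowerSpec(params=par, p=p, n=n, alpha=alpha, test=test)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def find_blind_spot(
    betaE: float,
    p: float = 0.3,
    target_prevalence: float = 0.1,
    n: int = 30_000,
    bound: float = 1.0,
    min_distance: float = 0.15,
) -> tuple[float, float]:
    """Locate a (betaG, betaGE) pair, both away from zero, where the joint
    test is nearly powerless because the induced betaA* and betaD* are
    both near zero.

    Exact simultaneous cancellation happens only at the origin, so the
    locator minimizes the joint-test non-centrality at sample size ``n``
    along the boundary min(|betaG|, |betaGE|) = ``min_distance``, trying
    each coordinate clamped to +/- the boundary in turn.
    """
    from scipy import optimize

    base = LatentModelParams(beta0=0.0, betaE=betaE, link="probit")
    L = constraint_matrix("joint")

    def lam(bG: float, bGE: float) -> float:
        par = replace(base, betaG=bG, betaGE=bGE)
        b0 = solve_intercept_for_prevalence(target_prevalence, par, p)
        orth = orthogonal_from_gammas(
            gammas_from_latent(replace(par, beta0=b0)), p
        )
        info = expected_information(orth, p, n, link="probit")
        return noncentrality(orth, L, info)

    best = None
    for clamp in ("bG", "bGE"):
        for sign in (1.0, -1.0):
            fixed = sign * min_distance
            obj = (
                (lambda t: lam(fixed, float(t)))
                if clamp == "bG"
                else (lambda t: lam(float(t), fixed))
            )
            for lo, hi in ((min_distance, bound), (-bound, -min_distance)):
                res = optimize.minimize_scalar(
                    obj, bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-9},
                )
                pair = (
                    (fixed, float(res.x)) if clamp == "bG"
                    else (float(res.x), fixed)
                )
                if best is None or res.fun < best[0]:
                    best = (float(res.fun), pair)
    return best[1]
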