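"""Theory of the induced non-additive effect under a latent interaction.

The generative model for a binary trait Y with genotype G (minor-allele
count) and an unobserved environmental variable E ~ N(0, sigmaE^2) is the
latent-threshold regression

    Y = 1{Y* >= 0},   Y* = beta0 + betaG*G + betaE*E + betaGE*G*E + eps,

with eps standard normal (probit) or standard logistic (logit).  When E is
latent, the marginal model of Y given G is still saturated in the three
genotype classes, with genotype-specific linear-predictor values

    gamma_g = (beta0 + betaG*g) / c(g),
    c(g)    = sqrt(sigma_eps^2 + (betaE + betaGE*g)^2 * sigmaE^2),

on the scale of the standardized error (eps - E*)/c(g).  Any latent
interaction (betaGE != 0) makes c(g) genotype-dependent and thereby bends
the genotype profile away from additivity: the induced dominance effect

    gammaD = gamma2 - 2*gamma1 + gamma0

is exactly zero when betaGE = 0, which is what makes a test of the
dominance coefficient an indirect test for the latent interaction.

The Fisher-orthogonal reparameterization of the same saturated model,
eta(G) = beta0* + betaA* * G_A + betaD* * G_D with G_D = (-p/q, 1, -q/p),
has closed-form coefficients

    betaA* = p*gammaD + (gamma1 - gamma0),    betaD* = -p*q*gammaD,

and the share of the genetic effect (on the latent scale) carried by the
non-additive component is R2_D = betaD*^2 / (2pq*betaA*^2 + betaD*^2).

For a probit error the standardized-error distribution is again standard
normal, so these expressions are exact; for a logistic error they are
approximate (the standardized error is only approximately logistic) and
the derived quantities are flagged accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .encodings import dominance_values, hwe_frequencies

__all__ = [
    "LatentModelParams",
    "GenotypicEffects",
    "OrthogonalEffects",
    "genotype_sd",
    "gammas_from_latent",
    "orthogonal_from_gammas",
    "dominance_variance_share",
    "solve_intercept_for_prevalence",
    "prevalence",
    "gamma_grid",
]

#: SD of the standard logistic distribution, pi/sqrt(3).
LOGISTIC_SD = math.pi / math.sqrt(3.0)


@dataclass(frozen=True)
class LatentModelParams:
    """True parameters of the latent-threshold generative model.

    ``sigma_eps`` defaults to the standard deviation of the error implied
    by the link: 1 for probit, pi/sqrt(3) for logit.  It may be overridden
    to explore other error scalings.
    """

    beta0: float
    betaG: float = 0.0
    betaE: float = 0.0
    betaGE: float = 0.0
    sigmaE: float = 1.0
    link: str = "probit"
    sigma_eps: float | None = None

    def __post_init__(self) -> None:
        if self.link not in ("probit", "logit"):
            raise ValueError(f"link must be 'probit' or 'logit', got {self.link!r}")
        if self.sigmaE <= 0:
            raise ValueError("sigmaE must be positive")
        if self.sigma_eps is None:
            object.__setattr__(
                self, "sigma_eps", 1.0 if self.link == "probit" else LOGISTIC_SD
            )
        elif self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")

    @property
    def error_cdf(self):
        """CDF of eps: standard normal (probit) or standard logistic (logit)."""
        return stats.norm.cdf if self.link == "probit" else stats.logistic.cdf


@dataclass(frozen=True)
class GenotypicEffects:
    """Saturated-model linear predictors per genotype class.

    ``exact`` is True when the working-link scale is exact (probit truth);
    logit-derived values rely on the approximate location-scale closure of
    the logistic family and are flagged approximate.
    """

    gamma0: float
    gamma1: float
    gamma2: float
    exact: bool = True

    @property
    def gammas(self) -> np.ndarray:
        return np.array([self.gamma0, self.gamma1, self.gamma2])

    @property
    def gammaD(self) -> float:
        """Dominance effect: deviation of the heterozygote from the homozygote midpoint."""
        return self.gamma2 - 2.0 * self.gamma1 + self.gamma0


@dataclass(frozen=True)
class OrthogonalEffects:
    """Coefficients of the Fisher-orthogonal parameterization at frequency p."""

    beta0_star: float
    betaA_star: float
    betaD_star: float
    p: float
    exact: bool = True

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0_star, self.betaA_star, self.betaD_star])


def genotype_sd(params: LatentModelParams, gA: int) -> float:
    """SD of the compound error eps - (betaE + betaGE*gA)*E given genotype gA."""
    slope = params.betaE + params.betaGE * gA
    return math.sqrt(params.sigma_eps**2 + slope**2 * params.sigmaE**2)


def gammas_from_latent(params: LatentModelParams) -> GenotypicEffects:
    """Induced genotype-class effects gamma_g = (beta0 + betaG*g)/c(g)."""
    g = [
        (params.beta0 + params.betaG * k) / genotype_sd(params, k) for k in range(3)
    ]
    return GenotypicEffects(*g, exact=params.link == "probit")


def orthogonal_from_gammas(
    g: GenotypicEffects, p: float
) -> OrthogonalEffects:
    """Map genotype-class effects to the orthogonal (beta0*, betaA*, betaD*).

    Uses the closed forms betaA* = p*gammaD + (gamma1 - gamma0) and
    betaD* = -p*q*gammaD; beta0* follows from matching the class-0 linear
    predictor.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    gD = g.gammaD
    betaA = p * gD + (g.gamma1 - g.gamma0)
    betaD = -p * q * gD
    # eta(0) = beta0* + betaD* * (-p/q) must equal gamma0
    beta0 = g.gamma0 + betaD * (p / q)
    return OrthogonalEffects(beta0, betaA, betaD, p=p, exact=g.exact)


def dominance_variance_share(o: OrthogonalEffects) -> float:
    """Proportion of latent-scale genetic variance from the non-additive term.

    Under HWE the orthogonal dominance column has unit variance and the
    additive column has variance 2pq, so
    R2_D = betaD*^2 / (2pq*betaA*^2 + betaD*^2).  Undefined (NaN) when both
    coefficients vanish.
    """
    two_pq = 2.0 * o.p * (1.0 - o.p)
    denom = two_pq * o.betaA_star**2 + o.betaD_star**2
    if denom == 0.0:
        return float("nan")
    return o.betaD_star**2 / denom


def prevalence(params: LatentModelParams, p: float, n_quad: int = 201) -> float:
    """Population case rate E[P(Y=1)] under HWE genotypes and E ~ N(0, sigmaE^2).

    For a probit error the inner integral over E is available in closed
    form; for logit it is computed by Gauss-Hermite quadrature.
    """
    weights = hwe_frequencies(p)
    if params.link == "probit":
        total = 0.0
        for k in range(3):
            total += weights[k] * stats.norm.cdf(
                (params.beta0 + params.betaG * k) / genotype_sd(params, k)
            )
        return float(total)
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quad)
    wts = wts / math.sqrt(2.0 * math.pi)
    total = 0.0
    for k in range(3):
        eta = (
            params.beta0
            + params.betaG * k
            + (params.betaE + params.betaGE * k) * params.sigmaE * nodes
        )
        total += weights[k] * float(np.sum(wts * stats.logistic.cdf(eta)))
    return float(total)


def solve_intercept_for_prevalence(
    target: float,
    params: LatentModelParams,
    p: float,
    tol: float = 1e-10,
) -> float:
    """Intercept beta0 giving the requested population prevalence.

    Solves prevalence(beta0) = target by Brent's method; the other fields
    of ``params`` are taken as given (its ``beta0`` is ignored).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")

    def resid(b0: float) -> float:
        return prevalence(replace(params, beta0=b0), p) - target

    lo, hi = -1.0, 1.0
    for _ in range(60):
        if resid(lo) < 0.0:
            break
        lo *= 2.0
    for _ in range(60):
        if resid(hi) > 0.0:
            break
        hi *= 2.0
    if resid(lo) > 0.0 or resid(hi) < 0.0:
        raise RuntimeError(
            f"could not bracket the intercept for target {target} in [{lo}, {hi}]"
        )
    b0 = optimize.brentq(resid, lo, hi, xtol=tol)
    if abs(resid(b0)) > 1e-8:
        raise RuntimeError(
            f"intercept solver residual {resid(b0):.3g} exceeds 1e-8"
        )
    return float(b0)


def gamma_grid(
    betaG_values,
    betaGE_values,
    betaE: float,
    p: float,
    target_prevalence: float,
    link: str = "probit",
    sigmaE: float = 1.0,
) -> pd.DataFrame:
    """Tabulate (gammaD, R2_D) over a (betaG, betaGE) mesh.

    For each grid point the intercept is re-solved so the population
    prevalence stays at ``target_prevalence``.  Returns one row per grid
    point with columns betaG, betaGE, betaE, p, prevalence, beta0, gammaD,
    betaA_star, betaD_star, r2_dominance.
    """
    rows = []
    base = LatentModelParams(
        beta0=0.0, betaE=betaE, link=link, sigmaE=sigmaE
    )
    for bG in np.atleast_1d(betaG_values):
        for bGE in np.atleast_1d(betaGE_values):
            par = replace(base, betaG=float(bG), betaGE=float(bGE))
            b0 = solve_intercept_for_prevalence(target_prevalence, par, p)
            par = replace(par, beta0=b0)
            gam = gammas_from_latent(par)
            orth = orthogonal_from_gammas(gam, p)
            rows.append(
                {
                    "betaG": float(bG),
                    "betaGE": float(bGE),
                    "betaE": betaE,
                    "p": p,
                    "prevalence": target_prevalence,
                    "beta0": b0,
                    "gammaD": gam.gammaD,
                    "betaA_star": orth.betaA_star,
                    "betaD_star": orth.betaD_star,
                    "r2_dominance": dominance_variance_share(orth),
                }
            )
    return pd.DataFrame(rows)


def class_probabilities(params: LatentModelParams) -> np.ndarray:
    """P(Y=1 | G=g) for g in (0, 1, 2) under the latent model.

    Exact for probit truth.  For logit truth these are the exact marginal
    probabilities computed by quadrature over E (not the location-scale
    approximation).
    """
    if params.link == "probit":
        return np.array(
            [
                stats.norm.cdf(
                    (params.beta0 + params.betaG * k) / genotype_sd(params, k)
                )
                for k in range(3)
            ]
        )
    nodes, wts = np.polynomial.hermite_e.hermegauss(201)
    wts = wts / math.sqrt(2.0 * math.pi)
    out = np.empty(3)
    for k in range(3):
        eta = (
            params.beta0
            + params.betaG * k
            + (params.betaE + params.betaGE * k) * params.sigmaE * nodes
        )
        out[k] = float(np.sum(wts * stats.logistic.cdf(eta)))
    return out


def orthogonal_design_row(g: int, p: float) -> np.ndarray:
    """Design row (1, G_A, G_D) of the orthogonal parameterization for class g."""
    return np.array([1.0, float(g), dominance_values(p)[g]])
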