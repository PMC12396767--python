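"""Synthetic data generation and the null-calibration studies.

Everything here draws from the latent-threshold generative model

    Y = 1{beta0 + betaG*G + betaE*E + betaGE*G*E + eps >= 0},

with G ~ Binomial(2, p) (HWE), E ~ N(0, sigmaE^2) and eps standard
normal or standard logistic.

Two computational paths exist for the replication studies.  The general
path simulates individual-level data and runs the full GLM machinery.
The fast path exploits that, with no covariates, the saturated model's
MLE depends on the data only through the per-genotype-class totals and
case counts: the fitted class probabilities equal the observed class case
rates, so the dominance and joint Wald statistics have closed forms that
vectorize across tens of thousands of replications.  The two paths agree
to machine precision (tested), and only the fast path is used for the
large type-I-error and power studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .encodings import hwe_frequencies
from .latent import LatentModelParams

__all__ = [
    "SimConfig",
    "simulate_dataset",
    "simulate_class_counts",
    "collapsed_wald",
    "null_pvalues",
    "type1_study",
    "permutation_null_scan",
    "make_fixture_panel",
    "FixturePanel",
]


@dataclass(frozen=True)
class SimConfig:
    """One simulation setting: model, MAF, sample size, replications, seed."""

    params: LatentModelParams
    maf: float
    n: int
    B: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.B < 1:
            raise ValueError("n and B must be at least 1")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("MAF must lie strictly in (0, 1)")


def _link_cdf(eta: np.ndarray, link: str) -> np.ndarray:
    return special.ndtr(eta) if link == "probit" else special.expit(eta)


def simulate_dataset(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw one individual-level dataset (y, g, E) from the latent model.

    Genotypes are Binomial(2, maf) (HWE), E ~ N(0, sigmaE^2) independent
    of G, and the outcome thresholds the latent liability.  Reproducible
    given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    par = cfg.params
    g = rng.binomial(2, cfg.maf, size=cfg.n).astype(float)
    e = rng.normal(0.0, par.sigmaE, size=cfg.n)
    eta = par.beta0 + par.betaG * g + par.betaE * e + par.betaGE * g * e
    y = (rng.random(cfg.n) < _link_cdf(eta, par.link)).astype(float)
    return y, g, e


def simulate_class_counts(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Per-replication genotype-class totals and case counts, vectorized.

    Returns ``(totals, cases)`` of shape (B, 3).  Individuals are still
    simulated one by one internally (the case count within a class is a
    Poisson-binomial over the latent E draws, not a plain binomial), but
    replications are processed in chunks of numpy work.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    par = cfg.params
    cum = np.cumsum(hwe_frequencies(cfg.maf))[:2]
    totals = np.empty((cfg.B, 3), dtype=np.int64)
    cases = np.empty((cfg.B, 3), dtype=np.int64)
    chunk = max(1, int(4_000_000 // cfg.n))
    done = 0
    while done < cfg.B:
        b = min(chunk, cfg.B - done)
        u = rng.random((b, cfg.n))
        g = (u > cum[0]).astype(np.int8) + (u > cum[1]).astype(np.int8)
        e = rng.standard_normal((b, cfg.n))
        if par.sigmaE != 1.0:
            e *= par.sigmaE
        eta = par.beta0 + par.betaG * g + (par.betaE + par.betaGE * g) * e
        y = rng.random((b, cfg.n)) < _link_cdf(eta, par.link)
        for k in range(3):
            mask = g == k
            totals[done : done + b, k] = mask.sum(axis=1)
            cases[done : done + b, k] = (y & mask).sum(axis=1)
        done += b
    return totals, cases


def collapsed_wald(totals, cases, link: str = "logit"):
    """Closed-form saturated-model Wald statistics from class counts.

    For a design collapsing to the three genotype classes the MLE fits
    each class case rate exactly; the information matrix is diagonal in
    the genotypic parameterization, giving

        T_dom   = gammaD_hat^2 / sum_g c_g^2 / (n_g w_g),  c = (1, -2, 1)
        T_joint = d' M^{-1} d,  d = (gamma1-gamma0, gamma2-gamma1),

    with w_g the GLM information weight at the fitted class rate.  Both
    statistics are invariant to the dominance encoding, so they equal the
    full-design fits in any saturated parameterization.

    Returns ``(t_dom, t_joint, valid)``; replications with an empty class
    or a class with no cases or no controls are flagged invalid (their
    saturated MLE is not finite) and carry NaN statistics.
    """
    totals = np.asarray(totals, dtype=float)
    cases = np.asarray(cases, dtype=float)
    valid = (totals > 0).all(axis=1) & (cases > 0).all(axis=1) & (
        cases < totals
    ).all(axis=1)
    mu = np.where(valid[:, None], cases / np.where(totals > 0, totals, 1.0), 0.5)
    if link == "logit":
        gam = np.log(mu / (1.0 - mu))
        w = mu * (1.0 - mu)
    elif link == "probit":
        gam = special.ndtri(mu)
        phi = stats.norm.pdf(gam)
        w = phi * phi / (mu * (1.0 - mu))
    else:
        raise ValueError(f"link must be 'logit' or 'probit', got {link!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        var = 1.0 / (totals * w)  # Var(gamma_g_hat), diagonal information

        gd = gam[:, 2] - 2.0 * gam[:, 1] + gam[:, 0]
        var_gd = var[:, 0] + 4.0 * var[:, 1] + var[:, 2]
        t_dom = gd * gd / var_gd

        d1 = gam[:, 1] - gam[:, 0]
        d2 = gam[:, 2] - gam[:, 1]
        m11 = var[:, 0] + var[:, 1]
        m22 = var[:, 1] + var[:, 2]
        m12 = -var[:, 1]
        det = m11 * m22 - m12 * m12
        t_joint = (m22 * d1 * d1 - 2.0 * m12 * d1 * d2 + m11 * d2 * d2) / det

    t_dom = np.where(valid, t_dom, np.nan)
    t_joint = np.where(valid, t_joint, np.nan)
    return t_dom, t_joint, valid


def null_pvalues(cfg: SimConfig, test: str = "nonadditive",
                 rng: np.random.Generator | None = None):
    """P-values of the requested test over B fast-path replications.

    Returns ``(pvalues, n_degenerate)``; degenerate replications (those
    whose saturated fit is not finite) are excluded from the p-value
    vector and counted, never silently dropped.
    """
    totals, cases = simulate_class_counts(cfg, rng=rng)
    t_dom, t_joint, valid = collapsed_wald(totals, cases, link=cfg.params.link)
    if test == "nonadditive":
        p = stats.chi2.sf(t_dom[valid], 1)
    elif test == "joint":
        p = stats.chi2.sf(t_joint[valid], 2)
    else:
        raise ValueError("test must be 'nonadditive' or 'joint'")
    return p, int((~valid).sum())


# -- Table-1-style type-I-error study ---------------------------------------

#: Generating values of the theoretical-null study: logistic model with
#: beta0 = -1 and betaG = 0.5 (dominance test) or betaG = 0 (joint test).
TYPE1_BETA0 = -1.0
TYPE1_BETAG = 0.5


def type1_study(
    test: str = "nonadditive",
    mafs=(0.1, 0.3, 0.5),
    betaEs=(0.0, 1.0),
    alphas=(0.05, 0.005, 0.0005),
    n: int = 20_000,
    B: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical type-I error of the dominance or joint test on a MAF x betaE grid.

    The generating model is the logistic null with beta0 = -1, betaGE = 0
    and betaG = 0.5 (dominance test) or betaG = 0 (joint test); E ~ N(0,1).
    The default scale (B = 2,000 replications of n = 20,000) is a
    desk-scale version of the full study (B = n = 100,000); pass larger
    ``n``/``B`` explicitly for the full protocol.

    Returns one row per (MAF, betaE) with the empirical size at each
    alpha, its binomial standard error, and the degenerate-replication
    count.
    """
    betaG = TYPE1_BETAG if test == "nonadditive" else 0.0
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(mafs) * len(betaEs))
    rows = []
    i = 0
    for betaE in betaEs:
        for maf in mafs:
            params = LatentModelParams(
                beta0=TYPE1_BETA0, betaG=betaG, betaE=betaE, betaGE=0.0,
                link="logit",
            )
            cfg = SimConfig(params=params, maf=maf, n=n, B=B, seed=seed)
            pvals, n_bad = null_pvalues(
                cfg, test=test, rng=np.random.default_rng(children[i])
            )
            i += 1
            row = {
                "test": test, "maf": maf, "betaE": betaE, "n": n,
                "B": B, "n_valid": pvals.size, "n_degenerate": n_bad,
            }
            for a in alphas:
                size = float((pvals <= a).mean())
                row[f"size_{a:g}"] = size
                row[f"se_{a:g}"] = float(
                    np.sqrt(a * (1.0 - a) / max(pvals.size, 1))
                )
            rows.append(row)
    return pd.DataFrame(rows)


# -- empirical-null permutation scan ----------------------------------------


def permutation_null_scan(y, genotypes, covariates=None, seed: int = 0,
                          **scan_kwargs):
    """Scan a permuted phenotype and report genomic-control lambdas.

    The phenotype is permuted once (seeded), preserving its prevalence
    exactly, and the full per-SNP scan is run.  Returns
    ``(scan_table, {"lambda_dominance": ..., "lambda_joint": ...,
    "lambda_additive": ...})``.
    """
    from .scan import gc_lambda, run_scan

    rng = np.random.default_rng(seed)
    y_perm = np.asarray(y, dtype=float).copy()
    rng.shuffle(y_perm)
    table = run_scan(y_perm, genotypes, covariates=covariates, **scan_kwargs)
    ok = table[table["status"] == "ok"]
    lambdas = {
        "lambda_dominance": gc_lambda(ok["p_dominance"].dropna(), df=1),
        "lambda_joint": gc_lambda(ok["p_joint"].dropna(), df=2),
        "lambda_additive": gc_lambda(ok["p_additive"].dropna(), df=1),
    }
    return table, lambdas


# -- synthetic cohort fixture ------------------------------------------------


@dataclass
class FixturePanel:
    """In-memory synthetic cohort: phenotype, genotypes, covariates, truth."""

    y: np.ndarray
    genotypes: pd.DataFrame  # individuals x SNPs, values in {0,1,2}
    covariates: pd.DataFrame
    truth: pd.DataFrame
    meta: dict = field(default_factory=dict)


def make_fixture_panel(
    n: int = 5_000,
    M: int = 200,
    planted: list[dict] | None = None,
    seed: int = 0,
    prevalence: float = 0.12,
    maf_range: tuple[float, float] = (0.05, 0.5),
    out_dir=None,
) -> FixturePanel:
    """Synthetic biobank-like cohort with mostly-null SNPs and planted effects.

    Emulates a self-reported binary trait at prevalence ~0.12 with
    covariates (age, sex, four genotype PCs) and independent SNPs under
    HWE.  ``planted`` entries are dicts with keys:

    ``snp``   index of the target SNP (int);
    ``kind``  one of ``additive``, ``dominance``, ``latent_gxg``;
    ``beta``  effect size on the latent logistic scale;
    ``index`` for ``latent_gxg``: index-SNP column whose product with the
              target enters the liability (inducing a marginal dominance
              effect at the target when the index SNP stays latent).

    The liability is logistic: covariate effects + planted genetic effects
    + intercept solved so the realized prevalence matches ``prevalence``.
    When ``out_dir`` is given, writes genotypes.tsv (matrix format),
    phenotype.tsv, covariates.tsv, truth.csv and meta.json.
    """
    rng = np.random.default_rng(seed)
    planted = planted or []

    mafs = rng.uniform(*maf_range, size=M)
    G = rng.binomial(2, mafs[None, :], size=(n, M)).astype(float)
    snp_ids = [f"snp{j:05d}" for j in range(M)]

    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    pcs = rng.standard_normal((n, 4))
    cov = pd.DataFrame(
        np.column_stack([age, sex, pcs]),
        columns=["age", "sex", "PC1", "PC2", "PC3", "PC4"],
    )
    # modest covariate effects on the liability (age in decades, male excess)
    lp = 0.02 * (age - 55.0) + 0.5 * sex + pcs @ np.full(4, 0.05)

    truth_rows = []
    for eff in planted:
        j = int(eff["snp"])
        beta = float(eff["beta"])
        kind = eff["kind"]
        if kind == "additive":
            lp = lp + beta * G[:, j]
        elif kind == "dominance":
            lp = lp + beta * (G[:, j] == 1).astype(float)
        elif kind == "latent_gxg":
            idx = int(eff["index"])
            lp = lp + beta * G[:, j] * G[:, idx]
        else:
            raise ValueError(f"unknown planted effect kind {kind!r}")
        truth_rows.append(
            {"snp": snp_ids[j], "kind": kind, "beta": beta,
             "index": snp_ids[int(eff["index"])] if kind == "latent_gxg" else ""}
        )

    # intercept calibrated so the expected case rate over the realized
    # liabilities equals the target prevalence
    b0 = optimize.brentq(
        lambda c: special.expit(c + lp).mean() - prevalence, -30.0, 30.0
    )
    y = (rng.random(n) < special.expit(b0 + lp)).astype(float)

    geno = pd.DataFrame(G, columns=snp_ids)
    geno.insert(0, "iid", [f"ind{i:06d}" for i in range(n)])
    geno = geno.set_index("iid")
    truth = pd.DataFrame(
        truth_rows, columns=["snp", "kind", "beta", "index"]
    )
    meta = {
        "n": n, "M": M, "seed": seed, "prevalence_target": prevalence,
        "prevalence_realized": float(y.mean()), "intercept": float(b0),
        "maf_range": list(maf_range), "planted": planted,
    }
    panel = FixturePanel(y=y, genotypes=geno, covariates=cov, truth=truth,
                         meta=meta)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gm = geno.copy()
        gm = gm.astype(int).astype(str)
        gm.to_csv(out / "genotypes.tsv", sep="\t")
        pd.DataFrame({"iid": geno.index, "phenotype": y.astype(int)}).to_csv(
            out / "phenotype.tsv", sep="\t", index=False
        )
        cov_out = cov.copy()
        cov_out.insert(0, "iid", geno.index)
        cov_out.to_csv(out / "covariates.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        with open(out / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return panel
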