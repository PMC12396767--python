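"""Single-SNP association models for binary traits.

The central object is :class:`SnpAssociationModel`, a statsmodels-style
model built from a binary phenotype, one SNP's genotypes and optional
covariates.  Its :meth:`~SnpAssociationModel.fit` returns a
:class:`SnpAssociationResults` exposing the three Wald tests around which
the method is organised:

* ``nonadditive_test`` — 1 df, H0: betaD = 0.  Because a latent
  interaction with an unobserved environment induces a non-zero dominance
  coefficient while a purely additive latent model does not, this is an
  indirect test for latent G×E (or G×G) interaction.
* ``joint_test`` — 2 df, H0: betaA = betaD = 0, detecting main effect and
  latent interaction together.
* ``additive_test`` — 1 df test of the additive coefficient in the
  traditional additive-only model (no dominance term).

Both the dominance and joint statistics are invariant to the choice of
saturated dominance encoding (Fisher-orthogonal, over-dominance or
genotypic indicators); the encoding only changes the interpretation of
the reported coefficients.

Module-level functions (``nonadditive_test``, ``joint_test``,
``additive_test``, ``interaction_test``, ``conditional_nonadditive_test``)
wrap these objects for one-shot use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encodings import as_genotype_vector, build_encoding, estimate_maf
from .glm import FitResult, TestResult, fit_binary_glm, wald_test

__all__ = [
    "SnpAssociationModel",
    "SnpAssociationResults",
    "nonadditive_test",
    "joint_test",
    "additive_test",
    "interaction_test",
    "conditional_nonadditive_test",
]


def _covariate_matrix(covariates, n: int):
    """Coerce covariates to (matrix, names); accepts None/DataFrame/array."""
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return C, [f"cov{j}" for j in range(C.shape[1])]


class SnpAssociationModel:
    """Binary-trait association model for one SNP with a dominance term.

    Parameters
    ----------
    y : binary phenotype vector (0/1).
    genotypes : minor-allele counts in {0, 1, 2}, NaN for missing;
        individuals with a missing call are dropped (complete-case).
    covariates : optional (n, c) array or DataFrame entering the linear
        predictor untransformed.
    link : "logit" (default, standard GWAS practice) or "probit".
    scheme : dominance encoding, "fisher_orthogonal" (default) or
        "overdominance".
    """

    def __init__(self, y, genotypes, covariates=None, link="logit",
                 scheme="fisher_orthogonal"):
        y = np.asarray(y, dtype=float)
        g = as_genotype_vector(genotypes)
        if y.size != g.size:
            raise ValueError("phenotype and genotype lengths differ")
        C, cov_names = _covariate_matrix(covariates, y.size)
        if C.shape[0] != y.size:
            raise ValueError("covariate rows do not match phenotype length")
        keep = ~np.isnan(g)
        if C.size:
            keep &= ~np.isnan(C).any(axis=1)
        self.n_dropped = int(y.size - keep.sum())
        self.y = y[keep]
        self.g = g[keep]
        self.covariates = C[keep]
        self.cov_names = cov_names
        self.link = link
        self.scheme = scheme
        self.maf = estimate_maf(self.g) if self.g.size else None
        if self.maf is not None and self.maf.flipped:
            self.g = 2.0 - self.g

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, phenotype: str, snp: str,
                       covariates: list[str] | None = None, **kwargs):
        cov = data[covariates] if covariates else None
        return cls(data[phenotype], data[snp], covariates=cov, **kwargs)

    # -- designs ---------------------------------------------------------
    def _design_full(self):
        enc = build_encoding(self.g, self.maf, scheme=self.scheme)
        if self.scheme == "genotypic":
            # saturated one-hot design: the indicators replace intercept + G_A
            X = np.column_stack([enc.dominance, self.covariates])
            names = [f"G_{k}" for k in range(3)] + self.cov_names
        else:
            X = np.column_stack(
                [np.ones(self.g.size), self.g, enc.dominance, self.covariates]
            )
            names = ["const", "G_A", "G_D"] + self.cov_names
        return X, names

    def _design_additive(self):
        X = np.column_stack([np.ones(self.g.size), self.g, self.covariates])
        return X, ["const", "G_A"] + self.cov_names

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.g).size)

    def fit(self) -> "SnpAssociationResults":
        """Fit the saturated (additive + dominance) and additive-only models."""
        if self.n_classes < 3:
            full = None
        else:
            X, names = self._design_full()
            full = fit_binary_glm(self.y, X, link=self.link, names=names)
        Xa, names_a = self._design_additive()
        additive = fit_binary_glm(self.y, Xa, link=self.link, names=names_a)
        return SnpAssociationResults(self, full, additive)


class SnpAssociationResults:
    """Fitted single-SNP association model; entry point to the Wald tests."""

    def __init__(self, model: SnpAssociationModel, full: FitResult | None,
                 additive: FitResult | None):
        self.model = model
        self.fit_full = full
        self.fit_additive = additive

    # -- coefficient access ----------------------------------------------
    @property
    def params(self) -> pd.Series:
        f = self.fit_full
        if f is None or f.status != "ok":
            return pd.Series(dtype=float)
        return pd.Series(f.params, index=f.names)

    @property
    def bse(self) -> pd.Series:
        f = self.fit_full
        if f is None or f.status != "ok":
            return pd.Series(dtype=float)
        return pd.Series(f.bse, index=f.names)

    def _constraint(self, which: str) -> np.ndarray:
        """Constraint matrix for the dominance or joint hypothesis.

        In the genotypic parameterization the same hypotheses are contrasts
        of the class effects: gammaD = gamma2 - 2*gamma1 + gamma0 for the
        dominance test, and equality of all three class effects for the
        joint test (a nonsingular recombination of betaA = betaD = 0, to
        which the Wald statistic is invariant).
        """
        names = self.fit_full.names
        k = len(names)
        if self.model.scheme == "genotypic":
            j = [names.index(f"G_{i}") for i in range(3)]
            if which == "dominance":
                L = np.zeros((1, k))
                L[0, j] = [1.0, -2.0, 1.0]
            else:
                L = np.zeros((2, k))
                L[0, j] = [-1.0, 1.0, 0.0]
                L[1, j] = [0.0, -1.0, 1.0]
            return L
        cols = ["G_D"] if which == "dominance" else ["G_A", "G_D"]
        L = np.zeros((len(cols), k))
        for i, nm in enumerate(cols):
            L[i, names.index(nm)] = 1.0
        return L

    # -- tests -----------------------------------------------------------
    def nonadditive_test(self) -> TestResult:
        """1-df Wald test of the dominance coefficient (H0: betaD = 0)."""
        if self.fit_full is None:
            return TestResult.invalid(
                "inestimable", "betaD = 0", df=1,
                message="dominance inestimable: fewer than 3 genotype classes",
            )
        if self.fit_full.status != "ok":
            return TestResult.invalid(
                self.fit_full.status, "betaD = 0", df=1,
                message=self.fit_full.message,
            )
        return wald_test(self.fit_full, self._constraint("dominance"),
                         constraint="betaD = 0")

    def joint_test(self) -> TestResult:
        """2-df joint Wald test (H0: betaA = betaD = 0).

        When the dominance column is inestimable (fewer than three genotype
        classes) the test degrades to the 1-df additive test with status
        ``additive_fallback`` — flagged, never silent.
        """
        if self.fit_full is None:
            res = self.additive_test()
            res.status = "additive_fallback"
            res.message = (
                "dominance inestimable (fewer than 3 genotype classes); "
                "1-df additive test reported instead"
            )
            return res
        if self.fit_full.status != "ok":
            return TestResult.invalid(
                self.fit_full.status, "betaA = betaD = 0", df=2,
                message=self.fit_full.message,
            )
        return wald_test(self.fit_full, self._constraint("joint"),
                         constraint="betaA = betaD = 0")

    def additive_test(self) -> TestResult:
        """1-df test of G_A in the additive-only model (traditional GWAS test)."""
        if self.fit_additive is None or self.fit_additive.status != "ok":
            status = "inestimable" if self.fit_additive is None else self.fit_additive.status
            return TestResult.invalid(status, "betaA = 0 (additive model)", df=1)
        k = len(self.fit_additive.names)
        L = np.zeros((1, k))
        L[0, self.fit_additive.names.index("G_A")] = 1.0
        return wald_test(self.fit_additive, L, constraint="betaA = 0 (additive model)")

    def summary(self) -> str:
        """Human-readable summary of the fits and the three tests."""
        lines = [
            "Single-SNP binary-trait association",
            f"  n = {self.model.y.size} (dropped {self.model.n_dropped} "
            "with missing data)",
            f"  link = {self.model.link}, dominance scheme = {self.model.scheme}",
            f"  MAF = {self.model.maf.p:.4f}"
            + (" (coding flipped to minor allele)" if self.model.maf.flipped else ""),
            "",
        ]
        if self.fit_full is not None and self.fit_full.status == "ok":
            lines.append("  coef        estimate        SE")
            for nm, b, s in zip(self.fit_full.names, self.fit_full.params,
                                self.fit_full.bse):
                lines.append(f"  {nm:<10s} {b:>10.5f} {s:>9.5f}")
            lines.append("")
        for label, res in [
            ("additive (1 df)", self.additive_test()),
            ("non-additive (1 df)", self.nonadditive_test()),
            ("joint (2 df)", self.joint_test()),
        ]:
            if res.status in ("ok", "additive_fallback"):
                lines.append(
                    f"  {label:<20s} T = {res.statistic:9.4f}  "
                    f"p = {res.p_value:.4g}"
                    + (f"  [{res.status}]" if res.status != "ok" else "")
                )
            else:
                lines.append(f"  {label:<20s} [{res.status}] {res.message}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def nonadditive_test(y, genotypes, covariates=None, link="logit",
                     scheme="fisher_orthogonal") -> TestResult:
    """1-df dominance Wald test; indirect test for latent interaction."""
    return SnpAssociationModel(
        y, genotypes, covariates, link=link, scheme=scheme
    ).fit().nonadditive_test()


def joint_test(y, genotypes, covariates=None, link="logit",
               scheme="fisher_orthogonal") -> TestResult:
    """2-df joint Wald test of the additive and dominance coefficients."""
    return SnpAssociationModel(
        y, genotypes, covariates, link=link, scheme=scheme
    ).fit().joint_test()


def additive_test(y, genotypes, covariates=None, link="logit") -> TestResult:
    """Traditional 1-df additive-only association test."""
    return SnpAssociationModel(y, genotypes, covariates, link=link).fit(
    ).additive_test()


def interaction_test(y, g1, g2, covariates=None, link="logit") -> TestResult:
    """Direct 1-df test of an additive-by-additive G×G product term.

    Fits intercept + G1 + G2 + G1·G2 (+ covariates) and Wald-tests the
    product coefficient.  Symmetric in the two SNPs.
    """
    y = np.asarray(y, dtype=float)
    a = as_genotype_vector(g1)
    b = as_genotype_vector(g2)
    if not (y.size == a.size == b.size):
        raise ValueError("phenotype and genotype lengths differ")
    C, cov_names = _covariate_matrix(covariates, y.size)
    keep = ~np.isnan(a) & ~np.isnan(b)
    if C.size:
        keep &= ~np.isnan(C).any(axis=1)
    y, a, b, C = y[keep], a[keep], b[keep], C[keep]
    for gv, nm in ((a, "g1"), (b, "g2")):
        if np.unique(gv).size < 2:
            return TestResult.invalid(
                "inestimable", "betaGE = 0", df=1,
                message=f"{nm} is monomorphic in the analyzed sample",
            )
    prod = a * b
    if np.unique(prod).size < 2:
        return TestResult.invalid(
            "inestimable", "betaGE = 0", df=1,
            message="product term is constant (empty interaction cells)",
        )
    X = np.column_stack([np.ones(y.size), a, b, prod, C])
    names = ["const", "G1_A", "G2_A", "G1xG2"] + cov_names
    fit = fit_binary_glm(y, X, link=link, names=names)
    L = np.zeros((1, X.shape[1]))
    L[0, 3] = 1.0
    return wald_test(fit, L, constraint="betaGE = 0")


def conditional_nonadditive_test(
    y, genotypes, index_snp, covariates=None, link="logit",
    scheme="fisher_orthogonal",
) -> tuple[TestResult, TestResult]:
    """Dominance test before and after adjusting for interaction with an index SNP.

    Returns ``(base, adjusted)`` where ``base`` is the ordinary dominance
    test and ``adjusted`` comes from the model that additionally includes
    the index SNP's additive effect and its product with the candidate's
    additive term.  If the candidate's dominance signal is driven by
    interaction with the index SNP, the adjusted dominance effect should
    attenuate toward zero.
    """
    if scheme == "genotypic":
        raise ValueError(
            "conditional dominance test needs a single dominance column; "
            "use fisher_orthogonal or overdominance"
        )
    y = np.asarray(y, dtype=float)
    g = as_genotype_vector(genotypes)
    idx = as_genotype_vector(index_snp)
    if not (y.size == g.size == idx.size):
        raise ValueError("phenotype and genotype lengths differ")
    C, cov_names = _covariate_matrix(covariates, y.size)
    keep = ~np.isnan(g) & ~np.isnan(idx)
    if C.size:
        keep &= ~np.isnan(C).any(axis=1)
    y, g, idx, C = y[keep], g[keep], idx[keep], C[keep]

    base = nonadditive_test(y, g, C if C.size else None, link=link, scheme=scheme)

    if np.unique(g).size < 3:
        return base, TestResult.invalid(
            "inestimable", "betaD = 0 | index adjustment", df=1,
            message="dominance inestimable: fewer than 3 genotype classes",
        )
    maf = estimate_maf(g)
    gg = 2.0 - g if maf.flipped else g
    enc = build_encoding(gg, maf, scheme=scheme)
    X = np.column_stack(
        [np.ones(y.size), gg, enc.dominance, idx, gg * idx, C]
    )
    names = ["const", "G_A", "G_D", "idx_A", "GxIdx"] + cov_names
    fit = fit_binary_glm(y, X, link=link, names=names)
    L = np.zeros((1, X.shape[1]))
    L[0, 2] = 1.0
    adjusted = wald_test(fit, L, constraint="betaD = 0 | index adjustment")
    return base, adjusted
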