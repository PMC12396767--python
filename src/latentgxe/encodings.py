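"""Genotype encodings for additive + non-additive single-SNP models.

A biallelic SNP is represented by per-individual minor-allele counts
``G_A`` in {0, 1, 2} (``aa``, ``Aa``, ``AA``), with ``NaN`` marking a
missing hard call.  On top of the additive column, three equivalent
saturated parameterizations of the genotypic model are supported through
their "dominance" column:

``fisher_orthogonal``
    ``(-p/q, 1, -q/p)`` for genotypes (0, 1, 2), where ``p`` is the
    frequency of the counted (minor) allele and ``q = 1 - p``.  Under
    Hardy-Weinberg equilibrium this column has mean 0, variance 1, and is
    uncorrelated with the additive column, so the coefficients cleanly
    partition the genetic effect into additive and non-additive parts.
``overdominance``
    ``(0, 1, 0)`` — the heterozygote indicator used by PLINK2's dominance
    term.  Not orthogonal to the additive column, but the dominance and
    joint Wald tests are invariant to this choice.
``genotypic``
    Three genotype-class indicators (a saturated one-hot design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleFrequency",
    "EncodingColumns",
    "as_genotype_vector",
    "estimate_maf",
    "build_encoding",
    "hwe_frequencies",
]

SCHEMES = ("fisher_orthogonal", "overdominance", "genotypic")


@dataclass(frozen=True)
class AlleleFrequency:
    """Frequency of the counted allele, with its complement.

    ``flipped`` records whether the original coding was reversed so that
    the counted allele is the minor one.
    """

    p: float
    flipped: bool = False
    q: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"allele frequency must be in [0, 1], got {self.p}")
        object.__setattr__(self, "q", 1.0 - self.p)


@dataclass(frozen=True)
class EncodingColumns:
    """Design columns for one SNP under a chosen dominance scheme."""

    additive: np.ndarray
    dominance: np.ndarray  # (n,) or (n, 3) for scheme="genotypic"
    scheme: str
    p: float


def as_genotype_vector(counts) -> np.ndarray:
    """Validate and coerce genotypes to a float array with NaN for missing.

    Accepts integer or float sequences; non-missing values must be exactly
    0, 1 or 2 (fractional imputation dosages are rejected).
    """
    g = np.asarray(counts, dtype=float)
    if g.ndim != 1:
        raise ValueError("genotype vector must be one-dimensional")
    if g.size == 0:
        raise ValueError("genotype vector is empty")
    obs = g[~np.isnan(g)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
        raise ValueError(
            f"genotypes must be hard calls in {{0,1,2}} or NaN; got {bad!r} "
            "(fractional dosages are not supported)"
        )
    return g


def estimate_maf(counts) -> AlleleFrequency:
    """Sample frequency of the minor allele, flipping the coding if needed.

    Returns the frequency computed from non-missing calls.  If the counted
    allele turns out to be the major one (frequency > 0.5) the coding is
    flipped (``2 - G``) and the flip recorded, so that downstream encodings
    always count the minor allele.
    """
    g = as_genotype_vector(counts)
    obs = g[~np.isnan(g)]
    if obs.size == 0:
        raise ValueError("no genotype data: all calls are missing")
    p = float(obs.sum() / (2.0 * obs.size))
    if p > 0.5:
        return AlleleFrequency(1.0 - p, flipped=True)
    return AlleleFrequency(p, flipped=False)


def hwe_frequencies(p: float | AlleleFrequency) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ``(q^2, 2pq, p^2)``."""
    if isinstance(p, AlleleFrequency):
        p = p.p
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def dominance_values(p: float) -> np.ndarray:
    """Fisher-orthogonal dominance codes ``(-p/q, 1, -q/p)`` for G=(0,1,2)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"degenerate encoding: need 0 < p < 1, got p={p}")
    q = 1.0 - p
    return np.array([-p / q, 1.0, -q / p])


def build_encoding(
    counts,
    p: float | AlleleFrequency | None = None,
    scheme: str = "fisher_orthogonal",
) -> EncodingColumns:
    """Build additive + dominance design columns for one SNP.

    Parameters
    ----------
    counts
        Minor-allele counts in {0, 1, 2}, NaN for missing.  If the supplied
        ``p`` is an :class:`AlleleFrequency` with ``flipped=True`` the counts
        are assumed already oriented to the minor allele.
    p
        Allele frequency of the counted allele; estimated from the sample
        when omitted.  Required to lie strictly in (0, 1) for the
        Fisher-orthogonal scheme.
    scheme
        One of ``fisher_orthogonal``, ``overdominance``, ``genotypic``.

    Missing genotypes propagate as NaN through every column.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    g = as_genotype_vector(counts)
    if p is None:
        freq = estimate_maf(g)
        if freq.flipped:
            g = 2.0 - g
        p_val = freq.p
    else:
        p_val = p.p if isinstance(p, AlleleFrequency) else float(p)
    if p_val > 0.5:
        warnings.warn(
            f"counted-allele frequency {p_val:.4g} exceeds 0.5; encoding built "
            "as given but the counted allele is not the minor one",
            stacklevel=2,
        )

    missing = np.isnan(g)
    if scheme == "genotypic":
        dom = np.zeros((g.size, 3))
        for k in range(3):
            dom[:, k] = (g == k).astype(float)
        dom[missing, :] = np.nan
        return EncodingColumns(additive=g, dominance=dom, scheme=scheme, p=p_val)

    if scheme == "fisher_orthogonal":
        codes = dominance_values(p_val)
    else:  # overdominance
        codes = np.array([0.0, 1.0, 0.0])
    dom = np.full(g.size, np.nan)
    ok = ~missing
    dom[ok] = codes[g[ok].astype(int)]
    return EncodingColumns(additive=g, dominance=dom, scheme=scheme, p=p_val)


def genotype_class_counts(counts) -> np.ndarray:
    """Counts of non-missing individuals in each genotype class (0, 1, 2)."""
    g = as_genotype_vector(counts)
    obs = g[~np.isnan(g)]
    return np.array([(obs == k).sum() for k in range(3)])
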