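"""Per-SNP genome scan: additive, dominance and joint tests with covariates.

Input genotypes are hard calls (minor-allele counts 0/1/2, NaN missing)
held in a :class:`GenotypeMatrix`.  Three plain-text sources are read:

* ``tsv_matrix`` — header row of SNP ids, first column individual id,
  cells in {0, 1, 2, NA};
* ``plink_raw`` — PLINK ``--export A`` dialect (FID IID PAT MAT SEX
  PHENOTYPE, then one ``<snp>_<allele>`` dosage column per SNP);
* ``vcf`` — GT fields converted to alt-allele counts (requires cyvcf2;
  half-calls and multi-allelic records are skipped with a log entry).

The scan applies the standard per-SNP QC filters (minimum MAF, call
rate, HWE goodness-of-fit floor), then runs the additive, dominance and
joint Wald tests per passing SNP, reporting all three p-values in one
row so the additive/joint contrast is reconstructable from a single
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encodings import estimate_maf, genotype_class_counts, hwe_frequencies
from .model import (
    SnpAssociationModel,
    conditional_nonadditive_test,
    interaction_test,
)

__all__ = [
    "GenotypeMatrix",
    "ScanFilters",
    "read_genotypes",
    "run_scan",
    "gc_lambda",
    "hwe_test_pvalue",
    "interaction_followup",
    "attenuation_analysis",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_SIGNIFICANCE = 5e-8


@dataclass
class GenotypeMatrix:
    """Hard-call genotype matrix (individuals x SNPs) with SNP metadata."""

    counts: np.ndarray  # (n, M) float, NaN = missing
    snp_ids: list[str]
    sample_ids: list[str]
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)
    counted_allele: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, m = self.counts.shape
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match matrix columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(set(self.snp_ids)) != m:
            raise ValueError("SNP ids must be unique")
        if not self.chrom:
            self.chrom = ["."] * m
        if not self.pos:
            self.pos = [0] * m
        if not self.counted_allele:
            self.counted_allele = ["."] * m

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.counts[:, self.snp_ids.index(snp_id)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        """Build from an individuals x SNPs DataFrame (index = sample ids)."""
        return cls(
            counts=df.to_numpy(dtype=float),
            snp_ids=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
        )

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=self.sample_ids,
                          columns=self.snp_ids)
        with np.errstate(invalid="ignore"):
            out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.index.name = "iid"
        out.to_csv(path, sep="\t")


def _read_tsv_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    counts = df.to_numpy(dtype=float)
    obs = counts[~np.isnan(counts)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        bad_rows = np.where(
            ~np.isin(counts, (0.0, 1.0, 2.0)) & ~np.isnan(counts)
        )[0]
        raise ValueError(
            f"malformed genotype value at data line {bad_rows[0] + 2} of {path}: "
            "cells must be 0, 1, 2 or NA"
        )
    return GenotypeMatrix(
        counts=counts,
        snp_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    fixed = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_cols = [c for c in fixed if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path} is not a PLINK --export A file: missing {missing_cols}"
        )
    snp_cols = [c for c in df.columns if c not in fixed]
    ids, alleles = [], []
    for c in snp_cols:
        if "_" not in c:
            raise ValueError(
                f"malformed PLINK raw column {c!r}: expected '<snp>_<allele>'"
            )
        snp, allele = c.rsplit("_", 1)
        ids.append(snp)
        alleles.append(allele)
    return GenotypeMatrix(
        counts=df[snp_cols].to_numpy(dtype=float),
        snp_ids=ids,
        sample_ids=[str(i) for i in df["IID"]],
        counted_allele=alleles,
    )


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading VCF requires cyvcf2 (install extra 'vcf')"
        ) from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, chroms, poss, alleles = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            logger.warning("skipping multi-allelic record %s:%s", v.CHROM, v.POS)
            continue
        col = np.full(len(samples), np.nan)
        half = False
        for i, gt in enumerate(v.genotypes):
            a = [x for x in gt[:-1]]
            if any(x < 0 for x in a):
                if any(x >= 0 for x in a):
                    half = True
                    break
                continue  # fully missing call
            col[i] = float(sum(1 for x in a if x == 1))
        if half:
            skipped += 1
            logger.warning("skipping half-called record %s:%s", v.CHROM, v.POS)
            continue
        cols.append(col)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        alleles.append(str(v.ALT[0]))
    if skipped:
        logger.info("skipped %d VCF records", skipped)
    if not cols:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(
        counts=np.column_stack(cols),
        snp_ids=ids,
        sample_ids=samples,
        chrom=chroms,
        pos=poss,
        counted_allele=alleles,
    )


def read_genotypes(path, format: str = "tsv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix from one of the supported plain formats."""
    readers = {
        "tsv_matrix": _read_tsv_matrix,
        "plink_raw": _read_plink_raw,
        "vcf": _read_vcf,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected {list(readers)}")
    return readers[format](path)


# ---------------------------------------------------------------------------


def hwe_test_pvalue(counts) -> float:
    """1-df chi-square goodness-of-fit p-value of HWE on genotype counts."""
    obs = genotype_class_counts(counts).astype(float)
    n = obs.sum()
    if n == 0:
        return float("nan")
    p = (obs[1] + 2.0 * obs[2]) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: HWE trivially satisfied
    exp = n * hwe_frequencies(p)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


@dataclass(frozen=True)
class ScanFilters:
    """Per-SNP QC thresholds (defaults follow common biobank practice)."""

    min_maf: float = 0.01
    min_call_rate: float = 0.8
    min_hwe_p: float = 1e-50


def run_scan(
    y,
    genotypes: GenotypeMatrix | pd.DataFrame,
    covariates=None,
    filters: ScanFilters | None = None,
    link: str = "logit",
    scheme: str = "fisher_orthogonal",
    alpha: float = GENOME_WIDE_SIGNIFICANCE,
) -> pd.DataFrame:
    """Additive, dominance and joint tests for every SNP passing QC.

    Returns one row per input SNP with columns: snp, chr, pos, maf,
    n_used, beta_A, se_A, beta_D, se_D, p_additive, p_dominance,
    p_joint, significant_joint, status.  Filtered SNPs keep a row with a
    ``filtered:*`` status so that #input = #tested + #filtered + #failed.
    The scan path involves no random numbers: identical inputs produce an
    identical table.
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = GenotypeMatrix.from_dataframe(genotypes)
    filters = filters or ScanFilters()
    y = np.asarray(y, dtype=float)
    if y.size != genotypes.n:
        raise ValueError(
            f"phenotype length {y.size} does not match genotype rows "
            f"{genotypes.n}"
        )
    if np.unique(y).size < 2:
        raise ValueError("phenotype must contain both classes")

    rows = []
    n_tested = n_filtered = n_failed = 0
    for j, snp in enumerate(genotypes.snp_ids):
        g = genotypes.counts[:, j]
        row = {
            "snp": snp,
            "chr": genotypes.chrom[j],
            "pos": genotypes.pos[j],
            "maf": np.nan, "n_used": 0,
            "beta_A": np.nan, "se_A": np.nan,
            "beta_D": np.nan, "se_D": np.nan,
            "p_additive": np.nan, "p_dominance": np.nan, "p_joint": np.nan,
            "significant_joint": False,
            "status": "",
        }
        obs = g[~np.isnan(g)]
        call_rate = obs.size / g.size
        if call_rate < filters.min_call_rate:
            row["status"] = "filtered:call_rate"
            n_filtered += 1
            rows.append(row)
            continue
        if obs.size == 0 or np.unique(obs).size == 1:
            row["status"] = "filtered:monomorphic"
            n_filtered += 1
            rows.append(row)
            continue
        maf = estimate_maf(g)
        row["maf"] = maf.p
        if maf.p < filters.min_maf:
            row["status"] = "filtered:maf"
            n_filtered += 1
            rows.append(row)
            continue
        if hwe_test_pvalue(g) < filters.min_hwe_p:
            row["status"] = "filtered:hwe"
            n_filtered += 1
            rows.append(row)
            continue

        try:
            res = SnpAssociationModel(
                y, g, covariates=covariates, link=link, scheme=scheme
            ).fit()
        except Exception as exc:  # defensive: scan must continue
            row["status"] = f"failed:{exc}"
            n_failed += 1
            rows.append(row)
            continue
        row["n_used"] = res.model.y.size
        add = res.additive_test()
        dom = res.nonadditive_test()
        joint = res.joint_test()
        params, bse = res.params, res.bse
        if "G_A" in params.index:
            row["beta_A"], row["se_A"] = params["G_A"], bse["G_A"]
        if "G_D" in params.index:
            row["beta_D"], row["se_D"] = params["G_D"], bse["G_D"]
        row["p_additive"] = add.p_value
        row["p_dominance"] = dom.p_value
        row["p_joint"] = joint.p_value
        statuses = {add.status, dom.status, joint.status}
        if statuses == {"ok"}:
            row["status"] = "ok"
            n_tested += 1
        else:
            bad = sorted(statuses - {"ok"})
            row["status"] = ";".join(bad)
            n_failed += 1
        row["significant_joint"] = bool(
            joint.status == "ok" and joint.p_value < alpha
        )
        rows.append(row)

    assert n_tested + n_filtered + n_failed == genotypes.n_snps
    logger.info(
        "scan: %d SNPs in, %d tested, %d filtered, %d failed",
        genotypes.n_snps, n_tested, n_filtered, n_failed,
    )
    return pd.DataFrame(rows)


def gc_lambda(p_values, df: int = 1) -> float:
    """Genomic-control inflation factor of a p-value vector.

    Converts p-values back to chi-square quantiles at the stated df and
    divides the observed median by the null median; 1 indicates a
    well-calibrated scan.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats_obs = stats.chi2.isf(p, df)
    return float(np.median(stats_obs) / stats.chi2.median(df))


def interaction_followup(
    y,
    genotypes: GenotypeMatrix | pd.DataFrame,
    index_snp_id: str,
    candidate_ids: list[str],
    covariates=None,
    link: str = "logit",
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise G×G interaction tests of candidates against an index SNP.

    For each candidate, reports the indirect (dominance) test p-value, the
    direct interaction test p-value, both coefficient estimates with
    standard errors, and a Bonferroni significance flag at family level
    ``family_alpha`` / #candidates.
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = GenotypeMatrix.from_dataframe(genotypes)
    if index_snp_id not in genotypes.snp_ids:
        raise ValueError(f"index SNP {index_snp_id!r} not present")
    if index_snp_id in candidate_ids:
        raise ValueError("index SNP cannot be tested against itself")
    g_idx = genotypes.column(index_snp_id)
    thr = family_alpha / max(len(candidate_ids), 1)
    rows = []
    for snp in candidate_ids:
        g = genotypes.column(snp)
        model_res = SnpAssociationModel(
            y, g, covariates=covariates, link=link
        ).fit()
        dom = model_res.nonadditive_test()
        inter = interaction_test(y, g, g_idx, covariates=covariates, link=link)
        beta_d = model_res.params.get("G_D", np.nan)
        se_d = model_res.bse.get("G_D", np.nan)
        rows.append(
            {
                "snp": snp,
                "p_indirect": dom.p_value,
                "p_interaction": inter.p_value,
                "beta_D": beta_d,
                "se_D": se_d,
                "beta_GE": inter.estimates[0] if inter.status == "ok" else np.nan,
                "se_GE": inter.stderrs[0] if inter.status == "ok" else np.nan,
                "significant_interaction": bool(
                    inter.status == "ok" and inter.p_value < thr
                ),
                "status": ";".join(sorted({dom.status, inter.status})),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thr
    return out


def attenuation_analysis(
    y,
    genotypes: GenotypeMatrix | pd.DataFrame,
    index_snp_id: str,
    candidate_ids: list[str],
    covariates=None,
    link: str = "logit",
) -> pd.DataFrame:
    """Dominance signal of candidates before/after adjusting for the index SNP.

    For each candidate runs the dominance test in the base model and in
    the model adding the index SNP's main effect and its interaction with
    the candidate.  Emits -log10 p and |beta_D| with standard errors for
    both fits, so attenuation of an interaction-induced dominance signal
    is directly measurable.
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = GenotypeMatrix.from_dataframe(genotypes)
    if index_snp_id not in genotypes.snp_ids:
        raise ValueError(f"index SNP {index_snp_id!r} not present")
    g_idx = genotypes.column(index_snp_id)
    rows = []
    for snp in candidate_ids:
        g = genotypes.column(snp)
        base, adj = conditional_nonadditive_test(
            y, g, g_idx, covariates=covariates, link=link
        )
        def _fields(res):
            if res.status != "ok":
                return np.nan, np.nan, np.nan
            return (
                -np.log10(max(res.p_value, 1e-320)),
                float(abs(res.estimates[0])),
                float(res.stderrs[0]),
            )
        nlp_b, abs_b, se_b = _fields(base)
        nlp_a, abs_a, se_a = _fields(adj)
        rows.append(
            {
                "snp": snp,
                "neglog10p_before": nlp_b,
                "neglog10p_after": nlp_a,
                "abs_beta_D_before": abs_b,
                "abs_beta_D_after": abs_a,
                "se_beta_D_before": se_b,
                "se_beta_D_after": se_a,
                "status": ";".join(sorted({base.status, adj.status})),
            }
        )
    return pd.DataFrame(rows)
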