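"""Per-SNP univariate association, Z-score correlation, and weighted-Z meta.

Univariate tests are ordinary least squares of each phenotype on each SNP
dosage with covariate adjustment, vectorised across SNPs and phenotypes by
residualising both sides on the covariate design (Frisch-Waugh).  Wald
p-values use the t reference with residual degrees of freedom
``n - n_covariates - 2``; a normal reference is available via ``use_t=False``
(at n = 2000 the two are indistinguishable).

The phenotype-by-phenotype correlation of Z scores across a pruned panel of
null SNPs is the plug-in estimate of the phenotype covariance the O'Brien
combined-Z test needs; under the null the correlation of Wald Z scores
equals the (sample) phenotype correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genosim import GenotypePanel, stabilize_correlation

__all__ = [
    "SnpSummaryTable",
    "ZCorrelation",
    "univariate_assoc",
    "zscore_correlation",
    "meta_weighted_z",
]


@dataclass
class SnpSummaryTable:
    """Per-SNP, per-phenotype summary statistics (beta, SE, Z, p).

    Arrays are ``(M, K)``; entries are NaN where a SNP was collinear with the
    covariates (flagged, not fatal).
    """

    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_effective: int
    maf: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return self.beta.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.beta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Wide TSV layout: SNP, CHR, POS, then BETA_k/SE_k/Z_k/P_k, N."""
        data = {"SNP": self.snp_ids, "CHR": self.chrom, "POS": self.pos}
        if self.maf is not None:
            data["MAF"] = self.maf
        for k in range(self.n_phenotypes):
            data[f"BETA_{k + 1}"] = self.beta[:, k]
            data[f"SE_{k + 1}"] = self.se[:, k]
            data[f"Z_{k + 1}"] = self.z[:, k]
            data[f"P_{k + 1}"] = self.p[:, k]
        data["N"] = self.n_effective
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpSummaryTable":
        ks = sorted(int(c.split("_")[1]) for c in df.columns if c.startswith("BETA_"))
        beta = np.column_stack([df[f"BETA_{k}"].to_numpy() for k in ks])
        se = np.column_stack([df[f"SE_{k}"].to_numpy() for k in ks])
        if all(f"Z_{k}" in df.columns for k in ks):
            z = np.column_stack([df[f"Z_{k}"].to_numpy() for k in ks])
        else:
            z = beta / se
        if all(f"P_{k}" in df.columns for k in ks):
            p = np.column_stack([df[f"P_{k}"].to_numpy() for k in ks])
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
        n = int(df["N"].iloc[0]) if "N" in df.columns else 0
        maf = df["MAF"].to_numpy() if "MAF" in df.columns else None
        return cls(snp_ids=list(df["SNP"]), chrom=df["CHR"].to_numpy(),
                   pos=df["POS"].to_numpy(), beta=beta, se=se, z=z, p=p,
                   n_effective=n, maf=maf)


@dataclass
class ZCorrelation:
    """K x K correlation of per-phenotype Z scores over a null SNP panel."""

    R: np.ndarray
    n_snps_used: int

    def __post_init__(self):
        self.R = stabilize_correlation(np.asarray(self.R, dtype=float))


def _residualize(mat: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Project out the orthonormal column span ``q``."""
    return mat - q @ (q.T @ mat)


def wald_z_residualized(gr: np.ndarray, yr: np.ndarray, gss: np.ndarray,
                        df: int) -> np.ndarray:
    """Wald Z of each residualized phenotype on each residualized SNP.

    ``gr``/``yr`` are genotype and phenotype matrices with the covariate
    span already projected out; ``gss`` the genotype residual sums of
    squares.  Fast path for repeated scans against a fixed genotype panel.
    """
    yss = np.einsum("ij,ij->j", yr, yr)
    cross = gr.T @ yr
    gss_safe = np.where(gss > 1e-12, gss, np.nan)
    rss = np.clip(yss[None, :] - cross**2 / gss_safe[:, None], 1e-300, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        return cross / np.sqrt(gss_safe[:, None] * rss / df)


def univariate_assoc(panel: GenotypePanel, phenotypes, covariates=None,
                     use_t: bool = True) -> SnpSummaryTable:
    """OLS slope, SE, Wald Z and two-sided p of every phenotype on every SNP.

    An intercept is always included.  Collinear SNPs (residual variance ~0
    after covariate projection) yield NaN statistics rather than an error.
    """
    y = phenotypes.values if hasattr(phenotypes, "values") else np.asarray(phenotypes)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.ndim == 1:
        y = y[:, None]
    g = panel.dosages
    n = g.shape[0]
    if y.shape[0] != n:
        raise ValueError("sample counts of panel and phenotypes differ")

    if covariates is None:
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        design = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(design)
    n_cov = design.shape[1] - 1
    df = n - n_cov - 2
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")

    gr = _residualize(g, q)
    yr = _residualize(y, q)

    gss = np.einsum("ij,ij->j", gr, gr)  # (M,)
    yss = np.einsum("ij,ij->j", yr, yr)  # (K,)
    cross = gr.T @ yr  # (M, K)

    ok = gss > n * 1e-12
    gss_safe = np.where(ok, gss, np.nan)
    beta = cross / gss_safe[:, None]
    rss = yss[None, :] - cross**2 / gss_safe[:, None]
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 / gss_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # underflow-protected
    p[np.isnan(z)] = np.nan  # collinear SNPs; infinite Z (perfect fit) keeps p

    return SnpSummaryTable(
        snp_ids=list(panel.snp_ids),
        chrom=np.repeat(panel.chrom, panel.n_snps),
        pos=panel.positions,
        beta=beta, se=se, z=z, p=p, n_effective=n, maf=panel.maf,
    )


def zscore_correlation(summaries: SnpSummaryTable, pruned_index=None,
                       min_snps: int = 30) -> ZCorrelation:
    """Pearson correlation of per-phenotype Z vectors over pruned null SNPs."""
    z = summaries.z
    if pruned_index is not None:
        z = z[np.asarray(pruned_index)]
    z = z[np.all(np.isfinite(z), axis=1)]
    if z.shape[0] < min_snps:
        raise ValueError(
            f"only {z.shape[0]} usable pruned SNPs (< {min_snps}); "
            "generate a larger null panel")
    return ZCorrelation(R=np.corrcoef(z, rowvar=False), n_snps_used=z.shape[0])


def meta_weighted_z(z, n):
    """Sample-size weighted Z meta-analysis.

    ``Z_meta = sum(w_i z_i) / sqrt(sum(w_i^2))`` with ``w_i = sqrt(n_i)``;
    returns ``(z_meta, p_two_sided)``.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.shape != n.shape:
        raise ValueError("z and n must have equal length")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n)
    z_meta = (w * z).sum(axis=0) / np.sqrt((w**2).sum(axis=0))
    return z_meta, 2.0 * stats.norm.sf(np.abs(z_meta))
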