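"""Gene-level combination of per-SNP p-values: GATES and VEGAS.

GATES is the extended Simes procedure over the SNPs of a gene: with ordered
p-values ``p_(j)`` the gene p is ``min_j m_e p_(j) / m_e(j)``, where the
effective numbers of independent SNPs come from the eigenvalues of the
p-value correlation matrix derived from LD.

VEGAS converts each SNP p to a 1-df chi-square quantile, sums them, and
compares the sum against a Monte-Carlo null obtained by drawing multivariate
normal Z vectors with the gene's LD correlation and summing their squares.
Simulation counts escalate adaptively (10^3 -> 10^4 -> 10^5 -> 10^6 by
default) until the exceedance count is well resolved, mirroring the
published VEGAS strategy; the resolution floor ``1/n_sims`` is recorded
whenever no simulated statistic exceeds the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genosim import (LDMatrix, effective_number_from_pcorr,
                      pvalue_correlation, stabilize_correlation)

__all__ = [
    "GeneDefinition",
    "GeneResult",
    "VegasNull",
    "map_snps_to_gene",
    "gates_combine",
    "vegas_combine",
    "pleiotropy_call",
    "gene_wide_threshold",
]

_P_FLOOR = 1e-300


@dataclass
class GeneDefinition:
    """A gene interval (1-based inclusive) with its SNP-to-gene mapping."""

    gene_id: str
    chrom: str
    start: int
    stop: int
    flank: int = 10_000
    snp_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.stop:
            raise ValueError("gene start must not exceed stop")

    @property
    def window(self) -> tuple[int, int]:
        return (self.start - self.flank, self.stop + self.flank)


@dataclass
class GeneResult:
    gene_id: str
    method_pair: str
    p_gene: float
    m_total: int
    m_e: float | None = None
    n_mc_sims: int | None = None
    mc_exceedances: int | None = None
    floor_hit: bool = False


def map_snps_to_gene(gene: GeneDefinition, summaries, maf_floor: float = 0.01,
                     rsq_floor: float = 0.4, mode: str = "application",
                     rsq=None) -> GeneDefinition:
    """Map SNPs into a gene's flanked window and apply quality filters.

    ``summaries`` provides ``snp_ids``, ``chrom``, ``pos`` and optionally
    ``maf`` (a :class:`~mgba.assoc.SnpSummaryTable` or similar).  In
    ``application`` mode SNPs with MAF <= ``maf_floor`` are removed (and
    SNPs with imputation quality ``rsq`` < ``rsq_floor`` when ``rsq`` is
    given); in ``simulation`` mode SNPs with MAF >= ``maf_floor`` are kept.
    Filters whose metadata are absent are skipped with a warning.
    """
    lo, hi = gene.window
    pos = np.asarray(summaries.pos)
    chrom = np.asarray(summaries.chrom).astype(str)
    keep = (chrom == str(gene.chrom)) & (pos >= lo) & (pos <= hi)

    maf = getattr(summaries, "maf", None)
    if maf is None:
        warnings.warn(f"{gene.gene_id}: no MAF metadata; frequency filter skipped",
                      stacklevel=2)
    elif mode == "application":
        keep &= np.asarray(maf) > maf_floor
    elif mode == "simulation":
        keep &= np.asarray(maf) >= maf_floor
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")

    if mode == "application":
        if rsq is None:
            warnings.warn(
                f"{gene.gene_id}: no imputation-quality metadata; R^2 filter skipped",
                stacklevel=2)
        else:
            keep &= np.asarray(rsq) >= rsq_floor

    ids = [summaries.snp_ids[i] for i in np.flatnonzero(keep)]
    return GeneDefinition(gene_id=gene.gene_id, chrom=gene.chrom,
                          start=gene.start, stop=gene.stop, flank=gene.flank,
                          snp_ids=ids)


def gates_combine(p, ld: LDMatrix, pcorr_method: str = "polynomial",
                  gene_id: str = "", method_pair: str = "gates") -> GeneResult:
    """GATES extended-Simes gene p-value from per-SNP p-values and LD."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    finite = np.isfinite(p)
    if not finite.all():
        p = p[finite]
    if p.size == 0:
        raise ValueError("no usable p-values for gene")
    p = np.clip(p, _P_FLOOR, 1.0)
    r = ld.r if hasattr(ld, "r") else np.asarray(ld)
    if not finite.all():
        r = r[np.ix_(finite, finite)]
    if r.shape[0] != p.size:
        raise ValueError("p-value vector and LD matrix dimensions disagree")
    if p.size == 1:
        return GeneResult(gene_id=gene_id, method_pair=method_pair,
                          p_gene=float(p[0]), m_total=1, m_e=1.0)
    pc = pvalue_correlation(r, method=pcorr_method)
    order = np.argsort(p, kind="stable")
    me_full = effective_number_from_pcorr(pc)
    best = np.inf
    for j in range(1, p.size + 1):
        sub = pc[np.ix_(order[:j], order[:j])]
        me_j = effective_number_from_pcorr(sub)
        best = min(best, me_full * p[order[j - 1]] / me_j)
    return GeneResult(gene_id=gene_id, method_pair=method_pair,
                      p_gene=float(min(best, 1.0)), m_total=int(p.size),
                      m_e=me_full)


class VegasNull:
    """Shared Monte-Carlo null for VEGAS over one gene's LD matrix.

    Caches the Cholesky factor and the simulated null statistics of each
    adaptive stage so several observed statistics (one per multivariate
    method) can be ranked against the same null draws.
    """

    def __init__(self, ld, seed=None):
        r = ld.r if hasattr(ld, "r") else np.asarray(ld, dtype=float)
        r = stabilize_correlation(r)
        try:
            self._chol = np.linalg.cholesky(r)
        except np.linalg.LinAlgError as exc:
            raise ValueError("LD matrix not PSD after stabilization") from exc
        self.m = r.shape[0]
        self._rng = (seed if isinstance(seed, np.random.Generator)
                     else np.random.default_rng(seed))
        self._stats = np.empty(0)

    def stats(self, n_sims: int) -> np.ndarray:
        """Null statistics; extends the cached pool up to ``n_sims`` draws."""
        if n_sims > self._stats.size:
            extra = n_sims - self._stats.size
            block = 200_000  # bound peak memory for large escalations
            chunks = [self._stats]
            done = 0
            while done < extra:
                b = min(block, extra - done)
                z = self._rng.standard_normal((b, self.m)) @ self._chol.T
                chunks.append(np.einsum("ij,ij->i", z, z))
                done += b
            self._stats = np.concatenate(chunks)
        return self._stats[:n_sims]


def vegas_combine(p, ld=None, n_sims: int = 1_000_000, seed=None,
                  null: VegasNull | None = None, gene_id: str = "",
                  method_pair: str = "vegas", strict: bool = False,
                  estimator: str = "raw") -> GeneResult:
    """VEGAS Monte-Carlo sum-of-chi-squares gene p-value.

    ``n_sims`` is the maximum simulation count; stages of 10^3, 10^4, ...
    are run until the exceedance proportion is resolved (at least ~100
    exceedances) or the maximum is reached.  ``strict=True`` counts
    strict exceedance (``>``) instead of the default ``>=``;
    ``estimator="smoothed"`` reports ``(x + 1) / (n + 1)``.
    """
    if n_sims < 1_000:
        raise ValueError("n_sims must be at least 10^3")
    p = np.atleast_1d(np.asarray(p, dtype=float))
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no usable p-values for gene")
    p = np.clip(p, _P_FLOOR, 1.0)
    t_obs = float(stats.chi2.isf(p, df=1).sum())
    if null is None:
        if ld is None:
            raise ValueError("either ld or a VegasNull must be provided")
        null = VegasNull(ld, seed=seed)

    stage = 1_000
    while True:
        sims = null.stats(min(stage, n_sims))
        n_used = sims.size
        exceed = int((sims > t_obs).sum() if strict else (sims >= t_obs).sum())
        # escalate while the exceedance count is too small to resolve p
        if exceed >= 100 or n_used >= n_sims:
            break
        stage *= 10

    if estimator == "smoothed":
        p_gene = (exceed + 1) / (n_used + 1)
        floor = False
    elif estimator == "raw":
        floor = exceed == 0
        p_gene = max(exceed, 1) / n_used  # never report below the resolution
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return GeneResult(gene_id=gene_id, method_pair=method_pair,
                      p_gene=float(p_gene), m_total=int(p.size),
                      n_mc_sims=int(n_used), mc_exceedances=exceed,
                      floor_hit=bool(floor))


def pleiotropy_call(p_multivariate: float, p_univariate) -> bool:
    """True iff the multivariate gene p is at least one order of magnitude
    below every univariate gene p."""
    p_uni = np.atleast_1d(np.asarray(p_univariate, dtype=float))
    if not (0.0 < p_multivariate <= 1.0) or np.any((p_uni <= 0) | (p_uni > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return bool(p_multivariate <= 0.1 * p_uni.min())


def gene_wide_threshold(alpha: float, n_genes: int) -> float:
    """Bonferroni gene-wide significance threshold alpha / n_genes."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    return alpha / n_genes
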