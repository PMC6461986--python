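"""LD-structured common-variant genotype simulation and LD utilities.

Genotypes are generated from a hierarchical Gaussian copula that mimics the
haplotype-block mosaic of real sequence data.  A region is partitioned into
contiguous blocks whose count shrinks as ``ld_strength`` grows; SNPs within
a block are near-duplicates (latent correlation ~0.997) sharing a
block-level allele frequency, while block-level latents carry only a weak
AR(1) correlation (``0.3 * ld_strength`` per adjacent block), mimicking
recombination hotspots that largely decouple neighbouring blocks, so a
causal effect is tagged within its own block but bleeds only mildly into
the rest of the region.  Latent normals are dichotomised at
the quantile of each SNP's target minor-allele frequency to give haplotype
alleles; a genotype is the sum of two independent haplotypes.  A pure
inter-SNP AR(1) decay cannot produce the strong region-wide LD seen in real
genes (the attainable correlation of two Bernoulli variables with different
frequencies is bounded well below 1), whereas block-sharing SNPs with
matched frequencies can, so the block mosaic is what lets the generator
span the full low/moderate/high range of independent-SNP proportions.

The module also provides the LD-aware quantities every gene-based test
downstream needs: the Pearson LD matrix, the eigenvalue-based effective
number of independent SNPs with its low/moderate/high classification,
greedy LD pruning, and principal-component scores for population-structure
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HaplotypePanel",
    "GenotypePanel",
    "LDMatrix",
    "EffectiveSnpCount",
    "generate_haplotypes",
    "generate_region",
    "compute_ld",
    "pvalue_correlation",
    "effective_snp_number",
    "ld_prune",
    "compute_pcs",
    "calibrate_ld_strength",
]

#: coefficients (descending degree, no constant) of the 6th-order polynomial
#: mapping |r| between two SNPs to the correlation of their association
#: p-values, as used by the extended-Simes gene test.
_PCORR_POLY = np.array([0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0])

_MIN_EIGENVALUE = 1e-10


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class HaplotypePanel:
    """Binary haplotypes for ``n`` diploid samples (``2n`` rows)."""

    haplotypes: np.ndarray  # (2n, M) 0/1
    positions: np.ndarray  # (M,) strictly increasing bp coordinates
    maf_target: np.ndarray  # (M,) target allele frequencies

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes)
        self.positions = np.asarray(self.positions)
        self.maf_target = np.asarray(self.maf_target, dtype=float)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even (diploid samples)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def to_genotypes(self, region_id: str = "region") -> "GenotypePanel":
        dos = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypePanel.from_dosages(dos, self.positions, region_id=region_id)


@dataclass
class GenotypePanel:
    """``n x M`` dosage matrix with per-SNP metadata.

    Dosages count copies of the minor allele; columns are oriented so that
    ``maf <= 0.5``.
    """

    dosages: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    region_id: str = "region"
    chrom: str = "1"
    snp_ids: list = field(default_factory=list)

    @classmethod
    def from_dosages(cls, dosages, positions, region_id="region", chrom="1",
                     snp_ids=None) -> "GenotypePanel":
        dosages = np.asarray(dosages, dtype=float)
        positions = np.asarray(positions)
        freq = dosages.mean(axis=0) / 2.0
        flip = freq > 0.5
        if flip.any():
            dosages = dosages.copy()
            dosages[:, flip] = 2.0 - dosages[:, flip]
            freq = np.where(flip, 1.0 - freq, freq)
        if snp_ids is None:
            snp_ids = [f"{region_id}_snp{i}" for i in range(dosages.shape[1])]
        return cls(dosages=dosages, positions=positions, maf=freq,
                   region_id=region_id, chrom=chrom, snp_ids=list(snp_ids))

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            positions=self.positions[idx],
            maf=self.maf[idx],
            region_id=self.region_id,
            chrom=self.chrom,
            snp_ids=[self.snp_ids[i] for i in idx],
        )


@dataclass
class LDMatrix:
    """Pearson correlation of dosage columns, PSD-stabilised."""

    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")

    @property
    def n_snps(self) -> int:
        return self.r.shape[0]


@dataclass
class EffectiveSnpCount:
    m_e: float
    m_total: int
    proportion: float
    class_label: str


def classify_proportion(proportion: float) -> str:
    """Low/moderate/high class of the independent-SNP proportion.

    Boundaries are <40% / 40-60% / >60%.
    """
    if proportion < 0.40:
        return "low"
    if proportion <= 0.60:
        return "moderate"
    return "high"


#: latent correlation of SNPs sharing a haplotype block (near-duplicates
#: separated by occasional historical recombination/genotyping noise).
_WITHIN_BLOCK_RHO = 0.997
#: s.d. of the allele-frequency jitter of SNPs around their block frequency.
_BLOCK_MAF_JITTER = 0.015
#: between-block latent correlation per unit ld_strength (weak leakage
#: across recombination hotspots).
_BETWEEN_BLOCK_SCALE = 0.3


def generate_haplotypes(n_samples, n_snps, ld_strength, maf_law=("uniform", 0.05, 0.5),
                        seed=None, region_length=10_000) -> HaplotypePanel:
    """Draw ``2 * n_samples`` haplotypes over ``n_snps`` SNPs.

    ``maf_law`` is ``("uniform", lo, hi)`` or ``("fixed", value)`` and gives
    the law of the block-level allele frequency; the lower bound must be at
    least 0.01 so that only common variants are emitted.  ``ld_strength = 0``
    gives independent SNPs (one block each); as it approaches 1 the region
    collapses towards a single block of near-duplicate SNPs.
    """
    if n_snps < 20:
        raise ValueError("a simulated region must contain at least 20 SNPs")
    if not (0.0 <= ld_strength < 1.0):
        raise ValueError("ld_strength must lie in [0, 1)")
    rng = _as_rng(seed)

    n_blocks = max(1, round(n_snps * (1.0 - ld_strength)))
    sizes = np.full(n_blocks, n_snps // n_blocks)
    sizes[: n_snps % n_blocks] += 1
    block_of = np.repeat(np.arange(n_blocks), sizes)

    kind = maf_law[0]
    if kind == "uniform":
        lo, hi = maf_law[1], maf_law[2]
        if lo < 0.01:
            raise ValueError("maf_law lower bound must be >= 0.01 (common SNPs only)")
        base = rng.uniform(lo, hi, size=n_blocks)
    elif kind == "fixed":
        lo, hi = 0.01, 0.5
        if maf_law[1] < 0.01:
            raise ValueError("maf_law must be >= 0.01 (common SNPs only)")
        base = np.full(n_blocks, float(maf_law[1]))
    else:
        raise ValueError(f"unknown maf_law kind {kind!r}")
    maf = np.clip(base[block_of] + rng.normal(0.0, _BLOCK_MAF_JITTER, n_snps),
                  max(lo, 0.01), 0.5)

    positions = np.sort(rng.choice(region_length, size=n_snps, replace=False)) + 1

    # Block-level AR(1) latent field, recursively (O(n*B)); the
    # between-block correlation is deliberately weak (recombination
    # hotspots largely decouple adjacent blocks) while ld_strength mainly
    # acts through the block count above.
    rho_b = _BETWEEN_BLOCK_SCALE * ld_strength
    n_hap = 2 * n_samples
    zb = rng.standard_normal((n_hap, n_blocks))
    b = np.empty_like(zb)
    b[:, 0] = zb[:, 0]
    if rho_b > 0 and n_blocks > 1:
        decay = np.sqrt(1.0 - rho_b**2)
        for k in range(1, n_blocks):
            b[:, k] = rho_b * b[:, k - 1] + decay * zb[:, k]
    else:
        b = zb

    eps = rng.standard_normal((n_hap, n_snps))
    lat = (np.sqrt(_WITHIN_BLOCK_RHO) * b[:, block_of]
           + np.sqrt(1.0 - _WITHIN_BLOCK_RHO) * eps)

    thresh = stats.norm.ppf(maf)
    haps = (lat < thresh[None, :]).astype(np.int8)
    return HaplotypePanel(haplotypes=haps, positions=positions, maf_target=maf)


def generate_region(n_samples, n_snps=60, ld_strength=0.0,
                    maf_law=("uniform", 0.05, 0.5), seed=None,
                    region_id="region", region_length=10_000,
                    maf_floor=0.01, max_redraws=10) -> GenotypePanel:
    """Simulate a gene region of common SNPs with tunable LD decay.

    Columns whose empirical MAF falls below ``maf_floor`` (or that are
    monomorphic) are redrawn so the returned panel contains common,
    polymorphic SNPs only; deterministic for a fixed ``seed``.
    """
    rng = _as_rng(seed)
    hap = generate_haplotypes(n_samples, n_snps, ld_strength, maf_law, rng,
                              region_length)
    panel = hap.to_genotypes(region_id=region_id)
    for _ in range(max_redraws):
        bad = panel.maf < maf_floor
        if not bad.any():
            break
        # redraw the whole region rather than patching columns, preserving LD
        hap = generate_haplotypes(n_samples, n_snps, ld_strength, maf_law, rng,
                                  region_length)
        panel = hap.to_genotypes(region_id=region_id)
    else:
        raise RuntimeError("could not generate a panel with all MAF above floor")
    return panel


def stabilize_correlation(r: np.ndarray, min_eig: float = _MIN_EIGENVALUE) -> np.ndarray:
    """Clip negative eigenvalues and renormalise the diagonal to 1."""
    r = np.asarray(r, dtype=float)
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() >= min_eig:
        return r
    w = np.clip(w, min_eig, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def compute_ld(panel: GenotypePanel) -> LDMatrix:
    """Pearson LD matrix of the panel's dosage columns."""
    if panel.n_snps < 2:
        raise ValueError("LD requires at least 2 SNPs")
    sd = panel.dosages.std(axis=0)
    mono = np.flatnonzero(sd == 0)
    if mono.size:
        names = ", ".join(panel.snp_ids[i] for i in mono[:5])
        raise ValueError(f"monomorphic SNP column(s): {names}")
    r = np.corrcoef(panel.dosages, rowvar=False)
    return LDMatrix(r=stabilize_correlation(r))


def pvalue_correlation(r: np.ndarray, method: str = "polynomial") -> np.ndarray:
    """Map an LD (or Z-score) correlation matrix to a p-value correlation matrix.

    ``polynomial`` applies the 6th-order polynomial in |r| used by the
    extended-Simes gene test; ``abs_r`` uses |r| directly.
    """
    a = np.abs(np.asarray(r, dtype=float))
    if method == "polynomial":
        p = np.polyval(_PCORR_POLY, a)
        # identical tests have p-value correlation exactly 1; pin the
        # perfect-LD limit the polynomial only approximates
        p[a > 1.0 - 1e-9] = 1.0
    elif method == "abs_r":
        p = a
    else:
        raise ValueError(f"unknown p-value correlation method {method!r}")
    np.fill_diagonal(p, 1.0)
    return np.clip(p, 0.0, 1.0)


def effective_number_from_pcorr(pcorr: np.ndarray) -> float:
    """m_e = M - sum_i I(lambda_i > 1)(lambda_i - 1) over eigenvalues.

    Only eigenvalues above 1 enter the excess sum, so indefiniteness of a
    noisy correlation matrix cannot change the result and no PSD
    stabilization is needed here.
    """
    w = np.linalg.eigvalsh((pcorr + pcorr.T) / 2.0)
    m = pcorr.shape[0]
    excess = np.clip(w - 1.0, 0.0, None).sum()
    return float(np.clip(m - excess, 1.0, m))


def effective_snp_number(ld: LDMatrix, pcorr_method: str = "polynomial") -> EffectiveSnpCount:
    """Effective number of independent SNPs and its low/moderate/high class."""
    pc = pvalue_correlation(ld.r, method=pcorr_method)
    m_e = effective_number_from_pcorr(pc)
    m = ld.n_snps
    prop = m_e / m
    return EffectiveSnpCount(m_e=m_e, m_total=m, proportion=prop,
                             class_label=classify_proportion(prop))


def ld_prune(panel: GenotypePanel, r2_threshold: float = 0.1, window: int = 50):
    """Greedy windowed LD pruning; returns retained SNP indices.

    SNPs are visited in position order; a SNP is kept iff its r^2 with every
    already-retained SNP within ``window`` SNP indices is at most
    ``r2_threshold``. Deterministic: ties broken by position order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    r2 = compute_ld(panel).r ** 2
    retained: list[int] = []
    for i in range(panel.n_snps):
        ok = True
        for j in reversed(retained):
            if i - j > window:
                break
            if r2[i, j] > r2_threshold:
                ok = False
                break
        if ok:
            retained.append(i)
    return retained


def compute_pcs(panel: GenotypePanel, k: int) -> np.ndarray:
    """Principal-component scores of the column-standardised dosage matrix.

    Ordered by decreasing explained variance; each component's sign is fixed
    so its largest-magnitude SNP loading is positive.
    """
    n, m = panel.dosages.shape
    if k >= min(n, m):
        raise ValueError("k must be smaller than min(n_samples, n_snps)")
    x = panel.dosages - panel.dosages.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic SNP column; filter before PCA")
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[k - 1] <= 1e-12 * s[0]:
        raise ValueError("k exceeds the numerical rank of the panel")
    scores = u[:, :k] * s[:k]
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            scores[:, c] *= -1.0
    return scores


_CLASS_TARGETS = {"low": 0.30, "moderate": 0.50, "high": 0.70}


def calibrate_ld_strength(target, n_samples=2000, n_snps=60,
                          maf_law=("uniform", 0.05, 0.5), n_seeds=50,
                          seed=0, tol=0.02, max_iter=14,
                          pcorr_method="polynomial") -> float:
    """Bisection search for the ``ld_strength`` whose mean independent-SNP
    proportion equals a target.

    ``target`` is either a class label (aimed at the class midpoint: low 0.30,
    moderate 0.50, high 0.70) or a numeric proportion. The realised proportion
    is averaged over ``n_seeds`` independently generated panels.
    """
    if isinstance(target, str):
        if target not in _CLASS_TARGETS:
            raise ValueError(f"unknown LD class {target!r}")
        target = _CLASS_TARGETS[target]
    if not (0.0 < target <= 1.0):
        raise ValueError("target proportion must lie in (0, 1]")

    def mean_prop(strength: float) -> float:
        props = []
        for s in range(n_seeds):
            panel = generate_region(n_samples, n_snps, strength, maf_law,
                                    seed=np.random.default_rng([seed, s, 1]))
            eff = effective_snp_number(compute_ld(panel), pcorr_method)
            props.append(eff.proportion)
        return float(np.mean(props))

    lo, hi = 0.0, 0.999  # proportion decreases in ld_strength
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        p = mean_prop(mid)
        if abs(p - target) < tol:
            return mid
        if p > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
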