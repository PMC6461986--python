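"""Correlated-phenotype simulation under a single-common-factor model.

Three (by default) continuous phenotypes share one latent factor:
``Sigma = Lambda Lambda^T + Theta`` with ``Lambda`` the loading vector and
``Theta`` a diagonal residual covariance.  Causal-SNP effects are added on
top of the multivariate-normal noise as ``Y_k = s_k * sum_i beta_i G_i + eps_k``
for each affected phenotype ``k`` (sign ``s_k``), where each causal SNP's
effect size is chosen so the SNP explains a fixed fraction ``h2`` of unit
phenotypic variance: ``beta_i = sqrt(h2 / (2 MAF_i (1 - MAF_i)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genosim import GenotypePanel, _as_rng

__all__ = [
    "FactorModel",
    "CausalSpec",
    "PhenotypeMatrix",
    "effect_size",
    "simulate_null_phenotypes",
    "simulate_causal_phenotypes",
    "select_causal",
]


@dataclass
class FactorModel:
    """Single-common-factor covariance model for K phenotypes.

    ``sigma`` is reconstructed from ``loading`` and ``residual_var`` on every
    access, so the factor decomposition and the covariance can never drift
    apart.
    """

    loading: np.ndarray  # (K,) factor loadings
    residual_var: np.ndarray  # (K,) diagonal of Theta, all positive

    def __post_init__(self):
        self.loading = np.atleast_1d(np.asarray(self.loading, dtype=float))
        self.residual_var = np.atleast_1d(np.asarray(self.residual_var, dtype=float))
        if self.loading.shape != self.residual_var.shape:
            raise ValueError("loading and residual_var must have equal length")
        if np.any(self.residual_var <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def n_phenotypes(self) -> int:
        return self.loading.size

    @property
    def sigma(self) -> np.ndarray:
        """Implied covariance Sigma = Lambda Lambda^T + Theta."""
        return np.outer(self.loading, self.loading) + np.diag(self.residual_var)

    @property
    def correlation(self) -> np.ndarray:
        s = self.sigma
        d = np.sqrt(np.diag(s))
        return s / np.outer(d, d)

    @classmethod
    def from_loading(cls, loading: float, n_phenotypes: int = 3) -> "FactorModel":
        """Equal loadings with Theta = diag(1 - loading^2): unit total variance."""
        if not (0.0 <= loading < 1.0):
            raise ValueError("loading must lie in [0, 1) under this convention")
        lam = np.full(n_phenotypes, float(loading))
        return cls(loading=lam, residual_var=1.0 - lam**2)

    @classmethod
    def from_target_correlation(cls, loading: float, r: float,
                                n_phenotypes: int = 3) -> "FactorModel":
        """Solve theta = loading^2 (1 - r) / r so pairwise correlation is ``r``.

        Total phenotypic variance is loading^2 / r, not 1.
        """
        if not (0.0 < r < 1.0):
            raise ValueError("target correlation must lie in (0, 1)")
        lam = np.full(n_phenotypes, float(loading))
        theta = loading**2 * (1.0 - r) / r
        return cls(loading=lam, residual_var=np.full(n_phenotypes, theta))

    @classmethod
    def from_loading_matrix(cls, loading: float,
                            n_phenotypes: int = 3) -> "FactorModel":
        """Literal K x K loading-matrix reading: every entry of Lambda equals
        ``loading``, Theta = diag(1 - loading^2).

        Then Sigma = K loading^2 J + diag(1 - loading^2): total variance
        1 + (K-1) loading^2 and pairwise correlation
        K loading^2 / (1 + (K-1) loading^2) — e.g. 0.565 at loading 0.55.
        """
        if not (0.0 <= loading < 1.0):
            raise ValueError("loading must lie in [0, 1)")
        lam = np.full(n_phenotypes, float(loading) * np.sqrt(n_phenotypes))
        theta = np.full(n_phenotypes, 1.0 - float(loading) ** 2)
        return cls(loading=lam, residual_var=theta)

    @classmethod
    def from_correlation(cls, r: float, n_phenotypes: int = 3) -> "FactorModel":
        """Unit-variance exchangeable model with pairwise correlation ``r``:
        loading = sqrt(r), Theta = diag(1 - r)."""
        if not (0.0 <= r < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        lam = np.full(n_phenotypes, float(np.sqrt(r)))
        return cls(loading=lam, residual_var=np.full(n_phenotypes, 1.0 - r))


@dataclass
class CausalSpec:
    """Which SNPs are causal, how strongly, for which phenotypes, which sign."""

    causal_indices: np.ndarray
    h2_per_snp: float = 0.01
    affected_phenotypes: tuple = (0, 1, 2)  # 0-based phenotype indices
    direction_signs: tuple = (1, 1, 1)

    def __post_init__(self):
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        if not (0.0 < self.h2_per_snp < 1.0):
            raise ValueError("h2_per_snp must lie in (0, 1)")
        if any(s not in (-1, 1) for s in self.direction_signs):
            raise ValueError("direction signs must be +1 or -1")


@dataclass
class PhenotypeMatrix:
    values: np.ndarray  # (n, K)
    model: FactorModel
    causal: CausalSpec | None = None
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]


def effect_size(maf: float, h2: float) -> float:
    """Per-SNP additive effect beta = sqrt(h2 / (2 MAF (1 - MAF)))."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must lie strictly between 0 and 1")
    if not (0.0 <= h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    return np.sqrt(h2 / (2.0 * maf * (1.0 - maf)))


def _noise(model: FactorModel, n: int, seed) -> np.ndarray:
    rng = _as_rng(seed)
    sigma = model.sigma
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied Sigma is not positive definite") from exc
    return rng.standard_normal((n, model.n_phenotypes)) @ chol.T


def simulate_null_phenotypes(model: FactorModel, n: int, seed=None) -> PhenotypeMatrix:
    """Draw ``n`` iid samples from N(0, Sigma)."""
    return PhenotypeMatrix(values=_noise(model, n, seed), model=model)


def simulate_causal_phenotypes(panel: GenotypePanel, model: FactorModel,
                               causal: CausalSpec, seed=None) -> PhenotypeMatrix:
    """Add causal genetic effects to factor-model noise.

    The noise component is drawn from the same stream as
    :func:`simulate_null_phenotypes` with the same seed, so toggling causal
    effects changes only the genetic term.
    """
    idx = causal.causal_indices
    if idx.size and (idx.min() < 0 or idx.max() >= panel.n_snps):
        raise ValueError("causal index outside the panel")
    if not causal.affected_phenotypes and idx.size:
        raise ValueError("at least one affected phenotype is required")
    y = _noise(model, panel.n_samples, seed)
    if idx.size:
        beta = effect_size(panel.maf[idx], causal.h2_per_snp)
        genetic = panel.dosages[:, idx] @ beta
        for k in causal.affected_phenotypes:
            y[:, k] += causal.direction_signs[k] * genetic
    return PhenotypeMatrix(values=y, model=model, causal=causal)


def select_causal(panel: GenotypePanel, fraction: float, seed=None,
                  h2_per_snp: float = 0.01, affected_phenotypes=(0, 1, 2),
                  direction_signs=(1, 1, 1)) -> CausalSpec:
    """Uniformly sample ``round(fraction * M)`` causal SNP indices."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    m = round(fraction * panel.n_snps)
    if m == 0:
        raise ValueError("fraction too small: zero causal SNPs")
    rng = _as_rng(seed)
    idx = np.sort(rng.choice(panel.n_snps, size=m, replace=False))
    return CausalSpec(causal_indices=idx, h2_per_snp=h2_per_snp,
                      affected_phenotypes=tuple(affected_phenotypes),
                      direction_signs=tuple(direction_signs))
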