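"""SNP-level multivariate association tests: O'Brien, TATES, MultiPhen.

O'Brien combines the per-phenotype Wald Z scores of a SNP into
``T = (1' R^-1 z) / sqrt(1' R^-1 1)`` with ``R`` the phenotype (Z-score)
correlation; ``T`` is standard normal under the null.

TATES applies the extended Simes procedure across phenotypes: the ordered
p-values ``p_(j)`` are combined as ``min_j m_e * p_(j) / m_e(j)`` where the
effective numbers come from the correlation matrix of the per-phenotype
p-values.  That p-value correlation is estimated by Monte Carlo by default
(seeded and cached per phenotype-correlation matrix) or by the same
6th-order polynomial in |r| used for SNPs.

MultiPhen inverts the regression: the ordinal genotype (0/1/2 minor-allele
dosage) is the outcome of a proportional-odds model with the phenotypes
(plus covariates) as predictors, tested against the covariates-only model
by a likelihood-ratio test with K degrees of freedom.  The proportional-odds
likelihood is maximised by Newton iteration with analytic gradient and
Hessian; covariates enter both the null and the alternative model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import expit

from .genosim import (effective_number_from_pcorr, pvalue_correlation,
                      stabilize_correlation)

__all__ = [
    "MultivariateSnpResult",
    "obrien_test",
    "obrien_batch",
    "tates_test",
    "tates_batch",
    "tates_pvalue_correlation",
    "multiphen_test",
    "multiphen_batch",
]

_P_FLOOR = 1e-300


@dataclass
class MultivariateSnpResult:
    snp_id: str
    method: str
    statistic: float
    p: float
    df_or_me: float
    n_effective: int = 0
    converged: bool = True


# ---------------------------------------------------------------- O'Brien

def obrien_batch(z: np.ndarray, R) -> tuple[np.ndarray, np.ndarray]:
    """Combined Z and two-sided p for each row of ``z`` (M x K)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    r = R.R if hasattr(R, "R") else np.asarray(R, dtype=float)
    k = r.shape[0]
    if z.shape[1] != k:
        raise ValueError("Z vector length does not match R")
    ones = np.ones(k)
    try:
        ri1 = np.linalg.solve(r, ones)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phenotype correlation matrix is singular") from exc
    denom = ones @ ri1
    if denom <= 0:
        raise ValueError("phenotype correlation matrix is not positive definite")
    t = z @ ri1 / np.sqrt(denom)
    p = 2.0 * stats.norm.sf(np.abs(t))
    return t, np.clip(p, _P_FLOOR, 1.0)


def obrien_test(z, R, snp_id: str = "") -> MultivariateSnpResult:
    """O'Brien combined-Z test for one SNP."""
    t, p = obrien_batch(np.atleast_2d(z), R)
    k = len(np.atleast_1d(z))
    return MultivariateSnpResult(snp_id=snp_id, method="obrien",
                                 statistic=float(t[0]), p=float(p[0]),
                                 df_or_me=float(k))


# ------------------------------------------------------------------ TATES

_MC_CACHE: dict = {}


def tates_pvalue_correlation(pheno_corr: np.ndarray, method: str = "mc",
                             n_mc: int = 100_000, seed: int = 0,
                             cache: dict | None = None) -> np.ndarray:
    """Correlation matrix of per-phenotype two-sided p-values.

    ``mc`` simulates ``n_mc`` null Z vectors with the given phenotype
    correlation (seeded; cached on the correlation rounded to 2 decimals);
    ``polynomial`` applies the |r| polynomial mapping directly.
    """
    r = stabilize_correlation(np.asarray(pheno_corr, dtype=float))
    if method == "polynomial":
        return pvalue_correlation(r)
    if method != "mc":
        raise ValueError(f"unknown p-value correlation method {method!r}")
    if cache is None:
        cache = _MC_CACHE
    # round the correlation for both the cache key and the simulation, so a
    # cache hit and a recomputation give identical results
    r_use = stabilize_correlation(np.round(r, 2))
    key = (r_use.tobytes(), n_mc, seed)
    if key in cache:
        return cache[key]
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(r_use)
    z = rng.standard_normal((n_mc, r_use.shape[0])) @ chol.T
    p = 2.0 * stats.norm.sf(np.abs(z))
    pc = stabilize_correlation(np.corrcoef(p, rowvar=False))
    cache[key] = pc
    return pc


def _extended_simes(p: np.ndarray, pcorr: np.ndarray,
                    subset_me: dict | None = None) -> tuple[float, float]:
    """min_j m_e p_(j) / m_e(j); returns (combined p, full m_e)."""
    order = np.argsort(p, kind="stable")
    if subset_me is not None:
        me_full = subset_me[frozenset(range(p.size))]
        me_top = [subset_me[frozenset(order[:j])] for j in range(1, p.size + 1)]
    else:
        me_full = effective_number_from_pcorr(pcorr)
        me_top = []
        for j in range(1, p.size + 1):
            sub = pcorr[np.ix_(order[:j], order[:j])]
            me_top.append(effective_number_from_pcorr(sub))
    vals = me_full * p[order] / np.asarray(me_top)
    return float(min(vals.min(), 1.0)), float(me_full)


def tates_test(p, pheno_corr, pcorr_method: str = "mc", n_mc: int = 100_000,
               seed: int = 0, snp_id: str = "",
               cache: dict | None = None) -> MultivariateSnpResult:
    """Extended Simes combination of one SNP's per-phenotype p-values."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any(p <= 0):
        warnings.warn("p-value of 0 clamped to floor", stacklevel=2)
        p = np.clip(p, _P_FLOOR, 1.0)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return MultivariateSnpResult(snp_id=snp_id, method="tates",
                                     statistic=float(p[0]), p=float(p[0]),
                                     df_or_me=1.0)
    pc = tates_pvalue_correlation(pheno_corr, pcorr_method, n_mc, seed, cache)
    combined, me = _extended_simes(p, pc)
    return MultivariateSnpResult(snp_id=snp_id, method="tates",
                                 statistic=combined, p=combined, df_or_me=me)


def tates_batch(p_matrix: np.ndarray, pheno_corr, pcorr_method: str = "mc",
                n_mc: int = 100_000, seed: int = 0,
                cache: dict | None = None) -> np.ndarray:
    """TATES p for each row of an (M x K) p-value matrix.

    Effective numbers of every phenotype subset are precomputed once (K is
    small), so the per-SNP work is an argsort and a lookup.
    """
    p_matrix = np.atleast_2d(np.asarray(p_matrix, dtype=float))
    p_matrix = np.clip(p_matrix, _P_FLOOR, 1.0)
    k = p_matrix.shape[1]
    if k == 1:
        return p_matrix[:, 0].copy()
    pc = tates_pvalue_correlation(pheno_corr, pcorr_method, n_mc, seed, cache)
    subset_me = {}
    for size in range(1, k + 1):
        for comb in combinations(range(k), size):
            idx = np.array(comb)
            subset_me[frozenset(comb)] = effective_number_from_pcorr(
                pc[np.ix_(idx, idx)])
    out = np.empty(p_matrix.shape[0])
    for i in range(p_matrix.shape[0]):
        out[i], _ = _extended_simes(p_matrix[i], pc, subset_me)
    return out


# --------------------------------------------------------------- MultiPhen

def _ordinal_cut_values(theta, slices, x, j_levels):
    """Per-observation logistic CDF/pdf values at the upper and lower cuts.

    Observations are pre-sorted by category so each category is a contiguous
    slice.  ``theta`` = (alpha_1..alpha_{J-1}, b); cumulative logits
    P(code <= j) = expit(alpha_{j+1} - x b).
    """
    n, p = x.shape
    n_cut = j_levels - 1
    alpha = theta[:n_cut]
    eta = x @ theta[n_cut:] if p else np.zeros(n)

    f_up = np.ones(n)
    f_lo = np.zeros(n)
    for j in range(j_levels):
        sl = slices[j]
        if j < n_cut:
            f_up[sl] = expit(alpha[j] - eta[sl])
        if j > 0:
            f_lo[sl] = expit(alpha[j - 1] - eta[sl])
    return f_up, f_lo


def _ordinal_loglik_parts(theta, slices, x, j_levels, ll_only=False):
    """Log-likelihood (and optionally gradient/Hessian) of the model."""
    n, p = x.shape
    n_cut = j_levels - 1
    f_up, f_lo = _ordinal_cut_values(theta, slices, x, j_levels)
    pi = f_up - f_lo
    if np.any(pi <= 0):
        return -np.inf, None, None
    ll = float(np.log(pi).sum())
    if ll_only:
        return ll, None, None

    d_up = f_up * (1 - f_up)
    d_lo = f_lo * (1 - f_lo)
    # the top category's f_up is exactly 1 and the bottom's f_lo exactly 0,
    # so their densities and density derivatives vanish automatically
    dd_up = d_up * (1 - 2 * f_up)
    dd_lo = d_lo * (1 - 2 * f_lo)

    w_up = d_up / pi
    w_lo = d_lo / pi
    g_eta = -(w_up - w_lo)

    haa = dd_up / pi - w_up**2
    hcc = -dd_lo / pi - w_lo**2
    hac = w_up * w_lo
    h_eta = haa + hcc + 2 * hac

    m_par = n_cut + p
    grad = np.zeros(m_par)
    hess = np.zeros((m_par, m_par))
    for j in range(j_levels):
        sl = slices[j]
        if j < n_cut:  # alpha_{j+1} is this category's upper cut -> index j
            grad[j] += w_up[sl].sum()
            hess[j, j] += haa[sl].sum()
            if p:
                hb = -(haa[sl] + hac[sl]) @ x[sl]
                hess[j, n_cut:] += hb
                hess[n_cut:, j] += hb
        if j > 0:  # alpha_j is the lower cut -> index j-1
            grad[j - 1] -= w_lo[sl].sum()
            hess[j - 1, j - 1] += hcc[sl].sum()
            if p:
                hb = -(hcc[sl] + hac[sl]) @ x[sl]
                hess[j - 1, n_cut:] += hb
                hess[n_cut:, j - 1] += hb
        if 0 < j < n_cut:  # both cuts finite: cross term alpha_j, alpha_{j+1}
            hess[j - 1, j] += hac[sl].sum()
            hess[j, j - 1] += hac[sl].sum()
    if p:
        grad[n_cut:] = x.T @ g_eta
        hess[n_cut:, n_cut:] = (x * h_eta[:, None]).T @ x
    return ll, grad, hess


def _fit_ordinal(codes: np.ndarray, x: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-10):
    """Newton fit of the proportional-odds model; returns (loglik, theta, ok)."""
    n = codes.size
    j_levels = int(codes.max()) + 1
    n_cut = j_levels - 1
    order = np.argsort(codes, kind="stable")
    xs = np.ascontiguousarray(x[order])
    counts = np.bincount(codes, minlength=j_levels).astype(float)
    bounds = np.concatenate([[0], np.cumsum(counts).astype(int)])
    slices = [slice(bounds[j], bounds[j + 1]) for j in range(j_levels)]
    cum = np.cumsum(counts)[:-1] / n
    alpha0 = np.log(cum / (1 - cum))
    theta = np.concatenate([alpha0, np.zeros(x.shape[1])])

    if x.shape[1] == 0:
        # intercept-only model: category probabilities are fitted exactly
        ll = float((counts * np.log(counts / n)).sum())
        return ll, theta, True

    ll, grad, hess = _ordinal_loglik_parts(theta, slices, xs, j_levels)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return ll, theta, False
        shrink = 0
        while True:
            new = theta - step
            # evaluate the full parts so an accepted point needs no re-eval
            ll_new, g_new, h_new = _ordinal_loglik_parts(new, slices, xs,
                                                         j_levels)
            if (np.isfinite(ll_new) and ll_new >= ll - 1e-12
                    and not np.any(np.diff(new[:n_cut]) <= 0)):
                break
            step *= 0.5
            shrink += 1
            if shrink >= 30:
                return ll, theta, False
        delta = ll_new - ll
        theta, ll, grad, hess = new, ll_new, g_new, h_new
        if abs(delta) < tol and np.max(np.abs(grad)) < 1e-6:
            return ll, theta, True
    return ll, theta, False


def _prepare_ordinal_outcome(genotype: np.ndarray) -> np.ndarray:
    g = np.asarray(genotype, dtype=float)
    if np.any(np.abs(g - np.round(g)) > 1e-8):
        warnings.warn("non-integer dosages rounded to nearest genotype",
                      stacklevel=3)
    g = np.round(g)
    levels = np.unique(g)
    if levels.size < 2:
        raise ValueError("monomorphic genotype: ordinal regression undefined")
    codes = np.searchsorted(levels, g)
    return codes.astype(np.intp)


def multiphen_test(genotype, phenotypes, covariates=None,
                   snp_id: str = "") -> MultivariateSnpResult:
    """MultiPhen reverse ordinal regression LRT for one SNP.

    Complete cases only: rows with any missing genotype, phenotype or
    covariate value are dropped before fitting (this is what shrinks
    MultiPhen's effective sample size relative to summary-statistic methods).
    """
    y = phenotypes.values if hasattr(phenotypes, "values") else np.asarray(phenotypes)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    g = np.asarray(genotype, dtype=float)
    cols = [g[:, None], y]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        cols.append(covariates)
    complete = np.all(np.isfinite(np.column_stack(cols)), axis=1)
    g, y = g[complete], y[complete]
    cov = covariates[complete] if covariates is not None else np.empty((g.size, 0))

    codes = _prepare_ordinal_outcome(g)
    k = y.shape[1]
    # standardise predictors for Newton stability; the LRT is invariant
    def _std(m):
        if m.shape[1] == 0:
            return m
        mu, sd = m.mean(axis=0), m.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (m - mu) / sd

    x_full = np.column_stack([_std(y), _std(cov)])
    x_null = _std(cov)

    ll_full, _, ok_full = _fit_ordinal(codes, x_full)
    ll_null, _, ok_null = _fit_ordinal(codes, x_null)
    converged = ok_full and ok_null
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(stats.chi2.sf(lrt, k)) if k else 1.0
    if not converged:
        p = np.nan
    return MultivariateSnpResult(snp_id=snp_id, method="multiphen",
                                 statistic=lrt, p=max(p, _P_FLOOR) if np.isfinite(p) else p,
                                 df_or_me=float(k), n_effective=int(codes.size),
                                 converged=converged)


def multiphen_batch(panel, phenotypes, covariates=None) -> np.ndarray:
    """MultiPhen p-value per SNP of a panel (NaN where the fit failed)."""
    out = np.empty(panel.n_snps)
    for j in range(panel.n_snps):
        try:
            res = multiphen_test(panel.dosages[:, j], phenotypes, covariates,
                                 snp_id=panel.snp_ids[j])
            out[j] = res.p
        except ValueError:
            out[j] = np.nan
    return out
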