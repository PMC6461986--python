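"""Scenario orchestration: type I error and power experiments.

A scenario fixes the study conditions — sample size, region size, LD class,
factor loading (equivalently phenotype correlation), causal fraction,
effect direction, number of affected phenotypes — and a replicate runs the
whole pipeline once: simulate a region, compute principal components, run
the PC-adjusted univariate GWAS, combine per-SNP statistics with the three
multivariate tests (O'Brien, TATES, MultiPhen), and collapse each test's
per-SNP p-values into gene p-values with GATES and VEGAS, yielding six gene
p-values per replicate.  Rejection rates are tabulated per nominal alpha
and per *realized* independent-SNP class, because LD class is a property of
the generated region, not of the generator knob.

Scenarios read the factor loading literally as a K x K matrix with every
entry equal to the stated value and residual variances 1 - loading^2, so
Sigma = K loading^2 J + diag(1 - loading^2).  The canonical loadings
0.15/0.35/0.55/0.75 then realize pairwise phenotype correlations of about
0.07/0.30/0.57/0.79 (0.57 at loading 0.55, the anchor every power scenario
uses) and total phenotypic variance 1 + 2 loading^2.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import genosim, phenosim, mvtests, genetests
from .assoc import ZCorrelation, univariate_assoc, wald_z_residualized

__all__ = [
    "ScenarioConfig",
    "SharedState",
    "LOADING_TO_CORRELATION",
    "prepare_shared",
    "run_replicate",
    "estimate_rejection",
    "rejection_table",
    "make_fixture",
    "METHOD_PAIRS",
]

logger = logging.getLogger("mgba")

METHOD_PAIRS = [
    "obrien_gates", "obrien_vegas",
    "tates_gates", "tates_vegas",
    "multiphen_gates", "multiphen_vegas",
]


@dataclass
class ScenarioConfig:
    """All simulation knobs of one scenario.

    ``causal_fraction = 0`` is type-I-error mode.  ``phenotype_correlation``
    defaults to the canonical loading map; setting it explicitly overrides
    the loading.
    """

    n_samples: int = 2000
    n_snps: int = 60
    n_phenotypes: int = 3
    loading: float = 0.55
    phenotype_correlation: float | None = None
    causal_fraction: float = 0.0
    h2_per_snp: float = 0.01
    direction_signs: tuple = (1, 1, 1)
    n_affected_phenotypes: int = 3
    ld_class: str = "low"
    ld_strength: float | None = None
    alpha_levels: tuple = (0.01, 0.001, 0.0001)
    n_replicates: int = 2000
    master_seed: int = 0
    n_pcs: int = 3
    n_null_snps: int = 5000
    vegas_max_sims: int = 1_000_000
    tates_mc_sims: int = 100_000
    calibration_seeds: int = 50
    maf_law: tuple = ("uniform", 0.05, 0.5)

    def factor_model(self) -> phenosim.FactorModel:
        if self.phenotype_correlation is not None:
            return phenosim.FactorModel.from_correlation(
                float(self.phenotype_correlation), self.n_phenotypes)
        return phenosim.FactorModel.from_loading_matrix(
            float(self.loading), self.n_phenotypes)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        for key in ("direction_signs", "alpha_levels", "maf_law"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("direction_signs", "alpha_levels", "maf_law"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SharedState:
    """Per-scenario state reused across replicates.

    ``pcs`` are the principal components of the genome-wide-like null panel
    (the analogue of genome-wide ancestry PCs): they are the covariates of
    every regression, and being computed away from the test region they do
    not absorb the region's own LD structure.  ``null_gr``/``null_gss`` hold
    the null panel residualized against the PC design for fast per-replicate
    Z-score scans.
    """

    ld_strength: float
    null_panel: genosim.GenotypePanel
    model: phenosim.FactorModel
    pcs: np.ndarray
    design_q: np.ndarray  # orthonormal basis of [1, pcs]
    null_gr: np.ndarray
    null_gss: np.ndarray
    tates_cache: dict = field(default_factory=dict)


_CALIBRATION_CACHE: dict = {}


def prepare_shared(config: ScenarioConfig) -> SharedState:
    """Calibrate the LD class and build the fixed null SNP panel."""
    if config.ld_strength is not None:
        strength = float(config.ld_strength)
    else:
        key = (config.ld_class, config.n_samples, config.n_snps,
               config.maf_law, config.calibration_seeds)
        if key not in _CALIBRATION_CACHE:
            logger.info("calibrating ld_strength for class %r", config.ld_class)
            _CALIBRATION_CACHE[key] = genosim.calibrate_ld_strength(
                config.ld_class, n_samples=config.n_samples,
                n_snps=config.n_snps, maf_law=config.maf_law,
                n_seeds=config.calibration_seeds, seed=1_000_003)
        strength = _CALIBRATION_CACHE[key]
        logger.info("ld_strength = %.4f", strength)
    # independent null SNPs standing in for a genome-wide LD-pruned set;
    # they feed the O'Brien Z-score correlation estimate
    null_panel = genosim.generate_region(
        config.n_samples, config.n_null_snps, ld_strength=0.0,
        maf_law=config.maf_law,
        seed=np.random.default_rng([config.master_seed, 999_983]),
        region_id="null_panel", region_length=max(20_000, 4 * config.n_null_snps))
    pcs = genosim.compute_pcs(null_panel, config.n_pcs)
    design = np.column_stack([np.ones(config.n_samples), pcs])
    q, _ = np.linalg.qr(design)
    gr = null_panel.dosages - q @ (q.T @ null_panel.dosages)
    gss = np.einsum("ij,ij->j", gr, gr)
    return SharedState(ld_strength=strength, null_panel=null_panel,
                       model=config.factor_model(), pcs=pcs, design_q=q,
                       null_gr=gr, null_gss=gss)


def run_replicate(config: ScenarioConfig, replicate_index: int,
                  shared: SharedState | None = None) -> dict:
    """One full simulation replicate; returns the six gene p-values plus the
    realized effective-SNP accounting.

    Deterministic in ``(config.master_seed, replicate_index)`` regardless of
    execution order across replicates.
    """
    if shared is None:
        shared = prepare_shared(config)
    seed_of = lambda k: np.random.default_rng(
        [config.master_seed, replicate_index, k])

    panel = genosim.generate_region(
        config.n_samples, config.n_snps, shared.ld_strength,
        maf_law=config.maf_law, seed=seed_of(0))
    pcs = shared.pcs

    if config.causal_fraction > 0:
        causal = phenosim.select_causal(
            panel, config.causal_fraction, seed=seed_of(2),
            h2_per_snp=config.h2_per_snp,
            affected_phenotypes=tuple(range(config.n_affected_phenotypes)),
            direction_signs=tuple(config.direction_signs))
        phenos = phenosim.simulate_causal_phenotypes(panel, shared.model,
                                                     causal, seed=seed_of(1))
    else:
        phenos = phenosim.simulate_null_phenotypes(shared.model,
                                                   config.n_samples,
                                                   seed=seed_of(1))

    region_sum = univariate_assoc(panel, phenos, covariates=pcs)
    y = phenos.values
    k = y.shape[1]
    yr = y - shared.design_q @ (shared.design_q.T @ y)
    null_z = wald_z_residualized(shared.null_gr, yr, shared.null_gss,
                                 df=config.n_samples - config.n_pcs - 2)
    ok_rows = np.all(np.isfinite(null_z), axis=1)
    if k == 1:
        r_z = ZCorrelation(R=np.eye(1), n_snps_used=int(ok_rows.sum()))
        pheno_corr = np.eye(1)
    else:
        r_z = ZCorrelation(R=np.corrcoef(null_z[ok_rows], rowvar=False),
                           n_snps_used=int(ok_rows.sum()))
        pheno_corr = np.corrcoef(y, rowvar=False)

    _, p_obrien = mvtests.obrien_batch(region_sum.z, r_z)
    p_tates = mvtests.tates_batch(region_sum.p, pheno_corr,
                                  n_mc=config.tates_mc_sims,
                                  cache=shared.tates_cache)
    p_multiphen = mvtests.multiphen_batch(panel, phenos, covariates=pcs)

    ld = genosim.compute_ld(panel)
    eff = genosim.effective_snp_number(ld)
    pool = genetests.VegasNull(ld, seed=seed_of(3))

    out = {"replicate": replicate_index,
           "m_e": eff.m_e, "m_total": eff.m_total,
           "proportion_independent": eff.proportion,
           "ld_class": eff.class_label}
    for name, p_snp in (("obrien", p_obrien), ("tates", p_tates),
                        ("multiphen", p_multiphen)):
        gates = genetests.gates_combine(p_snp, ld)
        vegas = genetests.vegas_combine(p_snp, null=pool,
                                        n_sims=config.vegas_max_sims)
        out[f"{name}_gates"] = gates.p_gene
        out[f"{name}_vegas"] = vegas.p_gene
    return out


def estimate_rejection(config: ScenarioConfig, n_jobs: int = 1,
                       shared: SharedState | None = None) -> pd.DataFrame:
    """Run all replicates and return the replicate-level results table.

    Failed replicates are excluded with a log entry; the count is carried in
    ``df.attrs['n_failed']``.
    """
    if config.n_replicates < 100:
        raise ValueError("at least 100 replicates are required")
    if shared is None:
        shared = prepare_shared(config)
    rows, n_failed = [], 0
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(
            delayed(_safe_replicate)(config, i, shared)
            for i in range(config.n_replicates))
    else:
        results = [_safe_replicate(config, i, shared)
                   for i in range(config.n_replicates)]
    for res in results:
        if res is None:
            n_failed += 1
        else:
            rows.append(res)
    if n_failed:
        logger.warning("%d replicate(s) failed and were excluded", n_failed)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


def _safe_replicate(config, i, shared):
    try:
        return run_replicate(config, i, shared)
    except Exception:
        logger.exception("replicate %d failed", i)
        return None


def rejection_table(replicates: pd.DataFrame, alpha_levels=(0.01, 0.001, 0.0001),
                    by_class: bool = True, min_cell: int = 50) -> pd.DataFrame:
    """Rejection rates with exact binomial 95% CIs per method pair, alpha and
    realized LD class."""
    groups = (replicates.groupby("ld_class") if by_class
              else [("all", replicates)])
    rows = []
    for label, grp in groups:
        for pair in METHOD_PAIRS:
            if pair not in grp.columns:
                continue
            p = grp[pair].to_numpy()
            p = p[np.isfinite(p)]
            n = p.size
            for alpha in alpha_levels:
                x = int((p <= alpha).sum())
                lo = stats.beta.ppf(0.025, x, n - x + 1) if x > 0 else 0.0
                hi = (stats.beta.ppf(0.975, x + 1, n - x)
                      if x < n else 1.0)
                rows.append({"ld_class": label, "method_pair": pair,
                             "alpha": alpha, "n_replicates": n,
                             "n_reject": x, "rate": x / n if n else np.nan,
                             "ci_low": lo, "ci_high": hi,
                             "low_count": n < min_cell})
    return pd.DataFrame(rows)


def make_fixture(kind: str, seed: int, outdir) -> dict:
    """Write a small on-disk data bundle for unit tests and CLI smoke runs.

    Kinds: ``toy-region``, ``null-gwas``, ``power-gwas``,
    ``application-like``.  Returns the mapping of role -> written path.
    """
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict = {}

    if kind == "toy-region":
        panel = genosim.generate_region(200, 20, 0.6, seed=rng)
        model = phenosim.FactorModel.from_correlation(0.3)
        phenos = phenosim.simulate_null_phenotypes(model, 200, seed=rng)
        gene = genetests.GeneDefinition("toyGene", panel.chrom,
                                        int(panel.positions[0]),
                                        int(panel.positions[-1]))
        mio.write_vcf(panel, outdir / "toy.vcf")
        mio.write_dosage_tsv(panel, outdir / "toy_dosages.tsv")
        mio.write_phenotypes_tsv(phenos, outdir / "toy_phenotypes.tsv")
        mio.write_bed([gene], outdir / "toy_genes.bed")
        paths = {"vcf": outdir / "toy.vcf",
                 "dosages": outdir / "toy_dosages.tsv",
                 "phenotypes": outdir / "toy_phenotypes.tsv",
                 "genes": outdir / "toy_genes.bed"}
    elif kind in ("null-gwas", "power-gwas"):
        panel = genosim.generate_region(400, 400, 0.0, seed=rng,
                                        region_length=40_000)
        model = phenosim.FactorModel.from_correlation(0.3)
        if kind == "power-gwas":
            causal = phenosim.select_causal(panel, 0.05, seed=rng,
                                            h2_per_snp=0.02)
            phenos = phenosim.simulate_causal_phenotypes(panel, model, causal,
                                                         seed=rng)
        else:
            phenos = phenosim.simulate_null_phenotypes(model, 400, seed=rng)
        summ = univariate_assoc(panel, phenos)
        mio.write_summary_tsv(summ, outdir / f"{kind}.sumstats.tsv")
        paths = {"sumstats": outdir / f"{kind}.sumstats.tsv"}
    elif kind == "application-like":
        panel = genosim.generate_region(300, 90, 0.7, seed=rng,
                                        region_length=30_000)
        model = phenosim.FactorModel.from_correlation(0.5)
        phenos = phenosim.simulate_null_phenotypes(model, 300, seed=rng)
        summ = univariate_assoc(panel, phenos)
        genes = [
            genetests.GeneDefinition("geneA", panel.chrom, 1, 8_000),
            genetests.GeneDefinition("geneB", panel.chrom, 9_000, 16_000),
            genetests.GeneDefinition("geneC", panel.chrom, 15_000, 22_000),
        ]
        mio.write_vcf(panel, outdir / "app.vcf")
        mio.write_summary_tsv(summ, outdir / "app.sumstats.tsv")
        mio.write_bed(genes, outdir / "app_genes.bed")
        paths = {"vcf": outdir / "app.vcf",
                 "sumstats": outdir / "app.sumstats.tsv",
                 "genes": outdir / "app_genes.bed"}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
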