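# mgba — multivariate gene-based association testing

Complex diseases are usually tracked by several correlated phenotypes
(for Alzheimer neuropathology: neuritic plaques, neurofibrillary tangles,
cerebral amyloid angiopathy), and risk genes often contain several weakly
associated common SNPs. Neither a univariate SNP test nor a single-trait
gene test sees the whole picture. `mgba` implements the six pipelines you
get by crossing three multivariate SNP-level tests with two gene-based
p-value combiners, plus the simulation machinery to measure each
pairing's type I error and power:

| SNP-level multivariate test | gene-level combiner |
|---|---|
| O'Brien combined Z: `T = (1'R⁻¹z)/√(1'R⁻¹1)` | GATES (extended Simes): `P = min_j m_e·p₍ⱼ₎/m_e(j)` |
| TATES (extended Simes across phenotypes) | VEGAS (Monte-Carlo sum of 1-df chi-squares under MVN(0, LD)) |
| MultiPhen (proportional-odds regression of genotype on phenotypes, K-df LRT) | |

The effective number of independent SNPs,
`m_e = M − Σᵢ I(λᵢ>1)(λᵢ−1)` over eigenvalues of the p-value correlation
matrix, drives both Simes procedures and the classification of gene
regions into low (<40%), moderate (40–60%) and high (>60%) independence.

The package also ships:

- a haplotype-block genotype simulator (Gaussian copula; block count
  controlled by `ld_strength`, calibrated by bisection to hit a requested
  independence class) emulating ~60 common SNPs (MAF ≥ 1%) per 10-kb
  region for n = 2000 samples;
- a single-common-factor phenotype simulator, `Σ = ΛΛᵀ + Θ`, with causal
  SNP effects `βᵢ = √(h²/(2·MAFᵢ(1−MAFᵢ)))` (h² = 1% per SNP), direction
  flips and partial-phenotype effects;
- sample-size-weighted Z meta-analysis, SNP↔gene window mapping with
  MAF/imputation-quality filters, the order-of-magnitude pleiotropy rule,
  and minimal VCF / dosage-TSV / BED / summary-TSV IO.

## Worked example

```python
import numpy as np
from mgba import genosim, phenosim, mvtests, genetests
from mgba.assoc import univariate_assoc, zscore_correlation

# a 2000-sample, 60-SNP region in strong LD, plus three phenotypes
# correlated at ~0.57 through one latent factor
panel = genosim.generate_region(2000, 60, ld_strength=0.9, seed=7)
model = phenosim.FactorModel.from_loading_matrix(0.55)
causal = phenosim.select_causal(panel, fraction=0.15, seed=7)
phenos = phenosim.simulate_causal_phenotypes(panel, model, causal, seed=7)

summ = univariate_assoc(panel, phenos)                  # 60 x 3 Wald scans
null_panel = genosim.generate_region(2000, 5000, 0.0, seed=8,
                                     region_length=20000)
r_z = zscore_correlation(univariate_assoc(null_panel, phenos))
t, p_obrien = mvtests.obrien_batch(summ.z, r_z)         # per-SNP combined Z

ld = genosim.compute_ld(panel)
eff = genosim.effective_snp_number(ld)
gates = genetests.gates_combine(p_obrien, ld)
vegas = genetests.vegas_combine(p_obrien, ld, n_sims=10**5, seed=9)
print(f"m_e = {eff.m_e:.1f}/60 ({eff.proportion:.0%}, {eff.class_label})")
print(f"O'Brien+GATES gene p = {gates.p_gene:.3g}")
print(f"O'Brien+VEGAS gene p = {vegas.p_gene:.3g} "
      f"(floor hit: {vegas.floor_hit})")
```

prints

```
m_e = 16.9/60 (28%, low)
O'Brien+GATES gene p = 9.68e-48
O'Brien+VEGAS gene p = 1e-05 (floor hit: True)
```

Nine causal SNPs at h² = 1% each are an overwhelming gene-level signal:
GATES reports the tiny analytic Simes p while VEGAS bottoms out at its
Monte-Carlo resolution `1/n_sims` and flags the floor. The region's 60
SNPs behave like ~17 independent ones ("low" class), the regime where
multivariate gene tests gain the most.

The same pipelines run from the shell:

```bash
mgba simulate-type1 --config scenario.yaml --out type1.tsv
mgba simulate-power --config scenario.yaml --out power.tsv
mgba test --sumstats s.tsv --genotypes ref.vcf --genes genes.bed \
     --methods obrien-vegas,tates-gates --out genes.tsv
mgba meta --inputs a.tsv --inputs b.tsv --out meta.tsv
```

`scenario.yaml` holds the `ScenarioConfig` fields (sample size, loading,
causal fraction, direction signs, LD class, replicate count, seed, ...);
`ScenarioConfig.to_yaml()` writes a template.

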