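"""Readers and writers for the formats the pipelines consume.

Genotypes travel as minimal VCF (GT or DS) or as a plain TSV dosage matrix
(samples x SNPs, header row of SNP ids); genes as BED (0-based half-open on
disk, converted to 1-based inclusive internally, matching VCF coordinates);
per-SNP summary statistics and phenotypes as TSV.  All TSV readers are
gzip-transparent through pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import SnpSummaryTable
from .genosim import GenotypePanel
from .genetests import GeneDefinition
from .phenosim import PhenotypeMatrix

__all__ = [
    "write_vcf", "read_vcf",
    "write_dosage_tsv", "read_dosage_tsv",
    "read_bed", "write_bed",
    "write_summary_tsv", "read_summary_tsv",
    "write_phenotypes_tsv", "read_phenotypes_tsv",
    "write_gene_results_tsv",
]


def write_vcf(panel: GenotypePanel, path, sample_prefix: str = "s") -> None:
    """Write a panel as a minimal VCF with GT (hard calls) or DS (dosages)."""
    n = panel.n_samples
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    hard = np.allclose(panel.dosages, np.round(panel.dosages))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        if hard:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_snps):
            base = [str(panel.chrom), str(int(panel.positions[j])),
                    panel.snp_ids[j], "A", "C", ".", "PASS", ".",
                    "GT" if hard else "DS"]
            if hard:
                cells = [gt_codes[int(round(d))] for d in panel.dosages[:, j]]
            else:
                cells = [f"{d:.3f}" for d in panel.dosages[:, j]]
            fh.write("\t".join(base + cells) + "\n")


def read_vcf(path, region_id: str = "region") -> GenotypePanel:
    """Read a (plain or bgzipped) VCF into a GenotypePanel via cyvcf2.

    Uses DS dosages when present, otherwise GT hard calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, pos, chroms, cols = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        pos.append(var.POS)
        chroms.append(var.CHROM)
        if "DS" in (var.FORMAT or []):
            cols.append(np.asarray(var.format("DS"), dtype=float).ravel())
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0,1,3=hom_alt,2=unknown
            dos = np.where(gts == 3, 2.0, gts)
            dos[gts == 2] = np.nan
            cols.append(dos)
    vcf.close()
    if not cols:
        raise ValueError(f"no variants in {path}")
    chrom = chroms[0]
    return GenotypePanel.from_dosages(np.column_stack(cols), np.asarray(pos),
                                      region_id=region_id, chrom=chrom,
                                      snp_ids=ids)


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages, columns=panel.snp_ids)
    df.insert(0, "sample", [f"s{i}" for i in range(panel.n_samples)])
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path, positions=None, region_id: str = "region") -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    snp_ids = [c for c in df.columns if c != "sample"]
    dos = df[snp_ids].to_numpy(dtype=float)
    if positions is None:
        positions = np.arange(1, len(snp_ids) + 1)
    return GenotypePanel.from_dosages(dos, positions, region_id=region_id,
                                      snp_ids=snp_ids)


def read_bed(path, flank: int = 10_000) -> list[GeneDefinition]:
    """Read genes from BED (0-based half-open); internal coordinates are
    1-based inclusive: start = bed_start + 1, stop = bed_end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"gene{i}"
        genes.append(GeneDefinition(gene_id=name, chrom=str(row[0]),
                                    start=int(row[1]) + 1, stop=int(row[2]),
                                    flank=flank))
    return genes


def write_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.stop}\t{g.gene_id}\n")


def write_summary_tsv(table: SnpSummaryTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_summary_tsv(path) -> SnpSummaryTable:
    return SnpSummaryTable.from_frame(pd.read_csv(path, sep="\t"))


def write_phenotypes_tsv(phenotypes: PhenotypeMatrix, path) -> None:
    k = phenotypes.n_phenotypes
    df = pd.DataFrame(phenotypes.values, columns=[f"pheno{i + 1}" for i in range(k)])
    df.insert(0, "sample", phenotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_results_tsv(results, genes, path) -> None:
    """Gene results TSV: GENE, CHR, START, STOP, M_TOTAL, M_EFF, METHOD_PAIR,
    P_GENE, N_SIMS."""
    gmap = {g.gene_id: g for g in genes}
    rows = []
    for r in results:
        g = gmap.get(r.gene_id)
        rows.append({
            "GENE": r.gene_id,
            "CHR": g.chrom if g else ".",
            "START": g.start if g else -1,
            "STOP": g.stop if g else -1,
            "M_TOTAL": r.m_total,
            "M_EFF": round(r.m_e, 3) if r.m_e is not None else np.nan,
            "METHOD_PAIR": r.method_pair,
            "P_GENE": r.p_gene,
            "N_SIMS": r.n_mc_sims if r.n_mc_sims is not None else 0,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
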