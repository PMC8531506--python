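"""File I/O: VCF genotypes, long-format phenotype TSV, result tables.

Genotypes travel as VCF (GT field, 1-based positions, one synthetic contig
per chromosome when written by the simulator); phenotypes as a long-format
TSV with columns ``individual_id, sex, day, weight_g``.  Only biallelic
SNPs are accepted on read; other records are skipped with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LongitudinalCohort

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_covariates",
]


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF with GT genotypes (pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom, grp in gm.snps.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1_000_000)
    for sid in gm.sample_ids:
        header.add_sample(str(sid))
    gt_of = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(gm.n_snps):
            rec = vcf.new_record(
                contig=str(gm.snps["chrom"].iloc[j]),
                start=int(gm.snps["pos"].iloc[j]) - 1,  # pysam start is 0-based
                alleles=("A", "G"),
                id=str(gm.snps["snp_id"].iloc[j]),
            )
            for i, sid in enumerate(gm.sample_ids):
                d = gm.dosages[i, j]
                rec.samples[str(sid)]["GT"] = gt_of.get(d, (None, None))
            vcf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (biallelic SNPs only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    dosage_cols, meta = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray([g[:2] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        dosage_cols.append(gts.sum(axis=1))
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS))
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic/non-SNP records", stacklevel=2)
    if not meta:
        raise ValueError(f"no biallelic SNPs found in {path}")
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos"])
    return GenotypeMatrix(np.column_stack(dosage_cols), snps, samples)


def write_phenotypes(cohort: LongitudinalCohort, path) -> None:
    """Write the long-format phenotype TSV (missing records omitted)."""
    cohort.to_long().to_csv(path, sep="\t", index=False)


def read_phenotypes(path, schedule=None) -> LongitudinalCohort:
    """Read a long-format phenotype TSV into a cohort."""
    long = pd.read_csv(path, sep="\t")
    return LongitudinalCohort.from_long(long, schedule=schedule)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Sidecar TSV with the generator's realized per-individual parameters."""
    truth.rename_axis("individual_id").to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    """Per-individual covariate TSV (e.g. PCA scores), indexed by id."""
    return pd.read_csv(path, sep="\t", index_col="individual_id")
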