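"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as uncompressed VCF 4.2 (GT-only, contig headers, 1-based
positions) read back through cyvcf2; phenotype/covariate tables and all
stage outputs are plain TSV so every number in a report can be recomputed
from the persisted files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GenotypeDataset

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the dosage matrix as a GT-only VCF 4.2 file.

    Dosage 1 is emitted as ``0/1``, 0/2 as the homozygous genotypes, and
    missing as ``./.``.  Hemizygous male X calls are therefore written as
    homozygous diploid genotypes, the same coding the association stage uses.
    """
    path = Path(path)
    contigs = dataset.snps["chrom"].drop_duplicates()
    lines = ["##fileformat=VCFv4.2"]
    lengths = dataset.meta.get("chrom_lengths", {})
    for chrom in contigs:
        if chrom in lengths:
            lines.append(f"##contig=<ID={chrom},length={lengths[chrom]}>")
        else:
            lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(dataset.samples)
    lines.append("\t".join(header))
    for j, row in dataset.snps.iterrows():
        gts = [
            _GT_STRINGS.get(dos, "./.") if not np.isnan(dos) else "./."
            for dos in dataset.dosages[:, j]
        ]
        rec = [str(row["chrom"]), str(row["pos"]), row["snp"], row["ref"],
               row["alt"], ".", "PASS", ".", "GT"] + gts
        lines.append("\t".join(rec))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Load a biallelic-SNP VCF into a dosage matrix (ALT-allele counts)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"non-biallelic record at {variant.CHROM}:{variant.POS}")
        # gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        dos = np.select(
            [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        rows.append((
            variant.ID or f"snp_{variant.CHROM}_{variant.POS}",
            str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0],
        ))
        cols.append(dos)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    return GenotypeDataset(
        dosages=np.column_stack(cols), snps=snps, samples=samples
    )


def write_phenotypes(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dataset(
    dataset: GenotypeDataset,
    frame: pd.DataFrame,
    vcf_path: str | Path,
    pheno_path: str | Path,
) -> None:
    """Persist a simulated cohort (VCF + phenotype TSV); round-trips losslessly."""
    write_vcf(dataset, vcf_path)
    write_phenotypes(frame, pheno_path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
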