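"""Variant/sample QC filters and genomic relationship matrix construction."""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import GenotypeDataset

log = logging.getLogger(__name__)


def apply_variant_filters(
    dataset: GenotypeDataset,
    min_call_rate: float = 0.90,
    maf_floor: float = 0.002,
) -> GenotypeDataset:
    """Drop SNPs failing call-rate or MAF screens within the given dataset.

    Retains SNPs with call rate >= ``min_call_rate`` and MAF strictly above
    ``maf_floor`` (a MAF exactly at the floor is excluded).  When the dataset
    is a single-sex stratum, this is the per-sex filter: call filtered
    per-stratum datasets rather than the pooled cohort.
    """
    call = dataset.snp_call_rate()
    maf = dataset.maf()
    keep = (call >= min_call_rate) & (maf > maf_floor)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info(
            "variant filters removed %d/%d SNPs (call rate < %.2f or MAF <= %g)",
            n_removed, dataset.n_snps, min_call_rate, maf_floor,
        )
    if not keep.any():
        raise ValueError("variant filters removed every SNP")
    return dataset.subset_snps(keep)


def sample_call_rate_filter(
    dataset: GenotypeDataset, min_rate: float = 0.90
) -> GenotypeDataset:
    """Drop samples with genotype call rate below ``min_rate`` (inclusive keep)."""
    rate = dataset.sample_call_rate()
    keep = rate >= min_rate
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("sample call-rate filter removed %d/%d samples",
                 n_removed, dataset.n_samples)
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    return dataset.subset_samples(keep)


def standardized_dosages(
    dataset: GenotypeDataset,
    autosomes_only: bool = False,
    scaled: bool = True,
) -> np.ndarray:
    """Centered (and optionally variance-scaled) dosage matrix ``Z``.

    Missing dosages are mean-imputed (0 after centering); monomorphic SNPs
    are dropped.  ``G = Z Z' / m`` is the GRM used throughout.
    """
    dos = dataset.dosages
    if autosomes_only:
        keep = (dataset.snps["chrom"] != "X").to_numpy()
        dos = dos[:, keep]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    dos = dos[:, poly]
    p = p[poly]
    if dos.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    Z = dos - 2.0 * p
    Z = np.where(np.isnan(Z), 0.0, Z)
    if scaled:
        Z = Z / np.sqrt(2.0 * p * (1.0 - p))
    return Z


def compute_grm(
    dataset: GenotypeDataset,
    autosomes_only: bool = False,
    scaled: bool = True,
) -> np.ndarray:
    """Genomic relationship matrix ``G = Z Z' / m`` from standardized dosages.

    Each retained SNP column is centered by ``2p`` and (when ``scaled``)
    divided by ``sqrt(2 p (1 - p))`` with ``p`` the counted-allele frequency
    in this dataset — the standardized (VanRaden method-1 style) GRM that
    mixed-model association tools build by default.  Missing dosages are
    mean-imputed (i.e. contribute 0 after centering); monomorphic SNPs are
    excluded.  Under HWE the average diagonal is ~1.

    ``autosomes_only=True`` restricts to non-X SNPs, matching a relationship
    matrix built from an autosomal panel even when association is also run
    on the X.
    """
    Z = standardized_dosages(dataset, autosomes_only=autosomes_only,
                             scaled=scaled)
    G = (Z @ Z.T) / Z.shape[1]
    return (G + G.T) / 2.0
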