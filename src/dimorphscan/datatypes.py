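"""In-memory containers shared across the pipeline stages.

Genotypes live in a dense ``samples x SNPs`` dosage matrix (ALT-allele
counts, ``NaN`` for missing calls) with a pandas SNP map alongside; tabular
stages (phenotypes, association summaries, dimorphism records) are plain
pandas DataFrames with documented column sets so they serialize to TSV
without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column layout of a per-stratum association summary (standard MLMA style).
ASSOC_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "counted_allele",
    "other_allele",
    "freq",
    "n",
    "beta",
    "se",
    "p",
]

#: Column layout of the per-SNP dimorphism table.
DIMORPH_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "counted_allele",
    "b_m",
    "se_m",
    "n_m",
    "freq_m",
    "b_f",
    "se_f",
    "n_f",
    "freq_f",
    "z",
    "p_dimorph",
    "log10_p_dimorph",
    "classification",
    "af_p",
    "minor_allele_concordant",
]


@dataclass
class GenotypeDataset:
    """Dosage matrix plus SNP map.

    Attributes
    ----------
    dosages:
        ``(n_samples, n_snps)`` float array of ALT-allele counts in
        ``{0, 1, 2}``; missing calls are ``NaN``.
    snps:
        DataFrame with columns ``snp`` (id), ``chrom``, ``pos`` (1-based bp),
        ``ref``, ``alt``, indexed 0..n_snps-1 in matrix column order.
    samples:
        sample ids in matrix row order.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample ids do not match the dosage row count")
        if len(self.snps) != m:
            raise ValueError("SNP map does not match the dosage column count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Counted (ALT) allele frequency per SNP, ignoring missing calls.

        Frequencies are computed over called alleles; on the X the male
        hemizygous 0/2 coding contributes two identical alleles per call,
        matching the homozygous coding used in association.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, mask: np.ndarray | list[int]) -> "GenotypeDataset":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            dosages=self.dosages[idx].copy(),
            snps=self.snps.copy(),
            samples=[self.samples[i] for i in idx],
            meta=dict(self.meta),
        )

    def subset_snps(self, mask: np.ndarray | list[int]) -> "GenotypeDataset":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            dosages=self.dosages[:, idx].copy(),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            meta=dict(self.meta),
        )


@dataclass
class VarianceComponents:
    """REML estimates for the single-GRM mixed model."""

    sigma_u2: float
    sigma_e2: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("non-finite REML log-likelihood")

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0
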