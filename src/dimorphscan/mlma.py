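"""Per-sex mixed-linear-model association.

For each sex stratum: variant QC within the stratum, an autosomal GRM, one
genome-wide REML fit of ``y = mu + u + e`` with ``u ~ N(0, G sigma_u2)``,
then a per-SNP GLS scan of ``y = mu + x b + u + e`` with the variance
components held fixed at the genome-wide optimum.  The candidate SNP is
tested against the full GRM (no leave-one-chromosome-out).  X-chromosome
dosages are recoded first so that non-PAR male calls are homozygous.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import grm as grm_mod
from . import lmm
from .config import DEFAULT_PAR_INTERVAL
from .datatypes import ASSOC_COLUMNS, GenotypeDataset, VarianceComponents

log = logging.getLogger(__name__)


def code_x_dosages(
    dataset: GenotypeDataset,
    is_male: np.ndarray,
    par_interval: tuple[int, int] = DEFAULT_PAR_INTERVAL,
) -> GenotypeDataset:
    """Resolve male heterozygous calls on the non-PAR X to homozygous dosages.

    The PAR (boundary inclusive) is left diploid for both sexes; females are
    never touched.  A male non-PAR dosage of 1 is a diploid-called artefact:
    since a single genotyped allele cannot be recovered from a dosage of 1,
    such calls are set missing.  Simulated males never produce them, so this
    path only guards dirty external data.
    """
    lo, hi = par_interval
    chrom = dataset.snps["chrom"].to_numpy()
    pos = dataset.snps["pos"].to_numpy()
    nonpar = (chrom == "X") & ~((pos >= lo) & (pos <= hi))
    if not nonpar.any():
        return dataset
    out = dataset.subset_snps(np.ones(dataset.n_snps, dtype=bool))
    male_rows = np.flatnonzero(np.asarray(is_male, dtype=bool))
    block = out.dosages[np.ix_(male_rows, np.flatnonzero(nonpar))]
    n_het = int(np.nansum(block == 1.0))
    if n_het:
        log.warning("set %d male heterozygous non-PAR X calls to missing", n_het)
    block[block == 1.0] = np.nan
    out.dosages[np.ix_(male_rows, np.flatnonzero(nonpar))] = block
    return out


def reml_fit(y: np.ndarray, G: np.ndarray) -> tuple[VarianceComponents, lmm.RemlResult]:
    """Genome-wide REML of the null model ``y = mu + u + e``."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.shape[0]:
        raise ValueError("phenotype and GRM dimensions differ")
    X = np.ones((y.shape[0], 1))
    fit = lmm.reml(y, X, K=G)
    vc = VarianceComponents(
        sigma_u2=fit.sigma_u2, sigma_e2=fit.sigma_e2,
        log_likelihood=fit.log_likelihood,
    )
    return vc, fit


def assoc_scan(
    y: np.ndarray,
    dataset: GenotypeDataset,
    fit: lmm.RemlResult,
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-SNP allele substitution effects by GLS at fixed variance components.

    Missing dosages are mean-imputed per SNP for the regression algebra only.
    SNPs monomorphic in the stratum are skipped (logged).  p-values are
    two-sided normal (Wald) tails of ``b / se``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != dataset.n_samples:
        raise ValueError("phenotype length does not match the dataset")
    dos = dataset.dosages
    freq = dataset.allele_freq()
    poly = (freq > 0) & (freq < 1) & np.isfinite(freq)
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("skipping %d monomorphic SNPs in stratum %s", n_mono, stratum)
    dos = dos[:, poly]
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    beta, se = lmm.gls_scan(y, dos, fit.ctx, fit.sigma_u2, fit.sigma_e2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    snps = dataset.snps.loc[poly]
    n_called = (~np.isnan(dataset.dosages[:, poly])).sum(axis=0)
    out = pd.DataFrame({
        "snp": snps["snp"].to_numpy(),
        "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(),
        "counted_allele": snps["alt"].to_numpy(),
        "other_allele": snps["ref"].to_numpy(),
        "freq": freq[poly],
        "n": n_called,
        "beta": beta,
        "se": se,
        "p": p,
    })
    out["stratum"] = stratum
    return out[ASSOC_COLUMNS + ["stratum"]]


def run_stratum(
    dataset: GenotypeDataset,
    y: np.ndarray,
    stratum: str,
    min_call_rate: float = 0.90,
    maf_floor: float = 0.002,
) -> tuple[pd.DataFrame, VarianceComponents]:
    """QC + GRM + REML + scan for one stratum (already subset to its samples)."""
    filtered = grm_mod.apply_variant_filters(
        dataset, min_call_rate=min_call_rate, maf_floor=maf_floor
    )
    G = grm_mod.compute_grm(filtered, autosomes_only=True)
    vc, fit = reml_fit(y, G)
    summary = assoc_scan(y, filtered, fit, stratum=stratum)
    return summary, vc


def run_sex_stratified(
    dataset: GenotypeDataset,
    frame: pd.DataFrame,
    trait_col: str = "adjusted",
    min_call_rate: float = 0.90,
    maf_floor: float = 0.002,
    min_stratum_n: int = 30,
    par_interval: tuple[int, int] = DEFAULT_PAR_INTERVAL,
) -> dict[str, pd.DataFrame]:
    """Independent male and female association analyses on one cohort.

    ``frame`` must align row-for-row with ``dataset.samples`` and carry
    ``sex`` plus the phenotype column.  Each stratum gets its own variant
    filters, allele frequencies, GRM and variance components.  Returns
    ``{"male": summary, "female": summary}``; each summary also records the
    stratum variance components in ``attrs``.
    """
    if list(frame["animal_id"]) != list(dataset.samples):
        raise ValueError("phenotype frame and dataset sample order differ")
    is_male = (frame["sex"] == "male").to_numpy()
    coded = code_x_dosages(dataset, is_male, par_interval=par_interval)
    results: dict[str, pd.DataFrame] = {}
    for sex, mask in (("male", is_male), ("female", ~is_male)):
        n = int(mask.sum())
        if n < min_stratum_n:
            raise ValueError(f"{sex} stratum has {n} < {min_stratum_n} samples")
        sub = coded.subset_samples(mask)
        y = frame.loc[mask, trait_col].to_numpy(dtype=float)
        summary, vc = run_stratum(
            sub, y, stratum=sex,
            min_call_rate=min_call_rate, maf_floor=maf_floor,
        )
        summary.attrs["variance_components"] = vc
        results[sex] = summary
    return results
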