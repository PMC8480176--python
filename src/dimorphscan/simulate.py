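"""Synthetic cattle-like cohorts with a known sex-specific genetic architecture.

Genotypes are drawn per SNP under Hardy–Weinberg equilibrium (no LD by
default), with the X chromosome handled as in the real data: males are
hemizygous outside the pseudoautosomal region, so their non-PAR dosages are
0 or 2 copies of the counted allele, while PAR genotypes are diploid in both
sexes.  Phenotypes follow the generative inverse of the adjustment model:

    trait = mean + sex + HSD + age-class + dam-parity
            + sum_j dosage_j * beta_sex,j + polygenic + residual

with the polygenic term drawn as ``u = Z g``, ``g ~ N(0, sigma_u2 / m I)``,
where ``Z`` is the standardized dosage matrix of the ``m`` non-causal
autosomal SNPs — since ``G = Z Z' / m`` this gives ``u ~ N(0, G sigma_u2)``
exactly without forming or factorizing ``G`` — and the residual scaled to
put the polygenic narrow-sense heritability at ``cfg.h2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .datatypes import GenotypeDataset
from .grm import standardized_dosages

EFFECT_CLASSES = ("shared", "male_only", "female_only", "opposite")


def _positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Strictly increasing 1-based positions on a chromosome."""
    if n > length:
        raise ValueError("more SNPs requested than base pairs available")
    pos = rng.choice(length, size=n, replace=False) + 1
    pos.sort()
    return pos


def simulate_genotypes(cfg: SimConfig) -> GenotypeDataset:
    """Draw a dosage matrix under HWE with sex-aware X-chromosome coding.

    Dosages count the ALT allele.  Missing calls (``NaN``) are placed
    uniformly at random at rate ``cfg.missing_rate``.  Sample ids encode sex
    (``M0001`` ...) so the dataset is self-describing even without the
    phenotype table.
    """
    if cfg.n_samples == 0 or cfg.n_snps_total == 0:
        raise ValueError("cannot simulate an empty cohort")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    is_male = np.zeros(n, dtype=bool)
    is_male[: cfg.n_males] = True

    snp_rows = []
    cols = []
    par_lo, par_hi = cfg.par_interval
    alleles = np.array(["A", "C", "G", "T"])
    for chrom, length in cfg.chrom_lengths.items():
        pos = _positions(rng, cfg.n_snps_per_chrom, length)
        mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.n_snps_per_chrom)
        for p_alt, bp in zip(mafs, pos):
            ref, alt = rng.choice(alleles, size=2, replace=False)
            snp_rows.append((f"snp_{chrom}_{bp}", chrom, int(bp), ref, alt))
            hemizygous = chrom == "X" and not (par_lo <= bp <= par_hi)
            if hemizygous:
                dos = rng.binomial(2, p_alt, size=n).astype(float)
                dos[is_male] = 2.0 * rng.binomial(1, p_alt, size=int(is_male.sum()))
            else:
                dos = rng.binomial(2, p_alt, size=n).astype(float)
            cols.append(dos)

    dosages = np.column_stack(cols)
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan
    samples = [
        f"M{i + 1:05d}" if is_male[i] else f"F{i + 1 - cfg.n_males:05d}"
        for i in range(n)
    ]
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    return GenotypeDataset(
        dosages=dosages,
        snps=snps,
        samples=samples,
        meta={
            "seed": cfg.seed,
            "par_interval": list(cfg.par_interval),
            "chrom_lengths": dict(cfg.chrom_lengths),
        },
    )


def assign_effects(cfg: SimConfig, dataset: GenotypeDataset) -> pd.DataFrame:
    """Sample causal SNPs and their per-sex allele substitution effects.

    Causal SNPs are drawn without replacement from autosomal SNPs segregating
    in the cohort.  Effect magnitudes are ``N(0, effect_size_sd^2)`` draws;
    the four classes fix the male/female relationship:

    - ``shared``: identical effect in both sexes,
    - ``male_only`` / ``female_only``: zero in the other sex,
    - ``opposite``: equal magnitude, reversed sign.

    Returns a DataFrame with columns ``snp, snp_index, class, beta_male,
    beta_female``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    total = cfg.total_causal
    if total == 0:
        return pd.DataFrame(
            columns=["snp", "snp_index", "class", "beta_male", "beta_female"]
        )
    maf = dataset.maf()
    autosomal = (dataset.snps["chrom"] != "X").to_numpy()
    candidates = np.flatnonzero(autosomal & (maf > 0))
    if total > candidates.size:
        raise ValueError(
            f"requested {total} causal SNPs but only {candidates.size} "
            "segregating autosomal SNPs are available"
        )
    chosen = rng.choice(candidates, size=total, replace=False)
    classes = (
        ["shared"] * cfg.n_causal_shared
        + ["male_only"] * cfg.n_causal_male_only
        + ["female_only"] * cfg.n_causal_female_only
        + ["opposite"] * cfg.n_causal_opposite
    )
    rows = []
    for idx, cls in zip(chosen, classes):
        mag = rng.normal(0.0, cfg.effect_size_sd)
        while mag == 0.0:  # degenerate draw; effects must be nonzero
            mag = rng.normal(0.0, cfg.effect_size_sd)
        if cls == "shared":
            bm, bf = mag, mag
        elif cls == "male_only":
            bm, bf = mag, 0.0
        elif cls == "female_only":
            bm, bf = 0.0, mag
        else:  # opposite
            bm, bf = mag, -mag
        rows.append((dataset.snps.loc[idx, "snp"], int(idx), cls, bm, bf))
    return pd.DataFrame(
        rows, columns=["snp", "snp_index", "class", "beta_male", "beta_female"]
    )


def _draw_factor(
    rng: np.random.Generator, n: int, n_levels: int, sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Random level assignment and level effects for one fixed factor."""
    levels = rng.integers(0, n_levels, size=n)
    effects = rng.normal(0.0, sd, size=n_levels) if sd > 0 else np.zeros(n_levels)
    return levels, effects


def simulate_phenotypes(
    dataset: GenotypeDataset,
    effects: pd.DataFrame,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Build the sample table with raw trait scores and true components.

    The polygenic background uses the GRM of non-causal autosomal SNPs
    (missing dosages mean-imputed), scaled so that the polygenic variance is
    ``cfg.h2`` against a residual variance of ``1 - cfg.h2`` — i.e. the trait
    SD net of fixed and foreground-SNP effects is 1.

    The returned frame carries the observable columns (ids, sex, breed,
    factor levels, the raw trait score) plus ``true_*`` columns used only by
    recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = dataset.n_samples
    is_male = np.array([s.startswith("M") for s in dataset.samples])

    frame = pd.DataFrame({"animal_id": dataset.samples})
    frame["sex"] = np.where(is_male, "male", "female")
    frame["breed"] = cfg.breed

    fixed_total = np.zeros(n)
    for factor, spec in cfg.fixed_effects.items():
        levels, level_effects = _draw_factor(rng, n, spec.n_levels, spec.sd)
        if factor == "dam_parity":
            frame[factor] = levels + 1  # parities are 1-based
        else:
            frame[factor] = [f"{factor}_{v:03d}" for v in levels]
        fixed_total += level_effects[levels]
    frame["classifier"] = [
        f"cls_{v}" for v in rng.integers(0, cfg.n_classifiers, size=n)
    ]
    frame["year"] = rng.integers(cfg.years[0], cfg.years[1] + 1, size=n)

    # Foreground causal effects, sex-specific.
    snp_effect = np.zeros(n)
    if len(effects):
        idx = effects["snp_index"].to_numpy()
        dos = dataset.dosages[:, idx]
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)
        beta = np.where(
            is_male[:, None],
            effects["beta_male"].to_numpy()[None, :],
            effects["beta_female"].to_numpy()[None, :],
        )
        snp_effect = (dos * beta).sum(axis=1)

    # Polygenic background from non-causal autosomal SNPs.
    causal = set(effects["snp_index"]) if len(effects) else set()
    autosomal = (dataset.snps["chrom"] != "X").to_numpy()
    bg_idx = [i for i in np.flatnonzero(autosomal) if i not in causal]
    if not bg_idx:
        raise ValueError("no non-causal autosomal SNPs left for the background")
    Z = standardized_dosages(dataset.subset_snps(bg_idx))
    m = Z.shape[1]
    # u = Z g with g ~ N(0, h2/m I) has covariance h2 * Z Z'/m = h2 * G
    # exactly -- the matrix square root of G without forming it.
    u = Z @ (np.sqrt(cfg.h2 / m) * rng.standard_normal(m))
    e = np.sqrt(1.0 - cfg.h2) * rng.standard_normal(n)

    sex_term = np.where(is_male, cfg.sex_effect / 2.0, -cfg.sex_effect / 2.0)
    frame[cfg.trait] = (
        cfg.trait_mean + sex_term + fixed_total + snp_effect + u + e
    )
    frame["true_fixed"] = fixed_total
    frame["true_genetic"] = u + snp_effect
    frame["true_polygenic"] = u
    frame["true_residual"] = e
    return frame
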