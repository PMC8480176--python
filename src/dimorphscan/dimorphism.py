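"""Between-sex contrast of allele substitution effects.

For every SNP segregating in both sexes, the male and female per-SNP effects
from the sex-stratified mixed-model scans are contrasted with

    z = (b_m - b_f) / sqrt(SE_m^2 + SE_f^2)

and a two-sided standard-normal tail probability.  A SNP is *suggestively*
dimorphic at p <= 1e-5 and *significantly* dimorphic at p <= 1e-8 (both
inclusive).  Two companion screens run per SNP: a contingency test of equal
allele frequency between the sexes, and a flag for whether both sexes share
the same minor allele.  A split-half experiment — contrasting two mixed-sex
halves of one cohort, each half containing half the males and half the
females — provides an empirical null for the genome-wide threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import mlma
from .config import DEFAULT_PAR_INTERVAL
from .datatypes import DIMORPH_COLUMNS, GenotypeDataset

log = logging.getLogger(__name__)

SUGGESTIVE = 1e-5
SIGNIFICANT = 1e-8


def effect_difference_test(
    b_m, se_m, b_f, se_f,
    n_m=None, n_f=None,
    denominator: str = "se",
):
    """Contrast statistic and two-sided p for a male/female effect pair.

    ``denominator="se"`` (default) uses ``sqrt(SE_m^2 + SE_f^2)``; the
    ``"printed"`` variant divides the summed squared errors by ``n_m + n_f``
    inside the root and exists for auditability only — the default is the
    form that reproduces worked examples from printed (b, SE) pairs.
    Inputs may be scalars or arrays.  Returns ``(z, p)``.
    """
    b_m, se_m, b_f, se_f = (np.asarray(v, dtype=float) for v in (b_m, se_m, b_f, se_f))
    for name, v in (("b_m", b_m), ("se_m", se_m), ("b_f", b_f), ("se_f", se_f)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite {name} passed to the contrast test")
    if np.any(se_m <= 0) or np.any(se_f <= 0):
        raise ValueError("standard errors must be positive")
    var = se_m**2 + se_f**2
    if denominator == "printed":
        if n_m is None or n_f is None:
            raise ValueError("printed denominator needs n_m and n_f")
        var = var / (np.asarray(n_m, dtype=float) + np.asarray(n_f, dtype=float))
    elif denominator != "se":
        raise ValueError(f"unknown denominator {denominator!r}")
    z = (b_m - b_f) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def log10_p_from_z(z) -> np.ndarray:
    """log10 of the two-sided normal tail, stable far below float precision."""
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)


def classify(p_dimorph, suggestive: float = SUGGESTIVE,
             significant: float = SIGNIFICANT):
    """Map contrast p-values to {none, suggestive, significant} (inclusive)."""
    p = np.asarray(p_dimorph, dtype=float)
    out = np.where(p <= significant, "significant",
                   np.where(p <= suggestive, "suggestive", "none"))
    if p.ndim == 0:
        return str(out)
    return out


def allele_frequency_divergence(counts_m, counts_f) -> float:
    """Two-sided p for unequal allele frequency from a 2x2 allele-count table.

    Chi-square with continuity correction; Fisher's exact test when any
    expected cell is below 5.  A zero-margin table returns 1 with a warning.
    """
    table = np.array([list(counts_m), list(counts_f)], dtype=float)
    if table.min() < 0:
        raise ValueError("negative allele count")
    if table.sum(axis=1).min() <= 0:
        raise ValueError("each sex needs a positive total allele count")
    if (table.sum(axis=0) == 0).any():
        log.warning("zero-margin allele-count table; af_p = 1")
        return 1.0
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 5:
        _, p = stats.fisher_exact(np.round(table).astype(int))
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def minor_allele_concordance(freq_m: float, freq_f: float) -> bool:
    """True when both sexes share the same minor allele.

    Frequencies refer to the same counted allele in both sexes.  A frequency
    of exactly 0.5 has no minor allele and counts as concordant with either.
    """
    for f in (freq_m, freq_f):
        if not 0.0 < f < 1.0:
            raise ValueError("frequencies must be in (0, 1)")
    return (freq_m - 0.5) * (freq_f - 0.5) >= 0.0


def join_sex_summaries(
    male: pd.DataFrame,
    female: pd.DataFrame,
    suggestive: float = SUGGESTIVE,
    significant: float = SIGNIFICANT,
    af_test: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-sex association summaries into the dimorphism table.

    Only SNPs present (i.e. segregating) in both summaries are contrasted;
    SNPs present in one sex only go to a separate monomorphic report, since
    monomorphism in one sex may itself indicate dimorphism.  When the two
    summaries counted different alleles at a site, the female effect and
    frequency are flipped onto the male counted allele before the contrast.

    Returns ``(dimorphism_table, monomorphic_report)``.
    """
    m = male.set_index("snp")
    f = female.set_index("snp")
    shared = m.index.intersection(f.index)
    only = pd.concat([
        male[~male["snp"].isin(shared)].assign(present_in="male"),
        female[~female["snp"].isin(shared)].assign(present_in="female"),
    ], ignore_index=True)
    if shared.empty:
        return pd.DataFrame(columns=DIMORPH_COLUMNS), only

    ms = m.loc[shared]
    fs = f.loc[shared]
    if not (ms["pos"].to_numpy() == fs["pos"].to_numpy()).all():
        bad = shared[ms["pos"].to_numpy() != fs["pos"].to_numpy()]
        raise ValueError(f"discordant positions for shared SNP ids: {list(bad[:5])}")

    b_f = fs["beta"].to_numpy().copy()
    freq_f = fs["freq"].to_numpy().copy()
    flip = (ms["counted_allele"].to_numpy() != fs["counted_allele"].to_numpy())
    if flip.any():
        swapped_ok = (
            fs["counted_allele"].to_numpy()[flip] == ms["other_allele"].to_numpy()[flip]
        )
        if not swapped_ok.all():
            raise ValueError("shared SNP ids with incompatible alleles")
        b_f[flip] = -b_f[flip]
        freq_f[flip] = 1.0 - freq_f[flip]

    z, p = effect_difference_test(
        ms["beta"].to_numpy(), ms["se"].to_numpy(), b_f, fs["se"].to_numpy()
    )
    out = pd.DataFrame({
        "snp": shared,
        "chrom": ms["chrom"].to_numpy(),
        "pos": ms["pos"].to_numpy(),
        "counted_allele": ms["counted_allele"].to_numpy(),
        "b_m": ms["beta"].to_numpy(),
        "se_m": ms["se"].to_numpy(),
        "n_m": ms["n"].to_numpy(),
        "freq_m": ms["freq"].to_numpy(),
        "b_f": b_f,
        "se_f": fs["se"].to_numpy(),
        "n_f": fs["n"].to_numpy(),
        "freq_f": freq_f,
        "z": z,
        "p_dimorph": p,
        "log10_p_dimorph": log10_p_from_z(z),
        "classification": classify(p, suggestive, significant),
    })
    if af_test:
        af_p = np.empty(len(out))
        for i, row in enumerate(out.itertuples(index=False)):
            cm = (round(2 * row.n_m * row.freq_m),
                  round(2 * row.n_m * (1 - row.freq_m)))
            cf = (round(2 * row.n_f * row.freq_f),
                  round(2 * row.n_f * (1 - row.freq_f)))
            af_p[i] = allele_frequency_divergence(cm, cf)
        out["af_p"] = af_p
    else:
        out["af_p"] = np.nan
    out["minor_allele_concordant"] = [
        minor_allele_concordance(a, b)
        for a, b in zip(out["freq_m"], out["freq_f"])
    ]
    return out.reset_index(drop=True)[DIMORPH_COLUMNS], only


def split_half_calibration(
    dataset: GenotypeDataset,
    frame: pd.DataFrame,
    trait_col: str = "adjusted",
    seed: int = 0,
    min_call_rate: float = 0.90,
    maf_floor: float = 0.002,
    min_stratum_n: int = 30,
    par_interval: tuple[int, int] = DEFAULT_PAR_INTERVAL,
) -> dict:
    """Mixed-sex split-half empirical null for the dimorphism threshold.

    Half the males plus half the females form group 1, the remainder group 2;
    the full per-group association + effect contrast runs as if the groups
    were the two sexes.  Because both halves have the same sex composition,
    any apparent "dimorphism" between them is sampling noise, so the
    genome-wide minimum contrast p calibrates the significance threshold.

    Returns ``{"min_p": float, "p_values": ndarray, "n_group1": int,
    "n_group2": int, "seed": int}``.
    """
    if list(frame["animal_id"]) != list(dataset.samples):
        raise ValueError("phenotype frame and dataset sample order differ")
    rng = np.random.default_rng(seed)
    is_male = (frame["sex"] == "male").to_numpy()
    group1 = np.zeros(len(frame), dtype=bool)
    for mask in (is_male, ~is_male):
        idx = np.flatnonzero(mask)
        take = rng.permutation(idx)[: idx.size // 2]
        group1[take] = True
    summaries = {}
    coded = mlma.code_x_dosages(dataset, is_male, par_interval=par_interval)
    for name, mask in (("group1", group1), ("group2", ~group1)):
        n = int(mask.sum())
        if n < min_stratum_n:
            raise ValueError(f"{name} has {n} < {min_stratum_n} samples")
        sub = coded.subset_samples(mask)
        y = frame.loc[mask, trait_col].to_numpy(dtype=float)
        summary, _ = mlma.run_stratum(
            sub, y, stratum=name,
            min_call_rate=min_call_rate, maf_floor=maf_floor,
        )
        summaries[name] = summary
    joined, _ = join_sex_summaries(
        summaries["group1"], summaries["group2"], af_test=False
    )
    p = joined["p_dimorph"].to_numpy()
    return {
        "min_p": float(p.min()) if p.size else 1.0,
        "p_values": p,
        "n_group1": int(group1.sum()),
        "n_group2": int((~group1).sum()),
        "seed": seed,
    }
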