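"""Reference experiments: worked examples, split-half threshold calibration,
null calibration of the contrast test, and parameter recovery.

Each function simulates its own cohort from a seed and runs the ordinary
library pipeline, so results are reproducible end to end.  Problem sizes are
the study conditions used throughout the package: cohorts of 2,000 animals
(1,400 males / 600 females), ~5,000 SNPs, h2 = 0.4.
"""

from __future__ import annotations

import numpy as np

from . import dimorphism, grm, lmm, mlma, simulate
from .config import SimConfig

#: Reported between-sex contrasts recomputed from published effect/SE pairs:
#: (male effect, male SE, female effect, female SE).
WORKED_EXAMPLES = {
    "angus_inner_thigh_bta6": (0.12, 0.13, -3.68, 0.63),
    "angus_hip_width_bta8": (-0.23, 0.10, 2.29, 0.40),
    "limousin_chest_width_bta11": (0.03, 0.29, -3.86, 0.51),
    "hereford_muscular_bta16": (0.42, 0.13, -0.61, 0.14),
}


def worked_example_pvalues() -> dict[str, float]:
    """Contrast p-values for the published male/female effect pairs."""
    out = {}
    for name, (bm, sm, bf, sf) in WORKED_EXAMPLES.items():
        _, p = dimorphism.effect_difference_test(bm, sm, bf, sf)
        out[name] = p
    return out


def _study_cohort(seed: int, **overrides) -> SimConfig:
    base = dict(
        n_males=1400,
        n_females=600,
        n_snps_per_chrom=1250,
        chrom_lengths={"1": 158_534_110, "2": 136_231_102,
                       "3": 121_005_158, "4": 120_000_601},
        maf_low=0.02,
        h2=0.4,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def split_half_calibration_experiment(
    seed: int, n_replicates: int = 10
) -> dict:
    """Genome-wide minimum contrast p across mixed-sex split-half replicates.

    One cohort of 2,000 animals and 5,000 SNPs, including 20 causal SNPs
    with opposite-sign effects in the two sexes, is split repeatedly into
    two halves that each contain half the males and half the females.  The
    per-group association + contrast pipeline runs on every split; because
    the halves share the same sex composition, the minimum p estimates the
    genome-wide null floor against which the significance threshold is
    judged.
    """
    cfg = _study_cohort(seed, n_causal_opposite=20)
    dataset = simulate.simulate_genotypes(cfg)
    effects = simulate.assign_effects(cfg, dataset)
    frame = simulate.simulate_phenotypes(dataset, effects, cfg)
    frame = frame.copy()
    frame["adjusted"] = frame[cfg.trait]
    min_ps = []
    for rep in range(n_replicates):
        res = dimorphism.split_half_calibration(
            dataset, frame, seed=seed * 1009 + rep, maf_floor=0.002,
        )
        min_ps.append(res["min_p"])
    min_ps = np.asarray(min_ps)
    return {
        "min_p": min_ps,
        "overall_min_p": float(min_ps.min()),
        "n_at_or_above_1e-8": int((min_ps >= 1e-8).sum()),
        "n_replicates": n_replicates,
    }


def null_contrast_calibration(seed: int, n_replicates: int = 2) -> dict:
    """Contrast-test calibration when every causal effect is shared.

    Cohorts carry 20 causal SNPs with b_m = b_f plus the polygenic
    background; the per-sex scans and the effect contrast then run as usual.
    Under this null the contrast p-values should be uniform, so the fraction
    at or below the suggestive threshold and the KS distance from
    uniformity measure the test's type-I behaviour.
    """
    from scipy import stats

    all_p = []
    for rep in range(n_replicates):
        cfg = _study_cohort(seed + 7919 * (rep + 1), n_causal_shared=20)
        dataset = simulate.simulate_genotypes(cfg)
        effects = simulate.assign_effects(cfg, dataset)
        frame = simulate.simulate_phenotypes(dataset, effects, cfg)
        frame["adjusted"] = frame[cfg.trait]
        res = mlma.run_sex_stratified(dataset, frame)
        joined, _ = dimorphism.join_sex_summaries(
            res["male"], res["female"], af_test=False
        )
        all_p.append(joined["p_dimorph"].to_numpy())
    p = np.concatenate(all_p)
    return {
        "n_snps": int(p.size),
        "frac_at_suggestive": float((p <= 1e-5).mean()),
        "ks_statistic": float(stats.kstest(p, "uniform").statistic),
    }


def heritability_recovery(seed: int) -> dict:
    """REML h2 on a cohort simulated at h2 = 0.4 (n = 2,000)."""
    cfg = _study_cohort(seed, n_snps_per_chrom=500)
    dataset = simulate.simulate_genotypes(cfg)
    effects = simulate.assign_effects(cfg, dataset)
    frame = simulate.simulate_phenotypes(dataset, effects, cfg)
    y = (frame["true_polygenic"] + frame["true_residual"]).to_numpy()
    G = grm.compute_grm(dataset, autosomes_only=True)
    vc, _ = mlma.reml_fit(y, G)
    return {"h2_true": cfg.h2, "h2_estimate": float(vc.h2)}


def snp_effect_recovery(seed: int, beta: float = 0.5, maf: float = 0.3) -> dict:
    """Mixed-model estimate of a single causal SNP effect (n = 2,000)."""
    cfg = _study_cohort(seed, n_snps_per_chrom=500, maf_low=maf, maf_high=maf,
                        n_causal_shared=1)
    dataset = simulate.simulate_genotypes(cfg)
    effects = simulate.assign_effects(cfg, dataset)
    effects.loc[0, ["beta_male", "beta_female"]] = beta
    frame = simulate.simulate_phenotypes(dataset, effects, cfg)
    y = frame[cfg.trait].to_numpy() - frame["true_fixed"].to_numpy()
    G = grm.compute_grm(dataset, autosomes_only=True)
    vc, fit = mlma.reml_fit(y, G)
    x = dataset.dosages[:, int(effects.loc[0, "snp_index"])]
    b, se = lmm.gls_scan(y, x[:, None], fit.ctx, fit.sigma_u2, fit.sigma_e2)
    return {"beta_true": beta, "beta_estimate": float(b[0]),
            "se": float(se[0])}


def dimorphism_power(
    seed: int, delta: float = 1.0, n_per_sex: int = 2000, n_dimorphic: int = 20
) -> dict:
    """Detection rate of opposite-sign dimorphic SNPs (+delta / -delta).

    A balanced cohort with ``n_per_sex`` animals per sex carries
    ``n_dimorphic`` causal SNPs whose male and female allele substitution
    effects are +delta and -delta phenotype SD; the full sex-stratified scan
    plus contrast runs and the fraction of those SNPs reaching the
    suggestive threshold is the empirical power.
    """
    cfg = _study_cohort(seed, n_males=n_per_sex, n_females=n_per_sex,
                        n_snps_per_chrom=400, n_causal_opposite=n_dimorphic)
    dataset = simulate.simulate_genotypes(cfg)
    effects = simulate.assign_effects(cfg, dataset)
    sign = np.sign(effects["beta_male"].to_numpy())
    effects["beta_male"] = delta * sign
    effects["beta_female"] = -delta * sign
    frame = simulate.simulate_phenotypes(dataset, effects, cfg)
    frame["adjusted"] = frame[cfg.trait]
    res = mlma.run_sex_stratified(dataset, frame)
    joined, _ = dimorphism.join_sex_summaries(
        res["male"], res["female"], af_test=False
    )
    hits = joined.set_index("snp").reindex(effects["snp"])
    power = float((hits["p_dimorph"] <= dimorphism.SUGGESTIVE).mean())
    return {"delta": delta, "power_at_suggestive": power,
            "n_dimorphic": n_dimorphic}
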