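"""Between-sex effect contrast, classification, AF divergence, concordance,
and the split-half empirical null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dimorphscan import dimorphism, pipeline
from dimorphscan.config import SimConfig
from dimorphscan.dimorphism import (
    allele_frequency_divergence,
    classify,
    effect_difference_test,
    join_sex_summaries,
    minor_allele_concordance,
    split_half_calibration,
)
from conftest import make_assoc


class TestEffectDifference:
    @pytest.mark.parametrize("bm,sm,bf,sf,expected_p", [
        (0.12, 0.13, -3.68, 0.63, 3.45e-9),    # inner-thigh SNP, Angus
        (-0.23, 0.10, 2.29, 0.40, 9.86e-10),   # hip-width SNP, Angus
        (0.03, 0.29, -3.86, 0.51, 3.63e-11),   # chest-width SNP, Limousin
        (0.42, 0.13, -0.61, 0.14, 6.30e-8),    # Hereford muscular SNP
    ])
    def test_reproduces_reported_contrasts(self, bm, sm, bf, sf, expected_p):
        """Published (b, SE) pairs reproduce the reported significance."""
        _, p = effect_difference_test(bm, sm, bf, sf)
        assert abs(np.log10(p) - np.log10(expected_p)) <= 0.1

    def test_equal_effects_give_null(self):
        z, p = effect_difference_test(0.7, 0.2, 0.7, 0.3)
        assert z == 0.0 and p == 1.0

    def test_sex_swap_antisymmetry(self):
        z1, p1 = effect_difference_test(0.5, 0.1, -0.2, 0.2)
        z2, p2 = effect_difference_test(-0.2, 0.2, 0.5, 0.1)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_printed_denominator_variant(self):
        z_se, _ = effect_difference_test(1.0, 0.5, 0.0, 0.5)
        z_pr, _ = effect_difference_test(1.0, 0.5, 0.0, 0.5, n_m=50, n_f=50,
                                         denominator="printed")
        assert z_pr == pytest.approx(z_se * 10.0)  # sqrt(n_m + n_f) = 10

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            effect_difference_test(np.nan, 0.1, 0.0, 0.1)
        with pytest.raises(ValueError):
            effect_difference_test(0.1, 0.0, 0.0, 0.1)

    @given(b=st.floats(-5, 5), se_m=st.floats(0.01, 2), se_f=st.floats(0.01, 2),
           c=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, b, se_m, se_f, c):
        """Multiplying effects and SEs by c > 0 leaves z and p unchanged."""
        z1, p1 = effect_difference_test(b, se_m, -b / 2, se_f)
        z2, p2 = effect_difference_test(c * b, c * se_m, -c * b / 2, c * se_f)
        assert z2 == pytest.approx(z1, rel=1e-8, abs=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-6, abs=1e-300)


class TestClassification:
    @pytest.mark.parametrize("p,expected", [
        (1e-5, "suggestive"),       # inclusive boundary
        (1e-8, "significant"),      # inclusive boundary
        (9.9e-9, "significant"),
        (5e-7, "suggestive"),
        (0.5, "none"),
        (1.0, "none"),
    ])
    def test_thresholds(self, p, expected):
        assert classify(p) == expected


class TestAlleleFrequencyDivergence:
    def test_identical_tables_are_null(self):
        assert allele_frequency_divergence((60, 40), (60, 40)) == 1.0

    def test_matches_hand_computed_yates_chi2(self):
        # independent oracle: Yates-corrected chi-square from first principles
        table = np.array([[90.0, 10.0], [50.0, 50.0]])
        n = table.sum()
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / n
        chi2 = float(((np.abs(table - expected) - 0.5) ** 2 / expected).sum())
        p_oracle = stats.chi2.sf(chi2, 1)
        p = allele_frequency_divergence((90, 10), (50, 50))
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_sparse_cells_use_exact_test(self):
        p = allele_frequency_divergence((2, 98), (0, 100))
        _, p_fisher = stats.fisher_exact([[2, 98], [0, 100]])
        assert p == pytest.approx(p_fisher, abs=1e-12)

    def test_type_one_error_calibrated(self):
        # equal-frequency sexes: ~5% of SNPs flagged at alpha = 0.05
        rng = np.random.default_rng(60)
        n_alleles = 2000
        hits = 0
        n_snps = 2000
        for _ in range(n_snps):
            f = rng.uniform(0.1, 0.5)
            a = rng.binomial(n_alleles, f)
            b = rng.binomial(n_alleles, f)
            p = allele_frequency_divergence((a, n_alleles - a),
                                            (b, n_alleles - b))
            hits += p <= 0.05
        assert hits / n_snps == pytest.approx(0.05, abs=0.02)

    def test_zero_margin_table(self):
        assert allele_frequency_divergence((5, 0), (7, 0)) == 1.0


class TestMinorAlleleConcordance:
    @pytest.mark.parametrize("fm,ff,expected", [
        (0.3, 0.4, True),
        (0.45, 0.55, False),
        (0.5, 0.7, True),   # exact 0.5 concordant with either
        (0.5, 0.2, True),
        (0.9, 0.8, True),
    ])
    def test_cases(self, fm, ff, expected):
        assert minor_allele_concordance(fm, ff) is expected


class TestJoin:
    def test_allele_alignment_flips_female(self):
        male = make_assoc(["rs1"], [0.2], [0.1], [0.3], counted=["A"],
                          other=["G"])
        female = make_assoc(["rs1"], [0.3], [0.1], [0.8], counted=["G"],
                            other=["A"], stratum="female")
        out, _ = join_sex_summaries(male, female)
        assert out["b_f"].iloc[0] == pytest.approx(-0.3)
        assert out["freq_f"].iloc[0] == pytest.approx(0.2)

    def test_disjoint_sets_give_empty_join(self):
        male = make_assoc(["rs1", "rs2"], [0.1, 0.2], [0.1, 0.1], [0.3, 0.4])
        female = make_assoc(["rs3"], [0.1], [0.1], [0.3], stratum="female")
        out, mono = join_sex_summaries(male, female)
        assert out.empty
        assert len(mono) == 3
        assert set(mono["present_in"]) == {"male", "female"}

    def test_shared_count_matches_set_oracle(self):
        rng = np.random.default_rng(61)
        all_snps = [f"rs{i}" for i in range(100)]
        male_ids = all_snps[:90]
        female_ids = all_snps[10:]
        male = make_assoc(male_ids, rng.normal(0, 0.2, 90),
                          np.full(90, 0.1), rng.uniform(0.1, 0.9, 90))
        male["pos"] = [all_snps.index(s) * 100 for s in male_ids]
        female = make_assoc(female_ids, rng.normal(0, 0.2, 90),
                            np.full(90, 0.1), rng.uniform(0.1, 0.9, 90),
                            stratum="female")
        female["pos"] = [all_snps.index(s) * 100 for s in female_ids]
        out, mono = join_sex_summaries(male, female)
        assert len(out) == len(set(male_ids) & set(female_ids)) == 80
        assert len(mono) == 20

    def test_discordant_positions_raise(self):
        male = make_assoc(["rs1"], [0.1], [0.1], [0.3])
        female = make_assoc(["rs1"], [0.1], [0.1], [0.3], stratum="female")
        female["pos"] = [999]
        with pytest.raises(ValueError, match="position"):
            join_sex_summaries(male, female)

    def test_allele_flip_leaves_screens_invariant(self):
        # flipping the counted allele in both sexes: |z|, p, af_p, concordance
        male = make_assoc(["rs1"], [0.4], [0.1], [0.3])
        female = make_assoc(["rs1"], [-0.1], [0.1], [0.35], stratum="female")
        out1, _ = join_sex_summaries(male, female)
        male_f = male.assign(beta=-male["beta"], freq=1 - male["freq"],
                             counted_allele="G", other_allele="A")
        female_f = female.assign(beta=-female["beta"], freq=1 - female["freq"],
                                 counted_allele="G", other_allele="A")
        out2, _ = join_sex_summaries(male_f, female_f)
        assert abs(out2["z"].iloc[0]) == pytest.approx(abs(out1["z"].iloc[0]))
        assert out2["p_dimorph"].iloc[0] == pytest.approx(out1["p_dimorph"].iloc[0])
        assert out2["af_p"].iloc[0] == pytest.approx(out1["af_p"].iloc[0], abs=1e-10)
        assert out2["minor_allele_concordant"].iloc[0] == \
            out1["minor_allele_concordant"].iloc[0]


def test_power_increases_with_effect_divergence():
    """Detection of opposite-sign dimorphic SNPs (+d / -d) at the suggestive
    threshold is monotone non-decreasing over a 3-point effect grid."""
    from dimorphscan import mlma, simulate
    rates = []
    for i, delta in enumerate((0.2, 0.5, 1.0)):
        cfg = SimConfig(n_males=500, n_females=500, n_snps_per_chrom=400,
                        chrom_lengths={"1": 10**8, "2": 10**8}, maf_low=0.05,
                        n_causal_opposite=10, h2=0.4, seed=99 + i)
        dataset = simulate.simulate_genotypes(cfg)
        effects = simulate.assign_effects(cfg, dataset)
        sign = np.sign(effects["beta_male"].to_numpy())
        effects["beta_male"] = delta * sign
        effects["beta_female"] = -delta * sign
        frame = simulate.simulate_phenotypes(dataset, effects, cfg)
        frame["adjusted"] = frame[cfg.trait]
        res = mlma.run_sex_stratified(dataset, frame)
        joined, _ = dimorphism.join_sex_summaries(res["male"], res["female"],
                                                  af_test=False)
        detected = (joined.set_index("snp")["p_dimorph"]
                    .reindex(effects["snp"]) <= 1e-5)
        rates.append(float(detected.mean()))
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] >= 0.8


class TestSplitHalf:
    def test_partition_is_seed_deterministic(self, small_cohort):
        cfg, dataset, effects, frame = small_cohort
        frame = frame.copy()
        frame["adjusted"] = frame[cfg.trait]
        a = split_half_calibration(dataset, frame, seed=5, maf_floor=0.0,
                                   min_stratum_n=10)
        b = split_half_calibration(dataset, frame, seed=5, maf_floor=0.0,
                                   min_stratum_n=10)
        assert a["min_p"] == b["min_p"]
        np.testing.assert_array_equal(a["p_values"], b["p_values"])
        assert a["n_group1"] == 210 // 2 + 90 // 2

    def test_null_contrast_p_distribution_uniform(self):
        # no dimorphic SNPs at all: split-half contrast p is uniform
        cfg = SimConfig(n_males=350, n_females=150, n_snps_per_chrom=1500,
                        chrom_lengths={"1": 10**8, "2": 10**8}, maf_low=0.05,
                        h2=0.4, seed=71)
        dataset, effects, frame = pipeline.prepare_cohort(cfg)
        frame = frame.copy()
        frame["adjusted"] = frame[cfg.trait]
        res = split_half_calibration(dataset, frame, seed=3, maf_floor=0.0,
                                     min_stratum_n=50)
        ks = stats.kstest(res["p_values"], "uniform").statistic
        assert ks < 0.05
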