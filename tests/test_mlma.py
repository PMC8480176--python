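"""Mixed-model association: REML, GLS scan, X coding, stratified runs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphscan import grm, lmm, mlma, pipeline, simulate
from dimorphscan.config import SimConfig
from dimorphscan.datatypes import GenotypeDataset


def hwe_dataset(rng, n, m, maf_low=0.05, chroms=None):
    p = rng.uniform(maf_low, 0.5, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    snps = pd.DataFrame({
        "snp": [f"s{i}" for i in range(m)],
        "chrom": chroms or ["1"] * m,
        "pos": np.arange(1, m + 1) * 50,
        "ref": ["A"] * m, "alt": ["G"] * m,
    })
    return GenotypeDataset(dosages=dos, snps=snps,
                           samples=[f"id{i}" for i in range(n)])


class TestXCoding:
    def _xds(self, positions, dosages):
        m = len(positions)
        snps = pd.DataFrame({
            "snp": [f"x{i}" for i in range(m)], "chrom": ["X"] * m,
            "pos": positions, "ref": ["A"] * m, "alt": ["G"] * m,
        })
        return GenotypeDataset(dosages=np.asarray(dosages, float), snps=snps,
                               samples=["m1", "f1"])

    def test_par_boundary_is_inclusive(self):
        # a male het at the PAR's first base stays diploid
        ds = self._xds([143_861_798], [[1.0], [1.0]])
        out = mlma.code_x_dosages(ds, np.array([True, False]))
        assert out.dosages[0, 0] == 1.0

    def test_nonpar_male_het_becomes_missing(self):
        ds = self._xds([100_000_000], [[1.0], [1.0]])
        out = mlma.code_x_dosages(ds, np.array([True, False]))
        assert np.isnan(out.dosages[0, 0])
        # homozygous male calls are untouched
        ds2 = self._xds([100_000_000], [[2.0], [1.0]])
        out2 = mlma.code_x_dosages(ds2, np.array([True, False]))
        assert out2.dosages[0, 0] == 2.0

    def test_females_never_touched(self):
        ds = self._xds([100_000_000, 144_000_000], [[0.0, 2.0], [1.0, 1.0]])
        out = mlma.code_x_dosages(ds, np.array([True, False]))
        np.testing.assert_array_equal(out.dosages[1], [1.0, 1.0])


class TestReml:
    def test_h2_recovery(self):
        # h2 = 0.5 cohorts: mean REML estimate across replicates in [0.4, 0.6]
        ests = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ds = hwe_dataset(rng, 1000, 800)
            G = grm.compute_grm(ds)
            d, U = np.linalg.eigh(G)
            u = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(1000))
            y = np.sqrt(0.5) * u + np.sqrt(0.5) * rng.standard_normal(1000)
            vc, _ = mlma.reml_fit(y, G)
            ests.append(vc.h2)
        assert 0.4 <= np.mean(ests) <= 0.6

    def test_identity_grm_total_variance(self):
        # with G = I only the total variance is identified
        rng = np.random.default_rng(7)
        y = rng.normal(0, 2.0, 500)
        vc, _ = mlma.reml_fit(y, np.eye(500))
        assert vc.sigma_u2 + vc.sigma_e2 == pytest.approx(np.var(y, ddof=1),
                                                          rel=0.02)

    def test_matches_brute_force_grid(self):
        # dense-algebra REML likelihood maximized on a fine h2 grid
        rng = np.random.default_rng(55)
        n = 50
        ds = hwe_dataset(rng, n, 200)
        G = grm.compute_grm(ds)
        d, U = np.linalg.eigh(G)
        u = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(n))
        y = np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal(n)
        vc, _ = mlma.reml_fit(y, G)

        X = np.ones((n, 1))
        def dense_reml_ll(lam):
            V = lam * G + np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            sigma_e2 = float(r @ Vi @ r) / (n - 1)
            _, ldV = np.linalg.slogdet(V)
            _, ldX = np.linalg.slogdet(XtViX)
            return -0.5 * ((n - 1) * np.log(sigma_e2) + ldV + ldX + (n - 1))

        hs = np.arange(0.0, 0.9999, 1e-4)
        lams = hs / (1 - hs)
        lls = np.array([dense_reml_ll(l) for l in lams])
        h_grid = hs[np.argmax(lls)]
        assert vc.h2 == pytest.approx(h_grid, abs=2e-4)


class TestScan:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(77)
        n, m = 500, 2000
        ds = hwe_dataset(rng, n, m)
        G = grm.compute_grm(ds)
        d, U = np.linalg.eigh(G)
        u = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(n))
        y = np.sqrt(0.3) * u + np.sqrt(0.7) * rng.standard_normal(n)
        vc, fit = mlma.reml_fit(y, G)
        res = mlma.assoc_scan(y, ds, fit)
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.05
        # genomic inflation: median chi2 near the null median
        chi2 = (res["beta"] / res["se"]) ** 2
        assert 0.9 <= np.median(chi2) / stats.chi2.ppf(0.5, 1) <= 1.1

    def test_causal_effect_recovered(self):
        rng = np.random.default_rng(78)
        n = 2000
        ds = hwe_dataset(rng, n, 600)
        x = rng.binomial(2, 0.3, n).astype(float)
        G = grm.compute_grm(ds)
        d, U = np.linalg.eigh(G)
        u = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(n))
        y = 0.5 * x + np.sqrt(0.3) * u + np.sqrt(0.7) * rng.standard_normal(n)
        vc, fit = mlma.reml_fit(y, G)
        beta, se = lmm.gls_scan(y, x[:, None], fit.ctx, fit.sigma_u2,
                                fit.sigma_e2)
        assert beta[0] == pytest.approx(0.5, abs=0.15)

    def test_gls_equals_ols_when_no_genetic_variance(self):
        rng = np.random.default_rng(79)
        n = 200
        ds = hwe_dataset(rng, n, 50)
        y = rng.standard_normal(n)
        ctx = lmm.eigen_context(grm.compute_grm(ds))
        beta, se = lmm.gls_scan(y, ds.dosages, ctx, 0.0, 1.0)
        for j in range(5):
            X = np.column_stack([np.ones(n), ds.dosages[:, j]])
            coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            XtX_inv = np.linalg.inv(X.T @ X)
            assert beta[j] == pytest.approx(coef[1], rel=1e-8)
            assert se[j] == pytest.approx(np.sqrt(XtX_inv[1, 1]), rel=1e-8)

    def test_allele_relabel_antisymmetry(self):
        rng = np.random.default_rng(80)
        n = 150
        ds = hwe_dataset(rng, n, 30)
        y = rng.standard_normal(n) + 0.3 * ds.dosages[:, 0]
        G = grm.compute_grm(ds)
        vc, fit = mlma.reml_fit(y, G)
        res = mlma.assoc_scan(y, ds, fit)
        flipped = ds.subset_snps(np.ones(30, dtype=bool))
        flipped.dosages[:] = 2.0 - flipped.dosages
        res2 = mlma.assoc_scan(y, flipped, fit)
        np.testing.assert_allclose(res2["beta"], -res["beta"], atol=1e-10)
        np.testing.assert_allclose(res2["se"], res["se"], atol=1e-10)
        np.testing.assert_allclose(res2["p"], res["p"], atol=1e-10)

    def test_eigen_route_matches_direct_inverse(self):
        rng = np.random.default_rng(81)
        n = 60
        ds = hwe_dataset(rng, n, 80)
        G = grm.compute_grm(ds)
        y = rng.standard_normal(n)
        vc, fit = mlma.reml_fit(y, G)
        beta, se = lmm.gls_scan(y, ds.dosages, fit.ctx, fit.sigma_u2,
                                fit.sigma_e2)
        V = fit.sigma_u2 * G + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        for j in range(6):
            X = np.column_stack([np.ones(n), ds.dosages[:, j]])
            XtViX = X.T @ Vi @ X
            bhat = np.linalg.solve(XtViX, X.T @ Vi @ y)
            cov = np.linalg.inv(XtViX)
            assert beta[j] == pytest.approx(bhat[1], rel=1e-8)
            assert se[j] == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-8)


class TestSexStratified:
    def test_intersection_matches_set_oracle(self, small_cohort):
        cfg, dataset, effects, frame = small_cohort
        frame = frame.copy()
        frame["adjusted"] = frame[cfg.trait]
        res = mlma.run_sex_stratified(dataset, frame, maf_floor=0.0,
                                      min_stratum_n=10)
        male_set = set(res["male"]["snp"])
        female_set = set(res["female"]["snp"])
        # brute-force per-stratum segregation check
        is_male = (frame["sex"] == "male").to_numpy()
        coded = mlma.code_x_dosages(dataset, is_male)
        for sex, mask, got in (("male", is_male, male_set),
                               ("female", ~is_male, female_set)):
            dos = coded.dosages[mask]
            freqs = np.nanmean(dos, axis=0) / 2
            seg = {coded.snps.loc[j, "snp"]
                   for j in range(coded.n_snps) if 0 < freqs[j] < 1}
            assert got == seg

    def test_monomorphic_in_one_sex_only_in_other_results(self):
        rng = np.random.default_rng(90)
        n = 80
        ds = hwe_dataset(rng, n, 40)
        ds.dosages[n // 2:, 0] = 0.0  # monomorphic in females only
        frame = pd.DataFrame({
            "animal_id": ds.samples,
            "sex": ["male"] * (n // 2) + ["female"] * (n // 2),
            "adjusted": rng.standard_normal(n),
        })
        res = mlma.run_sex_stratified(ds, frame, maf_floor=0.0,
                                      min_stratum_n=10)
        assert "s0" in set(res["male"]["snp"])
        assert "s0" not in set(res["female"]["snp"])

    def test_identical_cohorts_identical_effects(self):
        rng = np.random.default_rng(91)
        n = 60
        ds_half = hwe_dataset(rng, n, 40)
        dos = np.vstack([ds_half.dosages, ds_half.dosages])
        ds = GenotypeDataset(dosages=dos, snps=ds_half.snps,
                             samples=[f"m{i}" for i in range(n)]
                                     + [f"f{i}" for i in range(n)])
        y_half = rng.standard_normal(n)
        frame = pd.DataFrame({
            "animal_id": ds.samples,
            "sex": ["male"] * n + ["female"] * n,
            "adjusted": np.r_[y_half, y_half],
        })
        res = mlma.run_sex_stratified(ds, frame, maf_floor=0.0,
                                      min_stratum_n=10)
        merged = res["male"].merge(res["female"], on="snp",
                                   suffixes=("_m", "_f"))
        np.testing.assert_allclose(merged["beta_m"], merged["beta_f"],
                                   atol=1e-10)

    def test_small_stratum_raises(self):
        rng = np.random.default_rng(92)
        ds = hwe_dataset(rng, 40, 20)
        frame = pd.DataFrame({
            "animal_id": ds.samples,
            "sex": ["male"] * 38 + ["female"] * 2,
            "adjusted": rng.standard_normal(40),
        })
        with pytest.raises(ValueError, match="stratum"):
            mlma.run_sex_stratified(ds, frame, min_stratum_n=10)
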