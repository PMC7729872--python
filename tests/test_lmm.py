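"""Mixed-model machinery: HWE, LD pruning, GRM, REML, score scan."""

import math

import numpy as np
import pytest
from scipy import stats

from pqtlkit import lmm, simulate
from pqtlkit.lmm import GRM, hwe_exact_test

from conftest import make_cohort


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p: enumerate every heterozygote count
    consistent with the allele counts and sum probabilities <= observed."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)

    def prob(het):
        from fractions import Fraction

        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        num = math.factorial(n) * 2**het * math.factorial(n_minor) * math.factorial(2 * n - n_minor)
        den = (
            math.factorial(hom_minor) * math.factorial(het) * math.factorial(hom_major)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    hets = range(n_minor % 2, n_minor + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[min(n_Aa, n_minor)]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_equilibrium_configuration_near_one(self):
        assert hwe_exact_test(25, 50, 25) > 0.9

    @pytest.mark.parametrize("counts", [(50, 0, 50), (30, 20, 10), (5, 5, 5), (98, 1, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestLdPrune:
    def test_unlinked_variants_all_retained(self):
        rng = np.random.default_rng(0)
        c = make_cohort(rng.binomial(2, 0.4, size=(300, 6)).astype(float))
        kept = lmm.ld_prune(c, r2_max=0.2, window_bp=10_000_000)
        assert len(kept) == 6

    def test_duplicated_variant_keeps_one(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, size=(200, 1)).astype(float)
        c = make_cohort(np.hstack([g, g, rng.binomial(2, 0.4, size=(200, 1)).astype(float)]))
        kept = lmm.ld_prune(c, r2_max=0.5, window_bp=10_000_000)
        assert len(kept) == 2
        assert "v0" in kept and "v2" in kept

    def test_matches_greedy_positional_oracle(self):
        rng = np.random.default_rng(2)
        n, m = 400, 10
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        # correlate neighbours by blending columns
        for j in range(1, m):
            mix = rng.random(n) < 0.6
            base[mix, j] = base[mix, j - 1]
        c = make_cohort(base)
        r2_max, window = 0.2, 5_000
        kept = lmm.ld_prune(c, r2_max=r2_max, window_bp=window)
        # independent greedy trace
        X = base - base.mean(axis=0)
        X /= X.std(axis=0)
        expected = []
        for j in range(m):
            pos_j = 1000 * (j + 1)
            ok = True
            for k in expected:
                if abs(pos_j - 1000 * (k + 1)) <= window and (X[:, j] @ X[:, k] / n) ** 2 > r2_max:
                    ok = False
                    break
            if ok:
                expected.append(j)
        assert kept == [f"v{j}" for j in expected]


class TestGrm:
    def test_duplicated_samples_match_diagonal(self, pool):
        c = simulate.simulate_cohort(pool, n=80, seed=30)
        dup = np.vstack([c.dosages, c.dosages[:1]])
        import pandas as pd

        samples = pd.concat([c.samples, c.samples.iloc[[0]].assign(id="DUP")], ignore_index=True)
        from pqtlkit.simulate import Cohort

        c2 = Cohort(dup, c.variants, samples, None)
        grm = lmm.compute_grm(c2)
        assert grm.matrix[0, 80] == pytest.approx(grm.matrix[0, 0], rel=1e-6)

    def test_unrelated_mean_near_zero_and_sibs_near_half(self, pool):
        c = simulate.simulate_cohort(pool, n=200, n_families=20, seed=31)
        grm = lmm.compute_grm(c)
        kt = c.kinship_truth
        assert abs(np.mean(grm.matrix[kt == 0.0])) < 0.02
        assert np.mean(grm.matrix[kt == 0.5]) == pytest.approx(0.5, abs=0.05)

    def test_sample_permutation_equivariance(self, pool):
        c = simulate.simulate_cohort(pool, n=60, seed=32)
        grm = lmm.compute_grm(c)
        perm = np.random.default_rng(33).permutation(60)
        c2 = c.subset_samples(c.samples["id"].iloc[perm])
        grm2 = lmm.compute_grm(c2)
        np.testing.assert_allclose(grm2.matrix, grm.matrix[np.ix_(perm, perm)], atol=1e-10)

    def test_trace_normalisation(self, cohort):
        grm = lmm.compute_grm(cohort)
        assert np.trace(grm.matrix) / cohort.n_samples == pytest.approx(1.0, abs=0.1)


def reml_loglik_oracle(y, W, K, lam):
    """Independent dense REML log-likelihood at variance ratio lam
    (up to the same additive constant used by the implementation)."""
    n, c = W.shape
    V = lam * K + np.eye(n)
    Vi = np.linalg.inv(V)
    WVW = W.T @ Vi @ W
    P = Vi - Vi @ W @ np.linalg.inv(WVW) @ W.T @ Vi
    yPy = y @ P @ y
    _, ldV = np.linalg.slogdet(V)
    _, ldW = np.linalg.slogdet(WVW)
    return -0.5 * (ldV + ldW + (n - c) * np.log(yPy))


class TestReml:
    def test_null_heritability_estimated_near_zero(self, pool):
        c = simulate.simulate_cohort(pool, n=150, n_families=30, seed=34)
        grm = GRM(matrix=c.kinship_truth, n_variants_used=0, samples=list(c.samples["id"]))
        y = np.random.default_rng(35).standard_normal(150)
        vc = lmm.reml_fit(y, None, grm)
        assert vc.h2 < 0.15

    def test_optimum_beats_dense_grid_oracle(self, pool):
        rng = np.random.default_rng(36)
        c = simulate.simulate_cohort(pool, n=120, n_families=40, seed=37)
        K = c.kinship_truth
        L = np.linalg.cholesky(K + 1e-8 * np.eye(120))
        y = np.sqrt(0.5) * (L @ rng.standard_normal(120)) + np.sqrt(0.5) * rng.standard_normal(120)
        grm = GRM(matrix=K, n_variants_used=0, samples=list(c.samples["id"]))
        vc = lmm.reml_fit(y, None, grm)
        W = np.ones((120, 1))
        grid = [reml_loglik_oracle(y, W, K, 10.0**g) for g in np.linspace(-5, 5, 100)]
        assert vc.loglik_reml >= max(grid) - 1e-4
        if vc.lambda_ratio > 0:
            assert vc.loglik_reml == pytest.approx(
                reml_loglik_oracle(y, W, K, vc.lambda_ratio), abs=1e-6
            )

    def test_identity_grm_flagged_degenerate(self):
        n = 60
        grm = GRM(matrix=np.eye(n), n_variants_used=0, samples=[f"S{i}" for i in range(n)])
        y = np.random.default_rng(38).standard_normal(n)
        vc = lmm.reml_fit(y, None, grm)
        assert "identity" in vc.note
        assert vc.sigma_g2 + vc.sigma_e2 == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_heritability_recovery(self, pool):
        # infinitesimal trait at h2 = 0.4 recovered within +-0.1 on average
        h2hats = []
        for seed in range(6):
            c = simulate.simulate_cohort(pool, n=300, n_families=60, seed=40 + seed)
            cfg = simulate.EffectConfig(h2_poly=0.4)
            panel, _ = simulate.simulate_proteins(c, cfg, 12, seed=50 + seed)
            from pqtlkit import phenotypes

            prep = phenotypes.adjust_and_transform(phenotypes.censor_below_lod(panel), c.samples)
            y = prep["P000"].values.to_numpy()
            grm = lmm.compute_grm(c.subset_samples(prep["P000"].values.index))
            h2hats.append(lmm.reml_fit(y, None, grm).h2)
        assert np.mean(h2hats) == pytest.approx(0.4, abs=0.1)


class TestScoreScan:
    def test_identity_kinship_matches_ols_oracle(self, vc_identity):
        rng = np.random.default_rng(60)
        n, m = 250, 20
        G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        y = 0.3 * G[:, 0] + rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=0)
        c = make_cohort(G)
        tab = lmm.score_scan(y, c, vc_identity(n)).set_index("id")
        import statsmodels.api as sm

        for j in range(m):
            fit = sm.OLS(y, sm.add_constant(G[:, j])).fit()
            # the score scan uses known unit residual variance; OLS estimates
            # it, so betas agree exactly and ses agree up to that factor
            assert tab.loc[f"v{j}", "beta"] == pytest.approx(fit.params[1], rel=1e-6)
            sigma = np.sqrt(fit.mse_resid)
            assert tab.loc[f"v{j}", "se"] == pytest.approx(fit.bse[1] / sigma, rel=1e-6)

    def test_mac_filter_boundary(self, vc_identity):
        n = 200
        g9 = np.zeros((n, 1))
        g9[:9, 0] = 1.0  # MAC 9: filtered
        g10 = np.zeros((n, 1))
        g10[:10, 0] = 1.0  # MAC 10: kept
        c = make_cohort(np.hstack([g9, g10]))
        y = np.random.default_rng(61).standard_normal(n)
        tab = lmm.score_scan(y, c, vc_identity(n))
        assert tab["id"].tolist() == ["v1"]

    def test_null_scan_lambda_gc_calibrated(self, vc_identity):
        rng = np.random.default_rng(62)
        n, m = 300, 5000
        G = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
        c = make_cohort(G, positions=np.arange(1, m + 1) * 100)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        tab = lmm.score_scan(y, c, vc_identity(n))
        lam, ok = lmm.genomic_control(tab)
        assert 0.9 <= lam <= 1.1
        # uniform p-values overall
        assert stats.kstest(tab["p"], "uniform").pvalue > 1e-3

    def test_score_and_wald_pvalues_agree_for_moderate_effects(self, vc_identity):
        rng = np.random.default_rng(63)
        n, m = 300, 40
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.standard_normal(n)
        c = make_cohort(G)
        tab = lmm.score_scan((y - y.mean()) / y.std(), c, vc_identity(n))
        z = tab["beta"] / tab["se"]
        wald_p = 2 * stats.norm.sf(np.abs(z))
        sel = np.abs(z) < 3
        log_ratio = np.abs(np.log10(tab["p"][sel]) - np.log10(wald_p[sel]))
        assert (log_ratio <= 0.1 * np.abs(np.log10(tab["p"][sel]))).all()


class TestGenomicControl:
    def test_reference_median_gives_unity(self):
        import pandas as pd

        p = np.full(200, stats.chi2.sf(lmm.CHI2_MEDIAN, 1))
        lam, ok = lmm.genomic_control(pd.DataFrame({"p": p}))
        assert lam == pytest.approx(1.0, abs=1e-6)
        assert ok

    def test_doubled_statistics_fail_gate(self):
        import pandas as pd

        p = np.full(200, stats.chi2.sf(2 * lmm.CHI2_MEDIAN, 1))
        lam, ok = lmm.genomic_control(pd.DataFrame({"p": p}))
        assert lam == pytest.approx(2.0, abs=1e-6)
        assert not ok

    def test_uniform_pvalues_calibrated(self):
        import pandas as pd

        p = np.random.default_rng(64).uniform(size=10_000)
        lam, _ = lmm.genomic_control(pd.DataFrame({"p": p}))
        assert 0.95 <= lam <= 1.05
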