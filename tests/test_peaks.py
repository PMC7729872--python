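"""Peak extraction, clumping and approximate conditional/joint selection."""

import numpy as np
import pandas as pd
import pytest

from pqtlkit import lmm, peaks
from pqtlkit.peaks import LDSource, clump, cojo_select, conditional_scan, extract_signals

from conftest import make_cohort


def _assoc(ids, pos, p, beta=None, chrom="1", n=500):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": ids,
            "ea": "G",
            "oa": "A",
            "maf": 0.3,
            "mac": 100,
            "miss": 0.0,
            "beta": beta if beta is not None else np.ones(len(ids)),
            "se": 0.1,
            "p": p,
            "n": n,
        }
    )


def _ld_cohort(seed=0, n=500, m=6, rho_pairs=()):
    """Cohort with explicit correlated columns: rho_pairs = [(j, k, share)]."""
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    for j, k, share in rho_pairs:
        mix = rng.random(n) < share
        G[mix, k] = G[mix, j]
    return make_cohort(G, positions=[100_000 * (j + 1) for j in range(m)])


class TestExtractSignals:
    def test_single_significant_variant_is_its_own_signal(self):
        c = _ld_cohort()
        ld = LDSource(c)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"], [1e-9, 0.5, 0.5, 0.5, 0.5, 0.5])
        sig = extract_signals(assoc, threshold=1e-8, ld_source=ld)
        assert len(sig) == 1
        assert sig[0].index_variant == "v0"
        assert sig[0].members == ["v0"]

    def test_correlated_pair_collapses_to_one_signal(self):
        c = _ld_cohort(rho_pairs=[(0, 1, 0.95)])
        ld = LDSource(c)
        assert ld.r2("v0", "v1") > 0.8
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"], [1e-9, 1e-8, 0.5, 0.5, 0.5, 0.5])
        sig = extract_signals(assoc, threshold=1e-6, ld_source=ld)
        assert len(sig) == 1
        assert sig[0].index_variant == "v0"
        assert set(sig[0].members) == {"v0", "v1"}

    def test_hand_traced_six_variant_fixture(self):
        # v0 best p; v1 in LD with v0 (removed); v2 independent, 1 Mb from v0
        # (grouped with v0); v3 independent but 5 Mb away (own signal);
        # v4 in LD with v3 (removed); v5 not significant.
        c = _ld_cohort(seed=1, rho_pairs=[(0, 1, 0.9), (3, 4, 0.9)])
        c.variants["pos"] = [1_000_000, 1_050_000, 2_000_000, 7_000_000, 7_050_000, 9_000_000]
        c.variants["pos"] = c.variants["pos"].astype(int)
        ld = LDSource(c)
        assoc = _assoc(
            [f"v{j}" for j in range(6)],
            c.variants["pos"],
            [1e-12, 1e-10, 1e-9, 1e-11, 1e-9, 0.9],
        )
        sig = extract_signals(assoc, threshold=1e-8, ld_source=ld)
        assert len(sig) == 2
        first, second = sig
        assert first.index_variant == "v0" and set(first.members) == {"v0", "v1", "v2"}
        assert second.index_variant == "v3" and set(second.members) == {"v3", "v4"}

    def test_row_order_invariance(self):
        c = _ld_cohort(seed=2, rho_pairs=[(0, 1, 0.9)])
        ld = LDSource(c)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"],
                       [1e-12, 1e-10, 1e-9, 1e-11, 1e-9, 0.9])
        a = extract_signals(assoc, 1e-8, ld_source=ld)
        b = extract_signals(assoc.sample(frac=1, random_state=3), 1e-8, ld_source=ld)
        assert [(s.index_variant, tuple(s.members)) for s in a] == [
            (s.index_variant, tuple(s.members)) for s in b
        ]

    def test_signal_count_monotone_in_threshold(self):
        c = _ld_cohort(seed=4)
        ld = LDSource(c)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"],
                       [1e-12, 1e-10, 1e-9, 1e-7, 1e-6, 0.9])
        counts = [len(extract_signals(assoc, thr, ld_source=ld)) for thr in (1e-11, 1e-8, 1e-5)]
        assert counts == sorted(counts)

    def test_empty_below_threshold(self):
        c = _ld_cohort(seed=5)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"], np.full(6, 0.5))
        assert extract_signals(assoc, 1e-8, ld_source=LDSource(c)) == []


class TestClump:
    def test_unlinked_all_retained(self):
        c = _ld_cohort(seed=6)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"], np.linspace(1e-8, 1e-4, 6))
        kept = clump(assoc, LDSource(c), r2=0.1, window_bp=1_000_000)
        assert set(kept) == {f"v{j}" for j in range(6)}

    def test_moderate_ld_pair_within_window_collapses(self):
        c = _ld_cohort(seed=7, rho_pairs=[(0, 1, 0.5)])
        ld = LDSource(c)
        assert 0.1 < ld.r2("v0", "v1") < 0.9
        assoc = _assoc(["v0", "v1"], [100_000, 600_000], [1e-8, 1e-6])
        kept = clump(assoc, ld, r2=0.1, window_bp=1_000_000)
        assert kept == ["v0"]

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(8)
        n, m = 600, 8
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        for j, k in [(0, 1), (2, 3), (4, 5)]:
            mix = rng.random(n) < rng.uniform(0.3, 0.9)
            G[mix, k] = G[mix, j]
        pos = [100_000 * (j + 1) for j in range(m)]
        c = make_cohort(G, positions=pos)
        ld = LDSource(c)
        p = rng.uniform(1e-10, 1e-3, m)
        assoc = _assoc([f"v{j}" for j in range(m)], pos, p)
        kept = clump(assoc, ld, r2=0.1, window_bp=1_000_000)
        # independent greedy trace
        order = np.argsort(p, kind="stable")
        expected, removed = [], set()
        for j in order:
            if j in removed:
                continue
            expected.append(f"v{j}")
            for k in order:
                if k != j and k not in removed and abs(pos[k] - pos[j]) <= 1_000_000:
                    if ld.r2(f"v{j}", f"v{k}") > 0.1:
                        removed.add(k)
        assert kept == expected


class TestCojo:
    def _scan(self, c, y, ld=None):
        n = c.n_samples
        vc = lmm.VarianceComponents(0.0, 1.0, 0.0, 0.0, np.ones(n), np.eye(n), np.ones((n, 1)))
        return lmm.score_scan((y - y.mean()) / y.std(), c, vc)

    def test_linkage_equilibrium_joint_equals_marginal(self):
        rng = np.random.default_rng(9)
        n = 800
        G = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        y = 0.5 * G[:, 0] + 0.5 * G[:, 1] + rng.standard_normal(n)
        c = make_cohort(G, positions=[1_000_000, 50_000_000])
        tab = self._scan(c, y)
        jm = cojo_select(tab, LDSource(c), p_threshold=1e-4)
        assert set(jm.variant_ids) == {"v0", "v1"}
        t = tab.set_index("id")
        for vid, b in zip(jm.variant_ids, jm.beta):
            assert b == pytest.approx(t.loc[vid, "beta"], rel=0.05)

    def test_duplicate_of_top_variant_never_coselected(self):
        rng = np.random.default_rng(10)
        n = 600
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        G = np.hstack([g, g.copy()])
        y = 0.6 * g[:, 0] + rng.standard_normal(n)
        c = make_cohort(G)
        tab = self._scan(c, y)
        jm = cojo_select(tab, LDSource(c), p_threshold=1e-4)
        assert len(jm.variant_ids) == 1

    def test_joint_betas_match_exact_regression(self):
        rng = np.random.default_rng(11)
        n, m = 900, 5
        G = rng.binomial(2, 0.35, size=(n, m)).astype(float)
        mix = rng.random(n) < 0.5
        G[mix, 1] = G[mix, 0]  # correlated pair
        y = 1.0 * G[:, 0] + 0.8 * G[:, 1] + 0.9 * G[:, 3] + rng.standard_normal(n)
        c = make_cohort(G, positions=[200_000 * (j + 1) for j in range(m)])
        tab = self._scan(c, y)
        jm = cojo_select(tab, LDSource(c), p_threshold=1e-5)
        assert len(jm.variant_ids) >= 2
        idx = [int(v[1:]) for v in jm.variant_ids]
        X = np.column_stack([np.ones(n), G[:, idx]])
        ys = (y - y.mean()) / y.std()
        exact = np.linalg.lstsq(X, ys, rcond=None)[0][1:]
        np.testing.assert_allclose(jm.beta, exact, rtol=0.10)

    def test_orthonormal_limit_equals_thresholding(self):
        # independent standardized predictors: selection = marginal thresholding
        rng = np.random.default_rng(12)
        n, m = 1000, 6
        G = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = 0.35 * G[:, 0] + 0.30 * G[:, 2] + rng.standard_normal(n)
        c = make_cohort(G, positions=[10_000_000 * (j + 1) for j in range(m)])
        tab = self._scan(c, y)
        thr = 1e-6
        jm = cojo_select(tab, LDSource(c), p_threshold=thr)
        marginal = set(tab.loc[tab["p"] < thr, "id"])
        assert set(jm.variant_ids) == marginal


class TestConditionalScan:
    def test_conditioning_on_unlinked_variant_is_neutral(self):
        rng = np.random.default_rng(13)
        n = 700
        G = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        y = 0.5 * G[:, 0] + rng.standard_normal(n)
        c = make_cohort(G, positions=[1_000_000, 30_000_000, 60_000_000])
        vc = lmm.VarianceComponents(0.0, 1.0, 0.0, 0.0, np.ones(n), np.eye(n), np.ones((n, 1)))
        tab = lmm.score_scan((y - y.mean()) / y.std(), c, vc)
        cond = conditional_scan(tab, ["v2"], LDSource(c)).set_index("id")
        t = tab.set_index("id")
        assert cond.loc["v0", "beta_cond"] == pytest.approx(t.loc["v0", "beta"], rel=0.05)

    def test_perfect_proxy_is_fully_explained(self):
        rng = np.random.default_rng(14)
        n = 500
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        G = np.hstack([g, g.copy()])
        y = 0.6 * g[:, 0] + rng.standard_normal(n)
        c = make_cohort(G)
        vc = lmm.VarianceComponents(0.0, 1.0, 0.0, 0.0, np.ones(n), np.eye(n), np.ones((n, 1)))
        tab = lmm.score_scan((y - y.mean()) / y.std(), c, vc)
        cond = conditional_scan(tab, ["v0"], LDSource(c)).set_index("id")
        assert cond.loc["v1", "p_cond"] == 1.0

    def test_shadow_signal_dissolves_under_conditioning(self):
        rng = np.random.default_rng(15)
        n = 900
        g = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        shadow = g.copy()
        flip = rng.random(n) < 0.25
        shadow[flip, 0] = rng.binomial(2, 0.4, size=int(flip.sum()))
        G = np.hstack([g, shadow, rng.binomial(2, 0.4, size=(n, 1)).astype(float)])
        y = 0.6 * g[:, 0] + rng.standard_normal(n)
        c = make_cohort(G)
        vc = lmm.VarianceComponents(0.0, 1.0, 0.0, 0.0, np.ones(n), np.eye(n), np.ones((n, 1)))
        tab = lmm.score_scan((y - y.mean()) / y.std(), c, vc)
        t = tab.set_index("id")
        assert t.loc["v1", "p"] < 1e-8  # the shadow is marginally significant
        cond = conditional_scan(tab, ["v0"], LDSource(c)).set_index("id")
        assert cond.loc["v1", "p_cond"] > 0.05

    def test_missing_condition_variant_is_an_error(self):
        c = _ld_cohort(seed=16)
        assoc = _assoc([f"v{j}" for j in range(6)], c.variants["pos"], np.full(6, 0.5))
        with pytest.raises(KeyError):
            conditional_scan(assoc, ["nope"], LDSource(c))
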