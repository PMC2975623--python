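"""Association tests: encodings, logistic LRT, CMC, GWWS, batch surface."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import comb

from rareweight.association import (
    AssociationResults,
    RareVariantAssociation,
    TEST_ORDER,
    cmc_test,
    encode_fwbst,
    encode_fwcst,
    encode_st,
    gwws_test,
    logistic_burden_test,
    madsen_browning_weights,
    run_all_tests,
)
from rareweight.cohort import CaseControlSample, VariantPanel


class TestEncodings:
    g = np.array([[0, 1, 2], [0, 0, 0], [2, 0, 0]])

    def test_sum_encoding(self):
        np.testing.assert_array_equal(encode_st(self.g).values, [3, 0, 2])

    def test_continuous_weighting(self):
        s = encode_fwcst(self.g, np.array([0.5, 0.9, 1.0]))
        np.testing.assert_allclose(s.values, [2.9, 0.0, 1.0])

    def test_binary_weighting(self):
        s = encode_fwbst(self.g, np.array([0, 1, 1]))
        np.testing.assert_array_equal(s.values, [3, 0, 0])

    def test_unit_weights_recover_sum(self):
        np.testing.assert_array_equal(
            encode_fwcst(self.g, np.ones(3)).values, encode_st(self.g).values
        )
        np.testing.assert_array_equal(
            encode_fwbst(self.g, np.ones(3, dtype=int)).values,
            encode_st(self.g).values,
        )

    def test_zero_weights_zero_scores(self):
        assert (encode_fwcst(self.g, np.zeros(3)).values == 0).all()
        assert (encode_fwbst(self.g, np.zeros(3, dtype=int)).values == 0).all()

    def test_empty_rare_set_rejected(self):
        with pytest.raises(ValueError, match="no rare variants"):
            encode_st(np.empty((5, 0)))

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_fwcst(self.g, np.array([0.5]))

    def test_non_binary_weight_rejected(self):
        with pytest.raises(ValueError):
            encode_fwbst(self.g, np.array([0.0, 0.5, 1.0]))


def _null_dataset(rng, n=200, sites=15, freq=0.02):
    g = rng.binomial(2, freq, size=(n, sites))
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[: n // 2]] = 1
    return g, y


class TestLogisticBurdenTest:
    def test_constant_score_is_uninformative(self):
        scores = encode_st(np.ones((40, 1), dtype=int))
        y = np.array([0] * 20 + [1] * 20)
        res = logistic_burden_test(scores, y)
        assert res.p_value == 1.0
        assert "degenerate predictor" in res.diagnostics

    def test_separation_falls_back_to_firth(self):
        y = np.array([0] * 20 + [1] * 20)
        g = y.reshape(-1, 1)  # score perfectly tracks status
        res = logistic_burden_test(encode_st(g), y)
        assert "firth fallback" in res.diagnostics
        assert res.p_value < 1e-4

    def test_agrees_with_glm_deviance_oracle(self, rng):
        """LRT p equals the chi-square(1) tail of the GLM deviance drop."""
        g, y = _null_dataset(rng)
        x = rng.binomial(2, 0.3, size=(len(y), 2)).astype(float)
        s = encode_st(g)
        res = logistic_burden_test(s, y, x)

        X0 = sm.add_constant(x)
        X1 = sm.add_constant(np.column_stack([s.values, x]))
        d0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit().deviance
        d1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit().deviance
        p_oracle = stats.chi2.sf(d0 - d1, 1)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-8)

    def test_null_calibration(self, rng):
        """Rejection rate at alpha = 0.05 stays nominal under permuted labels."""
        hits = 0
        reps = 400
        for _ in range(reps):
            g, y = _null_dataset(rng, n=150, sites=10)
            if g.sum() == 0:
                continue
            res = logistic_burden_test(encode_st(g), y)
            hits += res.p_value <= 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            logistic_burden_test(
                encode_st(np.ones((3, 1), dtype=int)), np.array([0, 1, 1])
            )


def _fisher_enumeration(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (comb(row1, x, exact=True) * comb(row2, col1 - x, exact=True)
                / comb(n, col1, exact=True))

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestCMC:
    def test_identical_margins_give_p_one(self):
        g = np.zeros((200, 1), dtype=int)
        g[:5, 0] = 1
        g[100:105, 0] = 1
        y = np.array([1] * 100 + [0] * 100)
        res = cmc_test(g, y)
        assert res.p_value == 1.0
        assert "fisher path" in res.diagnostics

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 16, size=2)
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        g = np.zeros((n1 + n2, 1), dtype=int)
        g[:a, 0] = 1
        g[n1: n1 + c, 0] = 1
        y = np.array([1] * n1 + [0] * n2)
        res = cmc_test(g, y)
        expected = _fisher_enumeration([[a, n1 - a], [c, n2 - c]])
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_chisq_variant_available(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(1, 0.2, size=(200, 3))
        y = np.array([1] * 100 + [0] * 100)
        res = cmc_test(g, y, method="chisq")
        assert "chisq path" in res.diagnostics
        assert 0 <= res.p_value <= 1

    def test_hotelling_path_with_common_variants(self, rng):
        g = rng.binomial(2, 0.02, size=(300, 8))
        x = rng.binomial(2, 0.3, size=(300, 2)).astype(float)
        y = np.array([1] * 150 + [0] * 150)
        res = cmc_test(g, y, x)
        assert "hotelling path" in res.diagnostics
        assert res.df_or_k == 3
        assert 0 <= res.p_value <= 1

    def test_hotelling_matches_manual_f_transform(self, rng):
        g = rng.binomial(2, 0.05, size=(120, 5))
        x = rng.binomial(2, 0.4, size=(120, 1)).astype(float)
        y = np.array([1] * 60 + [0] * 60)
        res = cmc_test(g, y, x)
        v = np.column_stack([(g.sum(1) > 0).astype(float), x])
        v1, v2 = v[y == 1], v[y == 0]
        d = v1.mean(0) - v2.mean(0)
        sp = (59 * np.cov(v1.T) + 59 * np.cov(v2.T)) / 118
        t2 = 60 * 60 / 120 * d @ np.linalg.solve(sp, d)
        f = t2 * (120 - 2 - 1) / ((120 - 2) * 2)
        assert res.p_value == pytest.approx(stats.f.sf(f, 2, 117), rel=1e-9)

    def test_collinear_common_columns_dropped(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(1, 0.1, size=(100, 4))
        x = np.ones((100, 1))  # constant within both groups
        y = np.array([1] * 50 + [0] * 50)
        res = cmc_test(g, y, x)
        assert "dropped collinear columns" in res.diagnostics
        assert 0 <= res.p_value <= 1

    def test_no_rare_variants_rejected(self):
        with pytest.raises(ValueError):
            cmc_test(np.empty((10, 0)), np.array([0, 1] * 5))


class TestGWWS:
    def test_control_anchored_frequency(self):
        # no mutant alleles among 100 controls: q = 1/202
        g = np.zeros((200, 1))
        y = np.array([1] * 100 + [0] * 100)
        q, w = madsen_browning_weights(g, y)
        assert q[0] == pytest.approx(1 / 202)
        assert w[0] == pytest.approx(math.sqrt(200 * (1 / 202) * (201 / 202)))
        assert w[0] == pytest.approx(0.9926, abs=5e-4)

    def test_weights_grow_with_control_frequency(self):
        g = np.zeros((200, 2))
        g[100:150, 1] = 1  # 50 mutant alleles among controls at site 2
        y = np.array([1] * 100 + [0] * 100)
        q, w = madsen_browning_weights(g, y)
        assert q[1] > q[0]
        assert w[1] > w[0]

    def test_null_calibration(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            g, y = _null_dataset(rng, n=120, sites=8)
            res = gwws_test(g, y, k=200, rng=rng)
            hits += res.p_value <= 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps) + 0.015

    def test_z_approximation_tracks_raw_permutation_p(self, rng):
        """Normal tail of the permutation z matches the raw permutation p."""
        n = 120
        g = rng.binomial(2, 0.05, size=(n, 10))
        burden = g.sum(1)
        y = (burden + rng.normal(0, 2.2, n) > np.median(burden)).astype(int)
        if y.sum() in (0, n):
            pytest.skip("degenerate labelling")
        k = 3000
        res = gwws_test(g, y, k=k, rng=rng)
        # raw two-sided permutation p from an independent run
        q, w = madsen_browning_weights(g, y)
        gamma = g @ (1.0 / w)
        obs = stats.rankdata(gamma)[y == 1].sum()
        perms = np.empty(k)
        for i in range(k):
            perm_y = rng.permutation(y)
            q, w = madsen_browning_weights(g, perm_y)
            gamma = g @ (1.0 / w)
            perms[i] = stats.rankdata(gamma)[perm_y == 1].sum()
        centered = abs(obs - perms.mean())
        p_raw = (1 + (np.abs(perms - perms.mean()) >= centered).sum()) / (k + 1)
        if not 0.01 <= p_raw <= 0.5:
            pytest.skip("outside the moderate-p comparison band")
        se = math.sqrt(p_raw * (1 - p_raw) / k)
        assert abs(res.p_value - p_raw) < 5 * se + 0.02

    def test_requires_permutations(self):
        with pytest.raises(ValueError):
            gwws_test(np.ones((10, 1)), np.array([0, 1] * 5), k=0)


def _panel_for(sample_genotypes, rng, with_measures=True):
    n_sites = sample_genotypes.shape[1]
    panel = VariantPanel(freqs=np.full(n_sites, 0.003))
    panel.causative = rng.random(n_sites) < 0.3
    if with_measures:
        panel.functional_binary = rng.integers(0, 2, n_sites).astype(np.int8)
        panel.functional_score = rng.random(n_sites)
    return panel


class TestRunAllTests:
    def test_five_results_in_canonical_order(self, simulated_sample):
        results = run_all_tests(simulated_sample, k=200, seed=5)
        assert [r.test for r in results] == list(TEST_ORDER)
        for r in results:
            assert 0 <= r.p_value <= 1

    def test_fwbst_equals_st_under_unit_calls(self, rng):
        g = rng.binomial(2, 0.02, size=(200, 6))
        y = np.array([1] * 100 + [0] * 100)
        panel = _panel_for(g, rng)
        panel.functional_binary = np.ones(6, dtype=np.int8)
        sample = CaseControlSample(genotypes=g, status=y, panel=panel)
        res = {r.test: r for r in run_all_tests(sample, k=50, seed=1)}
        assert res["FWBST"].p_value == pytest.approx(res["ST"].p_value, abs=1e-12)

    def test_no_common_variants_takes_fisher_path(self, rng):
        g = rng.binomial(2, 0.002, size=(200, 6))
        y = np.array([1] * 100 + [0] * 100)
        panel = _panel_for(g, rng)
        sample = CaseControlSample(genotypes=g, status=y, panel=panel)
        res = {r.test: r for r in run_all_tests(sample, k=50, seed=1)}
        assert "fisher path" in res["CMC"].diagnostics

    def test_deterministic_under_seed(self, simulated_sample):
        a = run_all_tests(simulated_sample, k=100, seed=9)
        b = run_all_tests(simulated_sample, k=100, seed=9)
        assert [r.p_value for r in a] == [r.p_value for r in b]

    def test_missing_measures_fail_softly(self, rng):
        g = rng.binomial(2, 0.02, size=(100, 4))
        y = np.array([1] * 50 + [0] * 50)
        panel = _panel_for(g, rng, with_measures=False)
        sample = CaseControlSample(genotypes=g, status=y, panel=panel)
        results = run_all_tests(sample, k=50, seed=1)
        by_name = {r.test: r for r in results}
        assert math.isnan(by_name["FWCST"].p_value)
        assert any("error" in d for d in by_name["FWCST"].diagnostics)
        assert 0 <= by_name["ST"].p_value <= 1  # batch continues


class TestModelSurface:
    def test_fit_returns_results_with_summary(self, simulated_sample):
        model = RareVariantAssociation.from_sample(simulated_sample)
        res = model.fit(k=100, seed=3)
        assert isinstance(res, AssociationResults)
        assert set(res.pvalues.index) == set(TEST_ORDER)
        text = res.summary()
        for name in TEST_ORDER:
            assert name in text
        frame = res.to_frame()
        assert list(frame["test"]) == list(TEST_ORDER)

    def test_from_dataframe_constructor(self, rng):
        import pandas as pd

        g = rng.binomial(2, 0.02, size=(120, 5))
        y = np.array([1] * 60 + [0] * 60)
        panel = _panel_for(g, rng)
        df = pd.DataFrame(g, columns=[f"v{i}" for i in range(5)])
        model = RareVariantAssociation.from_dataframe(df, y, panel)
        res = model.fit(tests=("ST",), k=10)
        assert 0 <= res.pvalues["ST"] <= 1
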