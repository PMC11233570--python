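import numpy as np
import pandas as pd
import pytest

from gaitdyn.reliability_stats import (StatsError, hedges_g_paired, icc_3k,
                                       koo_li_band, pearson_correlations,
                                       sdd_from_sem)


class TestHedgesG:
    def test_no_effect_identical(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        es = hedges_g_paired(x, x, n_boot=200, seed=0)
        assert es.g == 0.0
        assert es.ci_low == 0.0 and es.ci_high == 0.0

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.3, 0.5, 40)
        gxy = hedges_g_paired(x, y, n_boot=10, seed=0).g
        gyx = hedges_g_paired(y, x, n_boot=10, seed=0).g
        assert gxy == -gyx

    def test_large_sample_analytic_limit(self):
        # known shift delta over known SD: g -> delta / SD
        rng = np.random.default_rng(2)
        n = 10_000
        delta, sd = 0.4, 1.0
        x = rng.normal(0, sd, n)
        y = x + delta + rng.normal(0, 0.1, n)
        es = hedges_g_paired(x, y, n_boot=10, seed=0)
        assert es.g == pytest.approx(delta / sd, abs=0.02)

    def test_small_sample_correction_applied(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = x + np.array([1.0, 1.2, 0.8, 1.0])
        es = hedges_g_paired(x, y, n_boot=10, seed=0)
        sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
        raw = np.mean(y - x) / np.sqrt((sx ** 2 + sy ** 2) / 2)
        j = 1 - 3 / (4 * 3 - 1)
        assert es.g == pytest.approx(j * raw, abs=1e-12)

    def test_complete_case_dropping(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 3.0, 4.0, np.nan, 6.0, 7.0])
        es = hedges_g_paired(x, y, n_boot=50, seed=0)
        assert es.n_pairs == 4

    def test_difference_standardizer_option(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0.5, 0.2, 30)
        g_avg = hedges_g_paired(x, y, n_boot=10, seed=0).g
        g_diff = hedges_g_paired(x, y, n_boot=10, seed=0,
                                 standardizer="difference").g
        assert g_diff > g_avg  # difference SD is small for correlated pairs

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = x + rng.normal(0.2, 0.6, 25)
        a = hedges_g_paired(x, y, n_boot=500, seed=42)
        b = hedges_g_paired(x, y, n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_pairs_errors(self):
        with pytest.raises(StatsError):
            hedges_g_paired([1.0, 2.0], [2.0, 3.0])

    def test_zero_variance_errors(self):
        with pytest.raises(StatsError):
            hedges_g_paired([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_ci_coverage_near_nominal(self):
        # percentile bootstrap, level 0.95, n=200: empirical coverage
        # must sit within +-3% of nominal over 1000 replicates
        delta, reps, n = 0.5, 1000, 200
        rng = np.random.default_rng(0)
        hits = 0
        for i in range(reps):
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, np.sqrt(0.75), n) + delta
            es = hedges_g_paired(x, y, level=0.95, n_boot=1000, seed=i)
            hits += es.ci_low <= delta <= es.ci_high
        assert abs(hits / reps - 0.95) <= 0.03


class TestPearsonCorrelations:
    def test_self_correlation_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        table = pearson_correlations(df)
        row = table[(table.var1 == "a") & (table.var2 == "a")].iloc[0]
        assert row.r == 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(0, 1, 10_000),
                           "b": rng.normal(0, 1, 10_000)})
        row = pearson_correlations(df)
        r = row[(row.var1 == "a") & (row.var2 == "b")].iloc[0].r
        assert abs(r) < 0.03

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        table = pearson_correlations(df)
        row = table[(table.var1 == "a") & (table.var2 == "c")].iloc[0]
        assert row.flag == "constant column"
        assert np.isnan(row.r)

    def test_complete_case_n(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, 4, 5],
                           "b": [2.0, 4, 6, np.nan, 10]})
        table = pearson_correlations(df)
        row = table[(table.var1 == "a") & (table.var2 == "b")].iloc[0]
        assert row.n == 3


class TestIcc:
    def test_perfect_agreement(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        r = icc_3k(t, t, n_boot=100, seed=0)
        assert r.icc == pytest.approx(1.0)
        assert r.sem == 0.0 and r.sdd == 0.0
        assert r.band == "excellent"

    def test_null_simulation(self):
        rng = np.random.default_rng(0)
        iccs = [icc_3k(rng.normal(0, 1, 200), rng.normal(0, 1, 200),
                       n_boot=10, seed=0).icc for _ in range(100)]
        assert abs(np.mean(iccs)) < 0.05

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        t1 = rng.normal(0, 1, 30)
        t2 = 0.8 * t1 + rng.normal(0.1, 0.5, 30)
        ours = icc_3k(t1, t2, n_boot=10, seed=0).icc
        df = pd.DataFrame({"s": np.tile(np.arange(30), 2),
                           "j": np.repeat([0, 1], 30),
                           "y": np.concatenate([t1, t2])})
        table = pg.intraclass_corr(df, targets="s", raters="j", ratings="y")
        theirs = table.set_index("Type").loc["ICC(A,k)", "ICC"]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(2)
        t1 = rng.normal(0, 1, 25)
        t2 = t1 + rng.normal(0, 0.4, 25)
        a = icc_3k(t1, t2, n_boot=500, seed=7)
        b = icc_3k(t1, t2, n_boot=500, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_coverage_near_nominal(self):
        var_s, var_e = 1.0, 0.25
        true = var_s / (var_s + var_e / 2)
        rng = np.random.default_rng(0)
        hits = 0
        reps = 1000
        for i in range(reps):
            s = rng.normal(0, 1, 100)
            t1 = s + rng.normal(0, 0.5, 100)
            t2 = s + rng.normal(0, 0.5, 100)
            r = icc_3k(t1, t2, n_boot=1000, seed=i)
            hits += r.ci_low <= true <= r.ci_high
        assert abs(hits / reps - 0.95) <= 0.03

    def test_missing_subjects_dropped(self):
        t1 = np.array([1.0, 2, 3, 4, 5, np.nan, 7])
        t2 = np.array([1.1, 2.2, 2.9, 4.2, 5.1, 6.0, np.nan])
        r = icc_3k(t1, t2, n_boot=50, seed=0)
        assert r.n == 5

    def test_too_few_subjects_errors(self):
        with pytest.raises(StatsError):
            icc_3k([1.0, 2, 3, 4], [1.0, 2, 3, 4])

    def test_koo_li_bands(self):
        assert koo_li_band(0.3) == "poor"
        assert koo_li_band(0.6) == "moderate"
        assert koo_li_band(0.8) == "good"
        assert koo_li_band(0.95) == "excellent"


class TestSdd:
    def test_table_arithmetic_speed(self):
        sdd, rel = sdd_from_sem(0.028, 1.27)
        assert round(sdd, 3) == 0.078
        assert round(rel) == 6

    def test_zero_sem(self):
        sdd, rel = sdd_from_sem(0.0, 1.0)
        assert sdd == 0.0 and rel == 0.0

    def test_zero_mean_flagged(self):
        sdd, rel = sdd_from_sem(0.1, 0.0)
        assert sdd > 0 and np.isnan(rel)

    def test_negative_sem_errors(self):
        with pytest.raises(StatsError):
            sdd_from_sem(-0.1)
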