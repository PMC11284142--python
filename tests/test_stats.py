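import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import anova_mean_squares, icc_oracle, pearson_oracle
from tibtorsion import (
    CohortSpec,
    fisher_ci,
    icc,
    icc_band,
    paired_compare,
    pearson_with_ci,
    reliability_study,
    simulate_cohort,
    summarize,
)
from tibtorsion.stats import (
    InsufficientDataError,
    UndefinedCorrelationError,
    _mean_squares,
)


class TestSummarize:
    def test_basic_row(self):
        row = summarize([1, 2, 3], "PTTA")
        assert (row.mean, row.median, row.sd) == (2.0, 2.0, 1.0)
        assert (row.min, row.max, row.n, row.missing) == (1.0, 3.0, 3, 0)

    def test_normal_sample_takes_mean_sd_branch(self):
        rng = np.random.default_rng(7)
        row = summarize(rng.normal(17.2, 16.9, 200), "TA")
        assert row.normality_p > 0.05
        assert row.display == "mean_sd"

    def test_skewed_sample_takes_median_range_branch(self):
        rng = np.random.default_rng(7)
        row = summarize(np.exp(rng.normal(0, 1, 200)))
        assert row.display == "median_range"

    def test_constant_vector_is_degenerate(self):
        row = summarize([4.0, 4.0, 4.0, 4.0])
        assert row.sd == 0.0 and row.display == "degenerate"
        assert np.isnan(row.normality_p)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0, 2.0])

    @given(
        values=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
        c=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    def test_shift_and_permutation_properties(self, values, c, seed):
        arr = np.asarray(values)
        rng = np.random.default_rng(seed)
        base = summarize(arr)
        perm = summarize(rng.permutation(arr))
        assert perm.mean == pytest.approx(base.mean, abs=1e-9)
        assert perm.median == pytest.approx(base.median, abs=1e-9)
        shifted = summarize(arr + c)
        assert shifted.mean == pytest.approx(base.mean + c, abs=1e-6)
        assert shifted.median == pytest.approx(base.median + c, abs=1e-6)
        assert shifted.min == pytest.approx(base.min + c, abs=1e-6)
        assert shifted.max == pytest.approx(base.max + c, abs=1e-6)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-6)


class TestPairedCompare:
    def test_identical_series_degenerate(self):
        res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_name == "degenerate"
        assert res.mean_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_normal_differences_use_paired_t(self, rng):
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0.1, 0.5, 50)
        res = paired_compare(a, b)
        assert res.test_name == "paired-t"
        assert res.normality_p > 0.05

    def test_heavy_tailed_differences_use_wilcoxon(self, rng):
        a = rng.normal(0, 1, 60)
        b = a + rng.standard_cauchy(60)
        res = paired_compare(a, b)
        assert res.test_name == "wilcoxon-signed-rank"
        assert res.normality_p <= 0.05

    def test_recovers_simulated_fibular_offset(self):
        spec = CohortSpec(n_subjects=100, raters=1, sessions=1, seed=11)
        records, _ = simulate_cohort(spec).measure()
        ima = np.array([r.ima for r in records])
        ta = np.array([r.ta for r in records])
        res = paired_compare(ima, ta)
        assert res.p_value < 1e-3
        se = np.std(ima - ta, ddof=1) / np.sqrt(len(ima))
        assert abs(res.mean_difference - spec.fibular_offset_mean) < 3 * se


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 3 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_matches_product_moment_formula(self):
        a = [2.0, 4.0, 5.0, 7.0, 9.0]
        b = [1.0, 3.0, 2.0, 6.0, 8.0]
        res = pearson_with_ci(a, b)
        assert res.r == pytest.approx(pearson_oracle(a, b), abs=1e-12)

    def test_fisher_interval_reference_case(self):
        lo, hi = fisher_ci(0.95, 200)
        assert lo == pytest.approx(0.9361, abs=0.01)
        assert hi == pytest.approx(0.9631, abs=0.01)

    def test_interval_shrinks_with_n(self):
        widths = [np.diff(fisher_ci(0.8, n))[0] for n in (10, 50, 200, 1000)]
        assert all(w1 > w2 for w1, w2 in zip(widths[:-1], widths[1:], strict=True))

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])

    def test_coverage_of_true_correlation(self):
        # nominal 95% coverage within ±2% over 1,000 simulated samples
        true_r = 0.6
        rng = np.random.default_rng(99)
        cov = np.array([[1, true_r], [true_r, 1]])
        hits = 0
        n_sim, n = 1000, 50
        for _ in range(n_sim):
            x = rng.multivariate_normal([0, 0], cov, size=n)
            r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
            lo, hi = fisher_ci(r, n)
            hits += lo <= true_r <= hi
        assert abs(hits / n_sim - 0.95) < 0.02


class TestICC:
    SIX_BY_TWO = np.array(
        [[10.0, 12.0], [12.0, 14.0], [8.0, 10.0],
         [14.0, 16.0], [11.0, 13.0], [9.0, 11.0]]
    )

    def test_identical_columns(self):
        x = np.tile(np.array([[1.0], [5.0], [3.0], [9.0], [7.0]]), (1, 2))
        res = icc(x)
        assert res.estimate == 1.0 and res.band == "excellent"

    def test_constant_rater_offset_against_oracle(self):
        absolute = icc(self.SIX_BY_TWO, model="absolute")
        consistency = icc(self.SIX_BY_TWO, model="consistency")
        assert absolute.estimate < consistency.estimate
        assert consistency.estimate == pytest.approx(1.0)  # perfect consistency
        assert absolute.estimate == pytest.approx(
            icc_oracle(self.SIX_BY_TWO, "absolute"), abs=1e-9
        )
        assert consistency.estimate == pytest.approx(
            icc_oracle(self.SIX_BY_TWO, "consistency"), abs=1e-9
        )

    @pytest.mark.parametrize(
        "value, band",
        [(0.2, "poor"), (0.5, "moderate"), (0.6, "moderate"),
         (0.75, "moderate"), (0.8, "good"), (0.9, "good"), (0.95, "excellent")],
    )
    def test_band_cut_points(self, value, band):
        assert icc_band(value) == band

    @given(
        n=st.integers(5, 8), k=st.integers(2, 3), seed=st.integers(0, 10_000)
    )
    def test_matches_loop_anova_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 5, (n, 1)) + rng.normal(0, 1, (n, k))
        assert _mean_squares(x) == pytest.approx(anova_mean_squares(x), abs=1e-9)
        for model in ("absolute", "consistency"):
            assert icc(x, model=model).estimate == pytest.approx(
                icc_oracle(x, model), abs=1e-9
            )

    def test_matches_pingouin_estimates_and_intervals(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(0, 10, (12, 1)) + rng.normal(0, 2, (12, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        table = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        # single-measurement rows: index 1 = random/absolute, 2 = mixed/consistency
        absolute_row, consistency_row = table.iloc[1], table.iloc[2]
        ours_abs = icc(x, model="absolute")
        ours_con = icc(x, model="consistency")
        assert ours_abs.estimate == pytest.approx(absolute_row["ICC"], abs=1e-6)
        assert ours_con.estimate == pytest.approx(consistency_row["ICC"], abs=1e-6)
        # pingouin rounds its intervals to 2 decimals
        assert ours_abs.ci_low == pytest.approx(absolute_row["CI95"][0], abs=0.011)
        assert ours_abs.ci_high == pytest.approx(absolute_row["CI95"][1], abs=0.011)
        assert ours_con.ci_low == pytest.approx(consistency_row["CI95"][0], abs=0.011)
        assert ours_con.ci_high == pytest.approx(consistency_row["CI95"][1], abs=0.011)

    def test_missing_cells_rejected(self):
        x = self.SIX_BY_TWO.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc(x)


class TestReliabilityStudy:
    def test_noise_free_cohort_gives_perfect_icc(self):
        cohort = simulate_cohort(
            CohortSpec(n_subjects=25, rater_noise_sd=0.0, seed=2)
        )
        for design in ("intra", "inter"):
            for res in reliability_study(cohort, design, seed=0).values():
                assert res.estimate == pytest.approx(1.0)

    def test_default_noise_lands_in_excellent_band(self):
        cohort = simulate_cohort(CohortSpec(n_subjects=25, seed=13))
        intra = reliability_study(cohort, "intra", seed=13)
        assert 0.9 < intra["PTTA"].estimate <= 1.0
        assert intra["PTTA"].band == "excellent"

    def test_doubling_noise_decreases_every_icc(self):
        base = simulate_cohort(CohortSpec(n_subjects=25, seed=4))
        noisy = simulate_cohort(
            CohortSpec(n_subjects=25, rater_noise_sd=1.0, seed=4)
        )
        low = reliability_study(base, "intra", seed=1)
        high = reliability_study(noisy, "intra", seed=1)
        for method in low:
            assert high[method].estimate < low[method].estimate

    def test_unsupported_design_errors(self):
        cohort = simulate_cohort(
            CohortSpec(n_subjects=6, raters=1, sessions=1, seed=0)
        )
        with pytest.raises(ValueError, match="session"):
            reliability_study(cohort, "intra", n_images=5)
        with pytest.raises(ValueError, match="rater"):
            reliability_study(cohort, "inter", n_images=5)
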