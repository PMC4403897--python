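"""Cohort statistics: descriptives, tests, ICC, power and sample size."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from linguapress import (
    PowerSpec,
    anova_gender_adjusted_age,
    describe,
    icc_agreement,
    normality_screen,
    power_two_group_t,
    sample_size_two_group_t,
    t_test_from_summary,
    t_test_independent,
)


def exact_sample(mean, sd, n, rng):
    """A sample whose mean and SD (n-1) equal the targets exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestDescribe:
    @pytest.mark.parametrize(
        "mean, sd, n, lo, hi",
        [
            (573.74, 143.11, 16, 497.49, 650.00),   # male peak strength pressure
            (488.24, 108.96, 18, 434.06, 542.43),   # female peak strength pressure
            (556.20, 138.33, 16, 482.49, 629.91),   # male peak endurance pressure
            (539.80, 149.83, 18, 465.29, 614.31),   # female peak endurance pressure
        ],
    )
    def test_t_based_ci_reproduces_published_pairs(self, mean, sd, n, lo, hi, rng):
        d = describe(exact_sample(mean, sd, n, rng))
        assert d.mean == pytest.approx(mean, abs=1e-9)
        assert d.sd == pytest.approx(sd, abs=1e-9)
        assert d.ci95_low == pytest.approx(lo, abs=0.02)
        assert d.ci95_high == pytest.approx(hi, abs=0.02)

    def test_constant_vector_ci_collapses(self):
        d = describe([5.0, 5.0, 5.0, 5.0])
        assert d.sd == 0.0
        assert d.ci95_low == d.mean == d.ci95_high == 5.0

    def test_order_invariants(self, rng):
        d = describe(rng.lognormal(2.0, 0.6, 50), distribution_hint="skewed")
        assert d.ci95_low <= d.mean <= d.ci95_high
        assert d.iqr_low <= d.median <= d.iqr_high
        assert d.skewness > 0  # lognormal is right-skewed

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            describe([1.0])


class TestNormalityScreen:
    def test_symmetric_data_near_zero_skewness(self, rng):
        report = normality_screen(rng.normal(0, 1, 500))
        assert abs(report["skewness"]) < 0.3
        assert report["route"] == "parametric"

    def test_type_one_error_rate_near_alpha(self):
        """Shapiro-Wilk rejects ~5% of truly normal samples."""
        rng = np.random.default_rng(42)
        reps, n = 2000, 30
        rejections = sum(
            normality_screen(rng.normal(0, 1, n))["route"] == "nonparametric"
            for _ in range(reps)
        )
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(43)
        reps, n = 400, 30
        rejections = sum(
            normality_screen(rng.lognormal(0, 1, n))["route"] == "nonparametric"
            for _ in range(reps)
        )
        assert rejections / reps > 0.5

    def test_rejects_out_of_range_n(self):
        with pytest.raises(ValueError):
            normality_screen([1.0, 2.0])


class TestTTests:
    def test_identical_groups(self):
        res = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = t_test_independent([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "a, b, p_expected, tol",
        [
            ((573.74, 143.11, 16), (488.24, 108.96, 18), 0.057, 0.002),
            ((556.20, 138.33, 16), (539.80, 149.83, 18), 0.743, 0.005),
        ],
    )
    def test_published_summary_p_values(self, a, b, p_expected, tol):
        res = t_test_from_summary(*a, *b)
        assert res.p_value == pytest.approx(p_expected, abs=tol)
        assert res.df == a[2] + b[2] - 2

    def test_equal_summary_means(self):
        res = t_test_from_summary(10.0, 2.0, 8, 10.0, 3.0, 9)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_raw_equals_own_summaries(self, rng):
        a, b = rng.normal(5, 2, 12), rng.normal(6, 2, 15)
        raw = t_test_independent(a, b, variant="pooled")
        summ = t_test_from_summary(a.mean(), a.std(ddof=1), len(a),
                                   b.mean(), b.std(ddof=1), len(b))
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-10)

    def test_pooled_p_near_exhaustive_permutation_p(self, rng):
        """At n=5 per group the pooled-t p is close to the exact
        permutation p over all 252 group relabellings."""
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.2, 1.0, 5)
        obs = abs(t_test_independent(a, b).statistic)
        pool = np.concatenate([a, b])
        count = 0
        idx_all = set(range(10))
        for picks in combinations(range(10), 5):
            ga = pool[list(picks)]
            gb = pool[list(idx_all - set(picks))]
            if abs(sps.ttest_ind(ga, gb, equal_var=True).statistic) >= obs - 1e-12:
                count += 1
        p_perm = count / 252
        assert t_test_independent(a, b).p_value == pytest.approx(p_perm, abs=0.1)

    def test_welch_variant_available(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 10)
        res = t_test_independent(a, b, variant="welch")
        assert res.df != 18  # Welch-Satterthwaite df, not pooled


class TestAnova:
    def test_matches_normal_equations_on_fixture(self):
        """OLS coefficients agree with the closed-form solve on 10 rows."""
        values = np.array([520.0, 480, 455, 610, 395, 505, 590, 442, 515, 470])
        gender = ["male", "female"] * 5
        age = np.array([25.0, 31, 44, 29, 52, 38, 27, 45, 33, 40])
        res = anova_gender_adjusted_age(values, gender, age)
        is_male = np.array([g == "male" for g in gender], dtype=float)
        X = np.column_stack([np.ones(10), is_male, age])
        beta = np.linalg.solve(X.T @ X, X.T @ values)
        coefs = res.extra["coefficients"]
        assert coefs["Intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert coefs["C(gender)[T.male]"] == pytest.approx(beta[1], abs=1e-8)
        assert coefs["age"] == pytest.approx(beta[2], abs=1e-8)

    def test_f_approximates_t_squared_when_age_irrelevant(self, rng):
        n = 200
        gender = np.array(["male"] * (n // 2) + ["female"] * (n // 2))
        age = rng.uniform(18, 40, n)  # no effect on the outcome
        values = rng.normal(500, 100, n) + 80 * (gender == "male")
        res = anova_gender_adjusted_age(values, gender, age)
        t_res = t_test_independent(values[gender == "male"], values[gender == "female"])
        assert res.statistic == pytest.approx(t_res.statistic ** 2, rel=0.05)
        assert res.p_value == pytest.approx(t_res.p_value, abs=0.01)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        reps, n, rejections = 400, 40, 0
        gender = np.array(["male"] * 20 + ["female"] * 20)
        for _ in range(reps):
            values = rng.normal(500, 100, n)
            age = rng.uniform(18, 40, n)
            if anova_gender_adjusted_age(values, gender, age).p_value < 0.05 :
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_rejects_single_gender(self, rng):
        with pytest.raises(ValueError):
            anova_gender_adjusted_age([1.0, 2, 3, 4], ["male"] * 4, [20.0, 30, 40, 50])


class TestIcc:
    def test_identical_repeats_perfect_agreement(self):
        x = np.tile(np.linspace(300, 600, 10)[:, None], (1, 3))
        res = icc_agreement(x)
        assert res.icc == pytest.approx(1.0, abs=1e-9)
        assert res.interpretation.startswith("good")

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        x = 500.0 + rng.normal(0, 30, size=(200, 3))  # no subject variance
        assert abs(icc_agreement(x).icc) <= 0.1

    def test_recovers_variance_ratio(self):
        """With between-subject variance 3x within-subject, ICC -> 0.75."""
        rng = np.random.default_rng(6)
        n, k = 500, 2
        sigma_b, sigma_w = np.sqrt(3.0), 1.0
        subj = rng.normal(0, sigma_b, n)
        x = subj[:, None] + rng.normal(0, sigma_w, (n, k))
        res = icc_agreement(x)
        target = sigma_b ** 2 / (sigma_b ** 2 + sigma_w ** 2)
        assert res.icc == pytest.approx(target, abs=0.05)

    def test_matches_pingouin_icc2(self, rng):
        """Cross-check against the reference ICC2 (two-way random,
        absolute agreement, single rater) implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = 20, 3
        x = rng.normal(50, 10, (n, 1)) + rng.normal(0, 5, (n, k))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(x).icc == pytest.approx(icc2, abs=1e-9)

    def test_rejects_incomplete_or_tiny(self):
        with pytest.raises(ValueError):
            icc_agreement(np.ones((3, 2)))
        bad = np.ones((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            icc_agreement(bad)


SPEC = PowerSpec(mu1=573.74, mu2=488.24, common_sd=131.54, alpha=0.05)


class TestPower:
    def test_published_sample_sizes(self):
        assert sample_size_two_group_t(replace(SPEC, power_target=0.90)) == 51
        assert sample_size_two_group_t(replace(SPEC, power_target=0.80)) == 39

    def test_power_at_51_reaches_ninety_percent(self):
        assert power_two_group_t(replace(SPEC, n_per_group=51)) >= 0.90
        assert power_two_group_t(replace(SPEC, n_per_group=50)) < 0.90

    def test_null_power_equals_alpha(self):
        spec = PowerSpec(mu1=10.0, mu2=10.0, common_sd=2.0, n_per_group=30)
        assert power_two_group_t(spec) == pytest.approx(0.05, abs=1e-6)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.power import TTestIndPower

        ref = TTestIndPower().power(effect_size=85.5 / 131.54, nobs1=51,
                                    ratio=1.0, alpha=0.05, alternative="two-sided")
        assert power_two_group_t(replace(SPEC, n_per_group=51)) == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_n_and_delta(self):
        powers = [power_two_group_t(replace(SPEC, n_per_group=n)) for n in range(5, 120, 10)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        deltas = [power_two_group_t(PowerSpec(0.0, d, 131.54, n_per_group=40))
                  for d in (20, 50, 85.5, 150)]
        assert all(b >= a for a, b in zip(deltas, deltas[1:]))

    def test_sample_size_power_round_trip(self):
        for n in (20, 51, 80):
            achieved = power_two_group_t(replace(SPEC, n_per_group=n))
            assert sample_size_two_group_t(replace(SPEC, power_target=achieved * 0.999)) <= n

    def test_large_effect_matches_brute_force(self):
        spec = PowerSpec(mu1=20.0, mu2=0.0, common_sd=2.0, power_target=0.90)
        n = sample_size_two_group_t(spec)
        oracle = next(
            m for m in range(2, 50)
            if power_two_group_t(replace(spec, n_per_group=m)) >= 0.90
        )
        assert n == oracle

    def test_rejects_zero_delta_search(self):
        with pytest.raises(ValueError, match="infeasible"):
            sample_size_two_group_t(PowerSpec(5.0, 5.0, 1.0))
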