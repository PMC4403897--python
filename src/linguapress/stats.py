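"""Cohort statistics for tongue-pressure parameters.

Reproduces the statistical workflow of a gender-comparison pressure study:
normality screening (skewness, excess kurtosis, Shapiro-Wilk),
descriptives (mean/SD/t-based 95% CI alongside median/IQR — the screening
decides which block is headlined, both are always computed), pooled-
variance two-sample t-tests (from raw data or from published summary
statistics), an age-adjusted ANOVA for the gender effect, intraclass
correlation for test-retest reliability, and exact noncentral-t power and
sample-size calculations for a two-group design.

Defaults follow the conventions that reproduce the published analyses:
pooled-variance (not Welch) t-tests, ICC(A,1) (two-way random effects,
absolute agreement, single measure), linear-interpolation quantiles, and
an integer-increment sample-size search on the noncentral-t power curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "Descriptives",
    "TestResult",
    "PowerSpec",
    "ReliabilityResult",
    "describe",
    "normality_screen",
    "t_test_independent",
    "t_test_from_summary",
    "anova_gender_adjusted_age",
    "icc_agreement",
    "power_two_group_t",
    "sample_size_two_group_t",
]


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    median: float
    iqr_low: float
    iqr_high: float
    skewness: float
    excess_kurtosis: float
    headline: Literal["normal", "skewed"] = "normal"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str
    assumptions_note: str = ""
    extra: dict | None = None


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-sided two-group t-test power calculation.

    ``mu1``/``mu2`` are the group means, ``common_sd`` the assumed common
    standard deviation (all mmHg for pressure outcomes, but the units
    cancel), ``alpha`` the two-sided level and ``power_target`` the power
    the sample-size search must reach.
    """

    mu1: float
    mu2: float
    common_sd: float
    alpha: float = 0.05
    power_target: float = 0.90
    n_per_group: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must lie in (0, 1)")
        if self.common_sd <= 0:
            raise ValueError("common_sd must be positive")

    @property
    def delta(self) -> float:
        return abs(self.mu1 - self.mu2)


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    model_label: str
    n_subjects: int
    n_repeats: int
    interpretation: str


def describe(values, distribution_hint: Literal["normal", "skewed"] = "normal") -> Descriptives:
    """Descriptive statistics with both parametric and rank-based blocks.

    Mean, SD (n-1 denominator) and the t-based 95% CI are always computed,
    as are the median and linear-interpolation quartiles; the hint only
    selects which block a report headlines.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return Descriptives(
        n=n,
        mean=mean,
        sd=sd,
        ci95_low=mean - half,
        ci95_high=mean + half,
        median=float(med),
        iqr_low=float(q1),
        iqr_high=float(q3),
        skewness=float(stats.skew(x, bias=False)) if n > 2 and sd > 0 else 0.0,
        excess_kurtosis=float(stats.kurtosis(x, bias=False)) if n > 3 and sd > 0 else 0.0,
        headline=distribution_hint,
    )


def normality_screen(values, alpha_screen: float = 0.05) -> dict:
    """Skewness, excess kurtosis, Shapiro-Wilk, and a routing decision.

    The route is advisory: ``"parametric"`` iff the Shapiro-Wilk p-value
    exceeds ``alpha_screen``; downstream reports still carry both
    descriptive blocks.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk screening supports 3 <= n <= 5000")
    w, p = stats.shapiro(x)
    return {
        "n": len(x),
        "skewness": float(stats.skew(x, bias=False)),
        "excess_kurtosis": float(stats.kurtosis(x, bias=False)) if len(x) > 3 else float("nan"),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "alpha_screen": alpha_screen,
        "route": "parametric" if p > alpha_screen else "nonparametric",
    }


def t_test_independent(
    group_a, group_b, variant: Literal["pooled", "welch"] = "pooled"
) -> TestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        df = len(a) + len(b) - 2 if variant == "pooled" else float("nan")
        return TestResult(0.0, df, 1.0, f"t-test ({variant})",
                          "zero variance, equal means: p = 1 by convention")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        test_name=f"independent-samples t-test ({variant} variance)",
    )


def t_test_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> TestResult:
    """Pooled-variance t-test from published summary statistics."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("sds must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        df=float(n_a + n_b - 2),
        p_value=float(res.pvalue),
        test_name="independent-samples t-test (pooled, from summaries)",
    )


def anova_gender_adjusted_age(values, gender, age) -> TestResult:
    """Gender effect on an outcome, adjusting for age (type-II partial F).

    Fits ``value ~ gender + age`` by OLS and reports the type-II F and p
    for the gender term, plus its observed power at the estimated effect
    size (noncentral F with the fitted noncentrality, the convention of
    classical ANOVA software).
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "gender": pd.Categorical(gender),
        "age": np.asarray(age, dtype=float),
    })
    if len(df) < 4:
        raise ValueError("need n >= 4")
    if df["gender"].nunique() < 2:
        raise ValueError("both genders must be present")
    model = smf.ols("value ~ C(gender) + age", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("degenerate design: collinear predictors")
    table = sm.stats.anova_lm(model, typ=2)
    f = float(table.loc["C(gender)", "F"])
    p = float(table.loc["C(gender)", "PR(>F)"])
    df_num = float(table.loc["C(gender)", "df"])
    df_den = float(table.loc["Residual", "df"])
    fcrit = stats.f.ppf(0.95, df_num, df_den)
    observed_power = float(1 - stats.ncf.cdf(fcrit, df_num, df_den, f * df_num))
    return TestResult(
        statistic=f,
        df=(df_num, df_den),
        p_value=p,
        test_name="ANOVA gender effect adjusted for age (type II)",
        extra={
            "observed_power": observed_power,
            "coefficients": dict(model.params),
        },
    )


def icc_agreement(matrix) -> ReliabilityResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``matrix`` is subjects x repeats, complete. From the two-way mean
    squares (rows = subjects, columns = repeats/sessions)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Values >= 0.75 are conventionally read as good reliability.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be subjects x repeats")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 repeats")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete matrix: non-finite entries")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc = float(np.clip(icc, -1.0, 1.0))
    if icc >= 0.75:
        interpretation = "good (>= 0.75)"
    elif icc >= 0.5:
        interpretation = "moderate (0.50-0.75)"
    else:
        interpretation = "poor (< 0.50)"
    return ReliabilityResult(
        icc=icc,
        model_label="ICC(A,1) two-way random, absolute agreement, single measure",
        n_subjects=n,
        n_repeats=k,
        interpretation=interpretation,
    )


def power_two_group_t(spec: PowerSpec) -> float:
    """Exact power of the two-sided two-group t-test via the noncentral t.

    With ``n`` per group, ``df = 2n - 2`` and noncentrality
    ``|mu1 - mu2| / (sd * sqrt(2/n))``; power is the probability the
    |t| statistic exceeds the two-sided critical value.
    """
    if spec.n_per_group is None or spec.n_per_group < 2:
        raise ValueError("spec.n_per_group must be >= 2")
    n = spec.n_per_group
    df = 2 * n - 2
    nc = spec.delta / (spec.common_sd * np.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    power = (1 - stats.nct.cdf(tcrit, df, nc)) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)


def sample_size_two_group_t(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest per-group n whose exact power reaches ``spec.power_target``.

    Integer-increment search from n = 2 on the noncentral-t power curve
    (power is monotone in n, so the first hit is the answer).
    """
    if spec.delta == 0:
        raise ValueError("infeasible: zero mean difference never reaches the target power")
    if not spec.alpha < spec.power_target:
        raise ValueError("power_target must exceed alpha")
    from dataclasses import replace

    n = 2
    while n <= n_max:
        if power_two_group_t(replace(spec, n_per_group=n)) >= spec.power_target:
            return n
        n += 1
    raise RuntimeError(f"no n <= {n_max} reaches the target power")
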