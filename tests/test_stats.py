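"""Nonparametric tests, severity regressions, prediction and rater agreement."""

import numpy as np
import pytest

import spiraltremor as st
from spiraltremor.errors import (
    CollinearityError,
    DegenerateInputError,
    InvalidParameterError,
    SampleSizeError,
)
from spiraltremor.stats import ET_GROUPS

# ---------------------------------------------------------------------------
# Shapiro–Wilk
# ---------------------------------------------------------------------------


def test_shapiro_detects_heavy_tails(rng):
    """Power check: a contaminated-normal mixture is flagged non-Gaussian in
    at least 90% of seeded replicates at n = 50."""
    rejections = 0
    for _ in range(100):
        x = np.where(rng.random(50) < 0.15, rng.normal(0, 6, 50), rng.normal(0, 1, 50))
        rejections += st.shapiro_wilk(x).p_value < 0.05
    assert rejections >= 90


def test_shapiro_null_p_values_are_uniform(rng):
    """Type-I calibration: under Gaussian data the p-values are uniform."""
    from scipy import stats as ss

    ps = [st.shapiro_wilk(rng.normal(size=100)).p_value for _ in range(200)]
    assert ss.kstest(ps, "uniform").pvalue > 0.01


def test_shapiro_degenerate_and_small_inputs():
    with pytest.raises(DegenerateInputError):
        st.shapiro_wilk([2.0, 2.0, 2.0, 2.0])
    with pytest.raises(SampleSizeError):
        st.shapiro_wilk([1.0, 2.0])


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def _brute_force_min_u(a, b):
    wins_a = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
    return min(wins_a, len(a) * len(b) - wins_a)


def test_mann_whitney_full_separation_gives_zero():
    res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0


def test_mann_whitney_matches_pairwise_count_oracle(rng):
    for _ in range(20):
        a = rng.integers(0, 10, size=rng.integers(3, 9)).astype(float)
        b = rng.integers(0, 10, size=rng.integers(3, 9)).astype(float)
        assert st.mann_whitney_u(a, b).statistic == pytest.approx(
            _brute_force_min_u(a, b)
        )


def test_mann_whitney_identical_groups():
    x = [1.0, 2.0, 3.0, 4.0]
    res = st.mann_whitney_u(x, x)
    assert res.statistic == pytest.approx(len(x) ** 2 / 2)
    assert res.p_value == pytest.approx(1.0, abs=0.01)


def test_mann_whitney_is_symmetric(rng):
    a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 12)
    r1, r2 = st.mann_whitney_u(a, b), st.mann_whitney_u(b, a)
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_mann_whitney_exact_close_to_normal_approximation(rng):
    """Oracle cross-check at n = 7: exact enumeration and the tie-corrected
    normal approximation agree in p within 0.02."""
    from scipy import stats as ss

    for _ in range(20):
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 7)
        pe = ss.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        pa = ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(pe - pa) < 0.02
        assert min(pe, pa) - 1e-12 <= st.mann_whitney_u(a, b).p_value <= max(pe, pa) + 1e-12


def test_mann_whitney_empty_group():
    with pytest.raises(SampleSizeError):
        st.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def test_kruskal_matches_rank_formula():
    """Brute-force rank-formula oracle (no ties):
    H = 12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2."""
    groups = [[1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9]]
    n = 9
    rank_means = [2.0, 5.0, 8.0]
    h_oracle = 12.0 / (n * (n + 1)) * sum(
        3 * (rm - (n + 1) / 2) ** 2 for rm in rank_means
    )
    res = st.kruskal_wallis(groups)
    assert res.statistic == pytest.approx(h_oracle, abs=1e-9)


def test_kruskal_two_groups_consistent_with_mann_whitney(rng):
    """Asymptotic equivalence for k = 2."""
    for _ in range(10):
        a, b = rng.normal(0, 1, 10), rng.normal(0.6, 1, 12)
        pk = st.kruskal_wallis([a, b]).p_value
        pm = st.mann_whitney_u(a, b).p_value
        assert abs(pk - pm) < 0.03


def test_kruskal_degenerate_input():
    with pytest.raises(DegenerateInputError):
        st.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def test_univariate_recovers_published_sensor2_coefficients():
    """Noiseless recovery of the mid-forearm ratio-only model."""
    rho = np.array([0.5, 2.0, 4.0, 7.0, 11.0])
    y = 15.6031 + 1.7763 * rho
    m = st.fit_univariate(rho, y)
    assert m.intercept == pytest.approx(15.6031, abs=1e-6)
    assert m.coef_psd == pytest.approx(1.7763, abs=1e-6)
    assert m.r_squared == pytest.approx(1.0)
    assert m.rmse == pytest.approx(0.0, abs=1e-8)


def test_univariate_null_relationship(rng):
    rho = rng.uniform(0, 10, 200)
    y = rng.normal(20, 5, 200)
    assert st.fit_univariate(rho, y).r_squared < 0.05


def test_univariate_constant_predictor():
    with pytest.raises(CollinearityError):
        st.fit_univariate([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])


def test_bivariate_recovers_published_equation(rng):
    t = rng.uniform(5, 40, 17)
    rho = rng.uniform(0, 12, 17)
    y = 8.2439 + 0.2791 * t + 1.9890 * rho
    m = st.fit_bivariate(t, rho, y)
    assert m.intercept == pytest.approx(8.2439, abs=1e-6)
    assert m.coef_time == pytest.approx(0.2791, abs=1e-6)
    assert m.coef_psd == pytest.approx(1.9890, abs=1e-6)
    assert m.r_squared == pytest.approx(1.0)


def test_bivariate_collinear_predictors():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(CollinearityError):
        st.fit_bivariate(t, t, 2 * t)


def test_ols_residuals_orthogonal_to_predictors(rng):
    t = rng.uniform(5, 40, 30)
    rho = rng.uniform(0, 12, 30)
    y = 8.0 + 0.3 * t + 2.0 * rho + rng.normal(0, 5, 30)
    m = st.fit_bivariate(t, rho, y)
    resid = y - (m.intercept + m.coef_time * t + m.coef_psd * rho)
    scale = np.abs(y).sum()
    assert abs(resid @ t) < 1e-8 * scale * np.abs(t).max()
    assert abs(resid @ rho) < 1e-8 * scale * np.abs(rho).max()
    assert abs(resid.sum()) < 1e-8 * scale


def test_bivariate_r2_dominates_univariate(rng):
    t = rng.uniform(5, 40, 25)
    rho = rng.uniform(0, 12, 25)
    y = 8.0 + 0.3 * t + 2.0 * rho + rng.normal(0, 8, 25)
    r2_bi = st.fit_bivariate(t, rho, y).r_squared
    r2_uni = st.fit_univariate(rho, y).r_squared
    assert r2_bi >= r2_uni - 1e-12


def test_coefficient_bias_vanishes_with_noise(rng):
    """Parameter recovery: estimator bias shrinks as the residual SD -> 0."""
    truth = np.array([8.2439, 0.2791, 1.9890])
    biases = []
    for sd in (8.0, 0.1):
        ests = []
        for _ in range(100):
            t = rng.uniform(5, 40, 17)
            rho = rng.uniform(0, 12, 17)
            y = truth[0] + truth[1] * t + truth[2] * rho + rng.normal(0, sd, 17)
            m = st.fit_bivariate(t, rho, y)
            ests.append([m.intercept, m.coef_time, m.coef_psd])
        biases.append(np.abs(np.mean(ests, axis=0) - truth).max())
    assert biases[1] < biases[0]
    assert biases[1] < 0.05


# ---------------------------------------------------------------------------
# Prediction and rater agreement
# ---------------------------------------------------------------------------


def test_predict_ftm_intercept_and_negative_inputs():
    assert st.predict_ftm(st.PUBLISHED_MODEL, 0.0, 0.0) == pytest.approx(8.2439)
    with pytest.raises(InvalidParameterError):
        st.predict_ftm(st.PUBLISHED_MODEL, -1.0, 2.0)


def test_predict_ftm_clips_at_zero():
    m = st.SeverityModel(intercept=-5.0, coef_time=0.0, coef_psd=1.0)
    assert st.predict_ftm(m, 0.0, 1.0) == 0.0


def test_interrater_r2_affine_invariance(rng):
    a = rng.uniform(5, 60, 17)
    assert st.interrater_r2(a, a) == pytest.approx(1.0)
    assert st.interrater_r2(a, 2 * a + 3) == pytest.approx(1.0)


def test_interrater_r2_independent_raters_near_zero(rng):
    a, b = rng.normal(20, 8, 500), rng.normal(20, 8, 500)
    assert st.interrater_r2(a, b) < 0.05


def test_interrater_r2_constant_rater():
    with pytest.raises(DegenerateInputError):
        st.interrater_r2([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Group summary
# ---------------------------------------------------------------------------


def test_group_summary_schema(cohort_table):
    summary = st.group_summary(cohort_table)
    measures = set(summary["measure"])
    assert {"n", "psd_ratio_S1", "psd_ratio_S2", "psd_ratio_S3", "task_time",
            "clinical_ftm", "estimated_ftm_S2"} <= measures
    for g in ("control", "ET0", "ET1plus", "ET2plus"):
        assert f"{g}_mean" in summary.columns and f"{g}_sd" in summary.columns
    ns = summary.loc[summary["measure"] == "n"].iloc[0]
    assert [ns[f"{g}_mean"] for g in ("control", "ET0", "ET1plus", "ET2plus")] == [
        18, 6, 5, 6
    ]


def test_group_summary_estimated_ftm_uses_model_on_group_means(cohort_table):
    summary = st.group_summary(cohort_table)
    row = summary.loc[summary["measure"] == "estimated_ftm_S2"].iloc[0]
    s2 = cohort_table[cohort_table["site"] == "S2"]
    for g in ET_GROUPS:
        sub = s2[s2["group"] == g]
        expected = st.predict_ftm(
            st.PUBLISHED_MODEL, sub["task_time"].mean(), sub["psd_ratio"].mean()
        )
        assert row[f"{g}_mean"] == pytest.approx(expected)


def test_group_summary_identical_groups_rarely_significant(rng):
    """Null simulation: with all groups drawn from one distribution the
    Kruskal–Wallis row p-value exceeds 0.05 in >= 90% of replicates."""
    import pandas as pd

    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        rows = []
        for g, n in (("control", 9), ("ET0", 9)):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{g}{i}",
                        "group": g,
                        "site": "S2",
                        "psd_ratio": rng.uniform(0, 5),
                        "task_time": rng.uniform(8, 30),
                    }
                )
        summary = st.group_summary(pd.DataFrame(rows))
        p = summary.loc[summary["measure"] == "psd_ratio_S2", "kruskal_p"].iloc[0]
        hits += p > 0.05
    assert hits >= 0.9 * n_rep * 0.9  # 90% with a margin for the small n_rep
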