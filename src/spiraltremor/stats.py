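"""Statistical layer: group comparisons, severity regression, rater agreement.

Because tremor features in small clinical cohorts are typically non-Gaussian
(Shapiro–Wilk is run as a report-only check), group comparisons use
nonparametric tests throughout: Mann–Whitney U for two groups and
Kruskal–Wallis across the phenotype groups.

Severity estimation regresses the clinical Fahn–Tolosa–Marin (FTM) score on
the sensor features by ordinary least squares — per-site univariate fits on
the PSD ratio, and the bivariate model

    FTM_hat = b0 + b1 * T + b2 * rho

with T the task time (s) and rho the mid-forearm PSD ratio.  The published
bivariate model (fitted on 17 ET subjects) is available as
:data:`PUBLISHED_MODEL` with coefficients (8.2439, 0.2791, 1.9890),
r^2 = 0.561 and RMSE = 8.158 FTM points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .errors import (
    CollinearityError,
    DegenerateInputError,
    InvalidParameterError,
    SampleSizeError,
)

#: Upper bound of the FTM total scale; predictions and synthetic scores are
#: clipped to [0, FTM_MAX].
FTM_MAX = 144.0


@dataclass(frozen=True)
class SeverityModel:
    """OLS severity estimator FTM = b0 + b1*T + b2*rho.

    Univariate ratio-only fits store the slope in ``coef_psd`` with
    ``coef_time`` = 0.
    """

    intercept: float
    coef_time: float
    coef_psd: float
    r_squared: float = float("nan")
    rmse: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not np.isnan(self.rmse) and self.rmse < 0:
            raise InvalidParameterError("rmse must be non-negative")
        if not np.isnan(self.r_squared) and not (0 <= self.r_squared <= 1 + 1e-12):
            raise InvalidParameterError("r_squared must lie in [0, 1]")


#: The published bivariate severity model (17 ET subjects, mid-forearm sensor).
PUBLISHED_MODEL = SeverityModel(
    intercept=8.2439,
    coef_time=0.2791,
    coef_psd=1.9890,
    r_squared=0.561,
    rmse=8.158,
    n_obs=17,
)

#: Published per-site univariate models (FTM on PSD ratio alone).
PUBLISHED_UNIVARIATE = {
    "S1": SeverityModel(11.6747, 0.0, 3.5655, r_squared=0.3855, rmse=9.6476, n_obs=17),
    "S2": SeverityModel(15.6031, 0.0, 1.7763, r_squared=0.50, rmse=8.7891, n_obs=17),
    "S3": SeverityModel(18.2019, 0.0, 4.6912, r_squared=0.4184, rmse=9.3858, n_obs=17),
}


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise InvalidParameterError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def shapiro_wilk(values) -> StatResult:
    """Shapiro–Wilk normality check (report-only; the pipeline is
    nonparametric regardless of the outcome)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise SampleSizeError("Shapiro–Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro–Wilk is undefined for a constant vector")
    res = sstats.shapiro(x)
    return StatResult("shapiro_wilk", float(res.statistic), float(res.pvalue), (x.size,))


def mann_whitney_u(group_a, group_b) -> StatResult:
    """Two-sided Mann–Whitney U test.

    The reported statistic is min(U_a, U_b), the convention under which a
    fully separated pair of groups gives U = 0.  The p-value uses exact
    enumeration for small tie-free samples and the tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SampleSizeError("Mann–Whitney U needs two non-empty groups")
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u_a = float(res.statistic)
    u_b = a.size * b.size - u_a
    return StatResult(
        "mann_whitney_u", min(u_a, u_b), float(res.pvalue), (a.size, b.size)
    )


def kruskal_wallis(groups) -> StatResult:
    """Tie-corrected Kruskal–Wallis H test across k >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise SampleSizeError("Kruskal–Wallis needs at least 2 groups")
    if any(g.size == 0 for g in arrays):
        raise SampleSizeError("Kruskal–Wallis groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateInputError("all values identical; Kruskal–Wallis undefined")
    res = sstats.kruskal(*arrays)
    return StatResult(
        "kruskal_wallis",
        float(res.statistic),
        float(res.pvalue),
        tuple(g.size for g in arrays),
    )


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def _ols(design: np.ndarray, y: np.ndarray) -> sm.regression.linear_model.RegressionResults:
    return sm.OLS(y, design).fit()


def _rmse(resid: np.ndarray) -> float:
    # sqrt(SSE/n): the population convention, not the n-p estimator
    return float(np.sqrt(np.mean(resid**2)))


def fit_univariate(psd_ratios, ftm_scores) -> SeverityModel:
    """OLS of FTM on the PSD ratio alone (per-site severity model)."""
    x = np.asarray(psd_ratios, dtype=float)
    y = np.asarray(ftm_scores, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("predictor and response lengths differ")
    if x.size < 3:
        raise SampleSizeError("univariate fit needs at least 3 observations")
    if np.ptp(x) == 0:
        raise CollinearityError("PSD ratio is constant; slope is unidentifiable")
    res = _ols(sm.add_constant(x), y)
    return SeverityModel(
        intercept=float(res.params[0]),
        coef_time=0.0,
        coef_psd=float(res.params[1]),
        r_squared=float(res.rsquared),
        rmse=_rmse(np.asarray(res.resid)),
        n_obs=int(x.size),
    )


def fit_bivariate(task_times, psd_ratios, ftm_scores) -> SeverityModel:
    """OLS of FTM on task time and PSD ratio jointly (the severity model)."""
    t = np.asarray(task_times, dtype=float)
    rho = np.asarray(psd_ratios, dtype=float)
    y = np.asarray(ftm_scores, dtype=float)
    if not (t.size == rho.size == y.size):
        raise InvalidParameterError("predictor and response lengths differ")
    if t.size < 4:
        raise SampleSizeError("bivariate fit needs at least 4 observations")
    design = sm.add_constant(np.column_stack([t, rho]), has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise CollinearityError("task time and PSD ratio are collinear")
    res = _ols(design, y)
    return SeverityModel(
        intercept=float(res.params[0]),
        coef_time=float(res.params[1]),
        coef_psd=float(res.params[2]),
        r_squared=float(res.rsquared),
        rmse=_rmse(np.asarray(res.resid)),
        n_obs=int(t.size),
    )


def predict_ftm(model: SeverityModel, task_time, psd_ratio):
    """Predicted FTM = b0 + b1*T + b2*rho, clipped at 0 (FTM is non-negative).

    Accepts scalars or arrays; returns the same shape.
    """
    t = np.asarray(task_time, dtype=float)
    rho = np.asarray(psd_ratio, dtype=float)
    if np.any(t < 0) or np.any(rho < 0):
        raise InvalidParameterError("task time and PSD ratio must be non-negative")
    y = model.intercept + model.coef_time * t + model.coef_psd * rho
    y = np.clip(y, 0.0, None)
    return float(y) if y.ndim == 0 else y


def interrater_r2(ftm_rater1, ftm_rater2) -> float:
    """Squared Pearson correlation between two blinded raters' FTM scores."""
    a = np.asarray(ftm_rater1, dtype=float)
    b = np.asarray(ftm_rater2, dtype=float)
    if a.size != b.size:
        raise InvalidParameterError("rater vectors must be paired")
    if a.size < 3:
        raise SampleSizeError("inter-rater correlation needs at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("a constant rater vector has no correlation")
    r = sstats.pearsonr(a, b).statistic
    return float(r**2)


# ---------------------------------------------------------------------------
# Cohort table and group summary
# ---------------------------------------------------------------------------

GROUP_ORDER = ("control", "ET0", "ET1plus", "ET2plus")
ET_GROUPS = ("ET0", "ET1plus", "ET2plus")


def build_cohort_table(features: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join per-subject features (long, one row per subject x site) with the
    clinical table; validates there is no duplicated (subject_id, site)."""
    required_f = {"subject_id", "site", "psd_ratio", "task_time"}
    required_c = {"subject_id", "group"}
    if not required_f.issubset(features.columns):
        raise InvalidParameterError(
            f"features table missing columns {sorted(required_f - set(features.columns))}"
        )
    if not required_c.issubset(clinical.columns):
        raise InvalidParameterError(
            f"clinical table missing columns {sorted(required_c - set(clinical.columns))}"
        )
    if features.duplicated(["subject_id", "site"]).any():
        raise InvalidParameterError("duplicated (subject_id, site) rows in features")
    features = features.copy()
    clinical = clinical.copy()
    features["subject_id"] = features["subject_id"].astype(str)
    clinical["subject_id"] = clinical["subject_id"].astype(str)
    merged = features.merge(clinical, on="subject_id", how="inner", validate="m:1")
    if {"ftm_rater1", "ftm_rater2"}.issubset(merged.columns):
        merged["ftm_mean"] = (merged["ftm_rater1"] + merged["ftm_rater2"]) / 2.0
    return merged


def _kw_p(table: pd.DataFrame, column: str, groups) -> float:
    samples = [
        table.loc[table["group"] == g, column].dropna().to_numpy() for g in groups
    ]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        return float("nan")
    try:
        return kruskal_wallis(samples).p_value
    except DegenerateInputError:
        return float("nan")


def group_summary(
    cohort: pd.DataFrame, model: SeverityModel = PUBLISHED_MODEL
) -> pd.DataFrame:
    """Per-group cohort summary in the layout of a clinical demographics table.

    One row per measure (PSD ratio per site, task time, clinical FTM,
    model-estimated FTM) with per-group mean and SD columns and a
    Kruskal–Wallis p-value across groups.  The estimated-FTM mean column is
    the model applied to the group means of T and the mid-forearm ratio; its
    SD column is the SD of per-subject predictions.
    """
    groups = [g for g in GROUP_ORDER if g in set(cohort["group"])]
    if len(groups) < 2:
        raise SampleSizeError("group summary needs at least 2 groups")
    sites = sorted(cohort["site"].unique())
    rows: list[dict] = []

    def add_row(measure: str, per_group: dict, p: float) -> None:
        row: dict = {"measure": measure}
        for g in groups:
            mean, sd = per_group.get(g, (float("nan"), float("nan")))
            row[f"{g}_mean"] = mean
            row[f"{g}_sd"] = sd
        row["kruskal_p"] = p
        rows.append(row)

    n_row: dict = {"measure": "n"}
    for g in groups:
        n_row[f"{g}_mean"] = cohort.loc[cohort["group"] == g, "subject_id"].nunique()
        n_row[f"{g}_sd"] = float("nan")
    n_row["kruskal_p"] = float("nan")
    rows.append(n_row)

    for site in sites:
        sub = cohort[cohort["site"] == site]
        per_group = {
            g: (
                float(sub.loc[sub["group"] == g, "psd_ratio"].mean()),
                float(sub.loc[sub["group"] == g, "psd_ratio"].std(ddof=1)),
            )
            for g in groups
        }
        add_row(f"psd_ratio_{site}", per_group, _kw_p(sub, "psd_ratio", groups))

    # task time is a per-subject quantity; deduplicate across sites
    per_subject = cohort.drop_duplicates("subject_id")
    per_group = {
        g: (
            float(per_subject.loc[per_subject["group"] == g, "task_time"].mean()),
            float(per_subject.loc[per_subject["group"] == g, "task_time"].std(ddof=1)),
        )
        for g in groups
    }
    add_row("task_time", per_group, _kw_p(per_subject, "task_time", groups))

    if "ftm_mean" in cohort.columns:
        et_groups = [g for g in groups if g in ET_GROUPS]
        per_group = {
            g: (
                float(per_subject.loc[per_subject["group"] == g, "ftm_mean"].mean()),
                float(per_subject.loc[per_subject["group"] == g, "ftm_mean"].std(ddof=1)),
            )
            for g in et_groups
        }
        add_row(
            "clinical_ftm",
            per_group,
            _kw_p(per_subject, "ftm_mean", et_groups) if len(et_groups) > 1 else float("nan"),
        )

    # model-estimated FTM from the mid-forearm sensor
    ref_site = "S2" if "S2" in sites else sites[0]
    sub = cohort[cohort["site"] == ref_site]
    est = sub.copy()
    est["ftm_est"] = predict_ftm(
        model, est["task_time"].to_numpy(), est["psd_ratio"].to_numpy()
    )
    per_group = {}
    for g in [g for g in groups if g in ET_GROUPS]:
        gsub = est[est["group"] == g]
        mean_pred = predict_ftm(
            model, float(gsub["task_time"].mean()), float(gsub["psd_ratio"].mean())
        )
        per_group[g] = (float(mean_pred), float(gsub["ftm_est"].std(ddof=1)))
    add_row(
        f"estimated_ftm_{ref_site}",
        per_group,
        _kw_p(est[est["group"].isin(ET_GROUPS)], "ftm_est", ET_GROUPS),
    )

    return pd.DataFrame(rows)
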