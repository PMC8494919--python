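"""Cohort correlation analysis.

Reproduces the study-style statistics: Pearson correlations of liver EIT
conductivity and MRI PDFF against demographic/anthropometric variables
(BMI, age, waist circumference, height, weight) plus the headline EIT-vs-
PDFF correlation, with two-sided p-values, 95 % confidence intervals of the
OLS slope, and Bonferroni multiple-testing correction.

The packaged fixture tables ship the printed per-subject values (liver EIT
mean ± SD, PDFF, demographics) with the three flagged subjects: subject 4
(electrode malfunction), 14 (renal failure) and 18 (leukemia).  Exclusion
policies: ``study_n16`` drops all three (the primary analysis), ``study_n18``
drops only subject 4 (the sensitivity analysis including the two subjects
with electrolyte-disturbing conditions), ``none`` keeps everyone.

Bonferroni family size defaults to m = 4 — the four demographic tests (age,
waist, height, weight) run per outcome; a pooled family (m = 8) is available
via ``bonferroni_m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import SubjectRecord
from .errors import DegenerateDataError, SchemaError

EXCLUSION_POLICIES = ("none", "study_n16", "study_n18")
#: subjects removed by each fixture policy
POLICY_DROPS = {"none": (), "study_n16": (4, 14, 18), "study_n18": (4,)}

DEMOGRAPHIC_VARS = ("bmi", "age", "waist", "height", "weight")
OUTCOME_VARS = ("pdff", "eit_mean")
#: Bonferroni family: the four demographic tests per outcome
DEFAULT_BONFERRONI_M = 4


def load_fixture_table(which: int) -> pd.DataFrame:
    """Packaged per-subject table 1 (BMI/EIT/PDFF/current) or 2 (demographics)."""
    name = {1: "cohort_table1.csv", 2: "cohort_table2.csv"}[which]
    with resources.files("livereit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixture_cohort() -> pd.DataFrame:
    """Fixture tables merged into one per-subject frame (n = 19)."""
    t1 = load_fixture_table(1)
    t2 = load_fixture_table(2)
    return t1.merge(
        t2[["subject", "sex", "age", "waist", "height", "weight"]], on="subject"
    )


@dataclass
class CohortTable:
    """A per-subject frame plus the exclusion policy applied to it."""

    records: pd.DataFrame
    exclusion_policy: str = "none"

    def __post_init__(self):
        if self.exclusion_policy not in EXCLUSION_POLICIES:
            raise SchemaError(
                f"unknown exclusion policy {self.exclusion_policy!r}; "
                f"choose from {EXCLUSION_POLICIES}"
            )
        if "subject" not in self.records.columns:
            raise SchemaError("cohort frame needs a 'subject' column")

    @classmethod
    def from_records(
        cls, records: Sequence[SubjectRecord], policy: str = "none"
    ) -> "CohortTable":
        df = pd.DataFrame([vars(r) for r in records]).rename(columns={"id": "subject"})
        return cls(df, policy)

    @classmethod
    def fixture(cls, policy: str = "study_n16") -> "CohortTable":
        return cls(load_fixture_cohort(), policy)

    def filtered(self) -> pd.DataFrame:
        df = self.records
        if self.exclusion_policy == "none":
            return df.reset_index(drop=True)
        drops = POLICY_DROPS[self.exclusion_policy]
        if set(drops).issubset(set(df["subject"])):
            return df[~df["subject"].isin(drops)].reset_index(drop=True)
        # synthetic cohorts carry their own flags instead of fixture ids
        if self.exclusion_policy == "study_n16" and "excluded" in df.columns:
            return df[~df["excluded"].astype(bool)].reset_index(drop=True)
        return df.reset_index(drop=True)


@dataclass
class CorrelationReport:
    variable_pair: tuple[str, str]
    n: int
    r: float
    p: float
    slope: float
    slope_ci: tuple[float, float]
    bonferroni_m: int

    @property
    def significant_nominal(self) -> bool:
        return self.p < 0.05

    @property
    def significant_corrected(self) -> bool:
        return self.p < 0.05 / self.bonferroni_m


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateDataError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in input")
    return x, y


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment r with the two-sided t-test p-value (n − 2 df)."""
    x, y = _check_xy(x, y)
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def slope_ci(x, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """OLS slope of y on x with its t-based confidence interval."""
    x, y = _check_xy(x, y)
    fit = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.5 + level / 2.0, len(x) - 2)
    half = tcrit * fit.stderr
    return float(fit.slope), (float(fit.slope - half), float(fit.slope + half))


def correlate(df: pd.DataFrame, xvar: str, yvar: str, m: int) -> CorrelationReport:
    if xvar not in df.columns or yvar not in df.columns:
        raise SchemaError(f"cohort frame lacks column {xvar!r} or {yvar!r}")
    r, p, n = pearson(df[xvar], df[yvar])
    s, ci = slope_ci(df[xvar], df[yvar])
    return CorrelationReport((xvar, yvar), n, r, p, s, ci, m)


def run_study_analysis(
    table: CohortTable, bonferroni_m: int = DEFAULT_BONFERRONI_M
) -> list[CorrelationReport]:
    """The full correlation grid: {PDFF, EIT} × {BMI, age, waist, height,
    weight}, plus EIT vs PDFF; one report per pair."""
    df = table.filtered()
    reports = []
    for outcome in OUTCOME_VARS:
        for demo in DEMOGRAPHIC_VARS:
            reports.append(correlate(df, demo, outcome, bonferroni_m))
    reports.append(correlate(df, "pdff", "eit_mean", bonferroni_m))
    return reports


def reports_frame(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": [r.variable_pair[0] for r in reports],
            "y": [r.variable_pair[1] for r in reports],
            "n": [r.n for r in reports],
            "r": [r.r for r in reports],
            "p": [r.p for r in reports],
            "slope": [r.slope for r in reports],
            "ci_lo": [r.slope_ci[0] for r in reports],
            "ci_hi": [r.slope_ci[1] for r in reports],
            "bonferroni_m": [r.bonferroni_m for r in reports],
            "significant_nominal": [r.significant_nominal for r in reports],
            "significant_corrected": [r.significant_corrected for r in reports],
        }
    )


def scatter_with_ci(df: pd.DataFrame, xvar: str, yvar: str, path=None, level=0.95):
    """Scatter plot with the OLS fit and its confidence band (mirrors the
    study's correlation figures).  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = df[xvar].to_numpy(float)
    y = df[yvar].to_numpy(float)
    r, p, n = pearson(x, y)
    fit = sps.linregress(x, y)
    xs = np.linspace(x.min(), x.max(), 100)
    ys = fit.intercept + fit.slope * xs
    # pointwise CI of the mean response
    dof = n - 2
    tcrit = sps.t.ppf(0.5 + level / 2.0, dof)
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    se_mean = np.sqrt(s2 * (1.0 / n + (xs - x.mean()) ** 2 / sxx))
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    ax.scatter(x, y, s=24, color="tab:blue")
    ax.plot(xs, ys, color="tab:red")
    ax.fill_between(xs, ys - tcrit * se_mean, ys + tcrit * se_mean, alpha=0.25,
                    color="tab:red", lw=0)
    ax.set_xlabel(xvar)
    ax.set_ylabel(yvar)
    ax.set_title(f"R = {r:.2f}, p = {p:.2g}, n = {n}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
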