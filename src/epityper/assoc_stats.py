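"""Association tests, FDR-controlled feature screens, and survival comparisons.

Categorical variables are tested against epitype labels with a chi-square test
(no continuity correction; df = k - 1 for a k x 2 table), falling back to
Fisher's exact test for 2 x 2 tables with any expected count below 5.
Continuous variables use the Kruskal-Wallis test.  Feature screens adjust
p values with Benjamini-Hochberg over the tested features only.  Survival is
compared with Kaplan-Meier estimates and the k-group log-rank test, with
optional administrative censoring at a follow-up horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class AssocResult:
    statistic: float
    p_value: float
    test: str
    table: pd.DataFrame | None = None
    df: int | None = None


def assoc_test(labels: pd.Series, variable: pd.Series, kind: str = "auto") -> AssocResult:
    """Test association between group labels and a variable.

    ``kind="categorical"`` builds the labels x variable contingency table and
    applies the chi-square test without continuity correction, switching to
    Fisher's exact test when the table is 2 x 2 and any expected count is
    below 5.  ``kind="continuous"`` applies the Kruskal-Wallis test across
    groups.  ``kind="auto"`` treats numeric variables as continuous.
    """
    df = pd.DataFrame({"label": labels, "value": variable}).dropna()
    if df["label"].nunique() < 2:
        raise ValueError("need at least 2 groups with data")
    if kind == "auto":
        kind = "continuous" if pd.api.types.is_numeric_dtype(df["value"]) else "categorical"
    if kind == "categorical":
        table = pd.crosstab(df["label"], df["value"])
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        if table.shape == (2, 2) and (expected < 5).any():
            odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
            return AssocResult(float(odds), float(p), "fisher", table, df=1)
        if (expected < 5).any() and table.shape != (2, 2):
            warnings.warn(
                "expected counts below 5 in a table larger than 2x2; "
                "chi-square approximation may be poor",
                stacklevel=2,
            )
        return AssocResult(float(chi2), float(p), "chi2", table, df=int(dof))
    if kind == "continuous":
        groups = [g["value"].to_numpy(float) for _, g in df.groupby("label")]
        stat, p = stats.kruskal(*groups)
        return AssocResult(float(stat), float(p), "kruskal", df=len(groups) - 1)
    raise ValueError(f"unknown kind {kind!r}")


def correlation_null_p(r: float, n: int) -> float:
    """Two-sided p value of a Pearson correlation ``r`` at sample size ``n``
    under the null of zero correlation (exact t transform,
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom)."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def expected_chance_correlations(r: float, n: int, n_tests: int) -> float:
    """Expected number of tests exceeding |correlation| ``r`` by chance alone
    across ``n_tests`` independent null tests at sample size ``n``."""
    return n_tests * correlation_null_p(r, n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    results: pd.DataFrame  # per feature: statistic, p, q, significant
    fdr_level: float
    n_tested: int

    @property
    def significant(self) -> pd.Index:
        return self.results.index[self.results["significant"]]


def screen_features(
    features: pd.DataFrame,
    labels: pd.Series,
    test: str = "kruskal",
    fdr_level: float = 0.05,
    min_count: int | None = None,
) -> ScreenResult:
    """Per-feature group test with BH FDR control.

    ``features`` is features x samples.  For ``test="chi2"`` features must be
    boolean/binary (e.g. mutation flags) and ``min_count`` drops features with
    fewer than that many positive samples before testing (mirroring screens
    restricted to genes mutated in at least 5 tumors).  ``test="wilcoxon"``
    is the two-group rank-sum test; ``test="kruskal"`` handles k groups.
    """
    labels = labels.reindex(features.columns)
    if labels.isna().any():
        raise ValueError("labels do not cover all samples")
    if min_count is not None:
        counts = features.sum(axis=1) if test == "chi2" else features.notna().sum(axis=1)
        features = features.loc[counts >= min_count]
    if features.shape[0] == 0:
        raise ValueError("no features left after filtering")

    group_values = sorted(labels.unique())
    groups_ix = [labels.index[labels == g] for g in group_values]
    rows = []
    for feat, row in features.iterrows():
        if test == "kruskal":
            groups = [row[ix].dropna().to_numpy(float) for ix in groups_ix]
            groups = [g for g in groups if g.size > 0]
            try:
                stat, p = stats.kruskal(*groups)
            except ValueError:  # all values identical
                stat, p = np.nan, 1.0
        elif test == "wilcoxon":
            if len(groups_ix) != 2:
                raise ValueError("wilcoxon screen needs exactly 2 groups")
            a = row[groups_ix[0]].dropna().to_numpy(float)
            b = row[groups_ix[1]].dropna().to_numpy(float)
            stat, p = stats.ranksums(a, b)
        elif test == "chi2":
            table = pd.crosstab(labels, row.astype(bool))
            if table.shape[1] < 2:
                stat, p = np.nan, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append((feat, float(stat) if stat == stat else np.nan, float(p)))
    res = pd.DataFrame(rows, columns=["feature", "statistic", "p"]).set_index("feature")
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = res["q"] <= fdr_level
    return ScreenResult(results=res, fdr_level=fdr_level, n_tested=len(res))


@dataclass
class SurvivalComparison:
    curves: dict[str, pd.DataFrame]  # per group: timeline, survival, at_risk
    statistic: float
    p_value: float
    truncate_years: float | None
    n_per_group: pd.Series


def first_primary_per_patient(clinical: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per patient: the first row in table order.

    Clinical tables are expected to list the first primary tumor before any
    additional sample of the same patient.
    """
    if "patient_id" not in clinical.columns:
        return clinical
    return clinical.drop_duplicates(subset="patient_id", keep="first")


def survival_logrank(
    clinical: pd.DataFrame,
    labels: pd.Series,
    truncate_years: float | None = None,
) -> SurvivalComparison:
    """Kaplan-Meier curves per group and the k-group log-rank test.

    ``clinical`` needs columns ``sample_id``, ``time`` (years) and ``event``
    (1 = event observed); a ``patient_id`` column triggers first-primary
    deduplication.  ``truncate_years`` applies administrative censoring: an
    event beyond the horizon becomes a censored observation at the horizon.
    """
    df = first_primary_per_patient(clinical).copy()
    df = df.set_index("sample_id")
    df["group"] = labels.reindex(df.index)
    df = df.dropna(subset=["group", "time", "event"])
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    time = df["time"].to_numpy(float)
    event = df["event"].astype(bool).to_numpy()
    if truncate_years is not None:
        over = time > truncate_years
        event = np.where(over, False, event)
        time = np.where(over, truncate_years, time)
    df["time_used"] = time
    df["event_used"] = event

    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_used"], sub["event_used"], label=str(g))
        curves[str(g)] = pd.DataFrame(
            {
                "timeline": kmf.survival_function_.index.to_numpy(float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(float),
            }
        )
    result = multivariate_logrank_test(df["time_used"], df["group"], df["event_used"])
    return SurvivalComparison(
        curves=curves,
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        truncate_years=truncate_years,
        n_per_group=df.groupby("group").size(),
    )
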