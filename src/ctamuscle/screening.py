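"""Z-score standardization and univariable feature screening.

Features are standardized column-wise (the transform is retained so new
data - e.g. per-segment re-extractions - can be mapped into the same
space).  Each feature is compared between the mild and severe groups with
Student's t test when both groups pass Shapiro-Wilk normality at alpha
0.05, otherwise with the Mann-Whitney U test (normal approximation with
tie correction).  Categorical tables use Pearson's chi-squared without
continuity correction, or Fisher's exact test when any expected count
falls below 5 (2x2 only).  Screening keeps features with p < alpha and
applies no multiple-testing correction, matching common radiomics
practice for a pre-selection stage (the cost is a known false-positive
rate among selected features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ZScoreTransform",
    "zscore",
    "univariable_test",
    "categorical_test",
    "screen",
    "TestResult",
]


@dataclass
class ZScoreTransform:
    """Column means/SDs (population form) frozen from a training matrix."""

    means: pd.Series
    sds: pd.Series

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        """Standardize the columns of ``df`` with the stored parameters.

        ``df`` may carry any subset of the training columns (e.g. only the
        model's input features re-extracted from a leg segment).
        """
        unknown = [c for c in df.columns if c not in self.means.index]
        if unknown:
            raise ValueError(f"columns without stored transform parameters: {unknown}")
        cols = list(df.columns)
        return (df - self.means[cols]) / self.sds[cols]


def zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, ZScoreTransform]:
    """Standardize each column to mean 0, SD 1 (population denominator)."""
    if df.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    means = df.mean()
    sds = df.std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero}")
    tf = ZScoreTransform(means=means, sds=sds)
    return tf.apply(df), tf


@dataclass
class TestResult:
    statistic: float
    p: float
    test_name: str


def univariable_test(values, groups, normality_alpha: float = 0.05, welch: bool = False) -> TestResult:
    """Two-sided t test (normality gate via Shapiro-Wilk) or Mann-Whitney U."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"exactly two groups required, got {labels.tolist()}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 subjects")

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate constant groups: identical -> no evidence; distinct
        # constants -> unambiguous separation
        if np.isclose(a.mean(), b.mean()):
            return TestResult(0.0, 1.0, "degenerate_constant")
        return TestResult(float("inf"), 0.0, "degenerate_constant")

    def _normal(x):
        if np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > normality_alpha

    if _normal(a) and _normal(b):
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        return TestResult(float(stat), float(p), "welch_t" if welch else "student_t")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(stat), float(p), "mann_whitney_u")


def categorical_test(table) -> TestResult:
    """Chi-squared without continuity correction, or Fisher's exact (2x2)."""
    t = np.asarray(table)
    if t.ndim != 2 or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2D array of non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    # expected counts under independence
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        stat, p = stats.fisher_exact(t)
        return TestResult(float(stat), float(p), "fisher_exact")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), "chi_squared")


def screen(
    features: pd.DataFrame,
    groups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariable p-value table; ``selected`` flags features with p < alpha.

    ``features`` should be the standardized matrix (p-values are invariant
    to the affine transform, but the modeling stage downstream expects
    standardized inputs).
    """
    groups = np.asarray(groups)
    rows = []
    for col in features.columns:
        res = univariable_test(features[col].to_numpy(), groups)
        family = col.split("_", 1)[0]
        rows.append(
            {
                "feature": col,
                "family": family,
                "statistic": res.statistic,
                "p": res.p,
                "test": res.test_name,
                "selected": bool(res.p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
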