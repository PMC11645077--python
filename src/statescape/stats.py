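"""Demographic/clinical group tests and behavioural correlation.

Summary-statistic two-sample t-tests (Welch and pooled), 2x2 chi-square
without continuity correction, the Fisher z-transform, and bivariate
Pearson correlation of paired-state probabilities with behavioural or
connectivity covariates, overall and per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "GroupSummary",
    "TestResult",
    "welch_t",
    "pooled_t",
    "chi2_2x2",
    "fisher_z",
    "correlate_pairs_with_covariates",
]


@dataclass
class GroupSummary:
    """Means, SDs and sizes of two groups (in the variable's own units)."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("sd must be >= 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    kind: str


def _summary_t(s: GroupSummary, equal_var: bool, kind: str) -> TestResult:
    if s.sd1 == 0 and s.sd2 == 0:
        raise ValueError("both group SDs are zero; t undefined")
    t, p = st.ttest_ind_from_stats(
        s.mean1, s.sd1, s.n1, s.mean2, s.sd2, s.n2, equal_var=equal_var
    )
    if equal_var:
        df = s.n1 + s.n2 - 2
    else:
        a, b = s.sd1 ** 2 / s.n1, s.sd2 ** 2 / s.n2
        df = (a + b) ** 2 / (a ** 2 / (s.n1 - 1) + b ** 2 / (s.n2 - 1))
    return TestResult(float(t), float(df), float(p), kind)


def welch_t(summary: GroupSummary) -> TestResult:
    """Two-sample t assuming unequal variances (Welch-Satterthwaite df)."""
    return _summary_t(summary, equal_var=False, kind="welch_t")


def pooled_t(summary: GroupSummary) -> TestResult:
    """Two-sample t assuming equal variances, df = n1 + n2 - 2."""
    return _summary_t(summary, equal_var=True, kind="pooled_t")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a table margin is zero")
    stat, p, df, _ = st.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(df), float(p), "chi2")


def fisher_z(r: float) -> float:
    """Variance-stabilising atanh transform of a correlation coefficient."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


def correlate_pairs_with_covariates(pair_freqs: pd.DataFrame, covariates: pd.DataFrame,
                                    grouping: pd.Series | None = None) -> pd.DataFrame:
    """Pearson correlation of each paired-state frequency with each covariate.

    ``pair_freqs`` and ``covariates`` are subject-indexed tables (a
    ``group`` column in either is ignored as a covariate).  When
    ``grouping`` is given, per-group rows are added alongside the overall
    ones.  Requires aligned subject ids and n >= 4 per stratum.
    """
    pf = pair_freqs.drop(columns=["group"], errors="ignore")
    cov = covariates.drop(columns=["group"], errors="ignore")
    if not pf.index.equals(cov.index):
        if set(pf.index) != set(cov.index):
            raise ValueError("subject ids of the two tables do not align")
        cov = cov.reindex(pf.index)
    strata = {"all": pf.index}
    if grouping is not None:
        grouping = grouping.reindex(pf.index)
        for g in grouping.dropna().unique():
            strata[str(g)] = pf.index[grouping == g]
    rows = []
    for stratum, idx in strata.items():
        if len(idx) < 4:
            raise ValueError(f"stratum {stratum!r} has n={len(idx)} < 4")
        for pair in pf.columns:
            x = pf.loc[idx, pair].to_numpy(dtype=float)
            for name in cov.columns:
                y = cov.loc[idx, name].to_numpy(dtype=float)
                if np.std(y) == 0:
                    raise ValueError(f"covariate {name!r} is constant in stratum {stratum!r}")
                if np.std(x) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = st.pearsonr(x, y)
                rows.append({"pair": pair, "covariate": name, "stratum": stratum,
                             "n": len(idx), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
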