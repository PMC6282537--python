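"""Descriptive statistics for nested field sampling (patch/tree/zone).

Covers the summaries a card-to-report pipeline needs: per-group mean
with t-based 95% confidence interval and coefficient of variation,
Welch's unequal-variance t-test for two-zone comparisons, and the
high-coverage exclusion rule (cards with coverage above a threshold,
default 30%, are dropped before volume-based analysis because stain
merging makes their deposition estimates unreliable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stain_geometry import CardMetrics

__all__ = [
    "ZONES",
    "GroupSummary",
    "WelchResult",
    "ExclusionReport",
    "group_summary",
    "summarize_by",
    "welch_compare",
    "exclusion_filter",
]

ZONES = ("top", "middle", "outer")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    ci95_lower: float
    ci95_upper: float
    cv_pct: float
    ci_defined: bool = True


@dataclass(frozen=True)
class WelchResult:
    mean_diff: float
    ci95_lower: float
    ci95_upper: float
    t_stat: float
    df: float
    p_value: float


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_excluded: int

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def group_summary(values) -> GroupSummary:
    """Mean, t-based 95% CI and CV (%) of one group of observations.

    With fewer than two observations the CI is undefined and flagged.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("group must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = int(x.size)
    mean = float(np.mean(x))
    if n < 2:
        return GroupSummary(n, mean, math.nan, math.nan, math.nan, ci_defined=False)
    sd = float(np.std(x, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    cv = 100.0 * sd / mean if mean != 0 else math.nan
    return GroupSummary(n, mean, mean - half, mean + half, cv)


def summarize_by(df: pd.DataFrame, value_col: str, group_cols: Sequence[str]) -> pd.DataFrame:
    """Group summaries in a long table, one row per group."""
    rows = []
    for key, sub in df.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        s = group_summary(sub[value_col].to_numpy())
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n": s.n,
                "mean": s.mean,
                "ci95_lower": s.ci95_lower,
                "ci95_upper": s.ci95_upper,
                "cv_pct": s.cv_pct,
            }
        )
    return pd.DataFrame(rows)


def welch_compare(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance t-test: difference of means a - b.

    Uses the Welch–Satterthwaite degrees of freedom for both the
    two-sided p-value and the 95% CI of the difference.  If both groups
    are degenerate (zero variance) the comparison reduces to exact
    equality of the two constants.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(np.mean(a) - np.mean(b))
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        p = 1.0 if diff == 0 else 0.0
        return WelchResult(diff, diff, diff, math.inf if diff else 0.0, math.nan, p)
    sa2, sb2 = va / a.size, vb / b.size
    se = math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return WelchResult(diff, diff - half, diff + half, t, df, p)


def exclusion_filter(cards, threshold: float = 30.0):
    """Drop cards whose coverage exceeds ``threshold`` percent.

    Accepts a sequence of :class:`CardMetrics` or a DataFrame with a
    ``coverage_pct`` column; returns (retained, ExclusionReport).
    Idempotent: re-filtering the retained set excludes nothing.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if isinstance(cards, pd.DataFrame):
        keep = cards["coverage_pct"].to_numpy() <= threshold
        retained = cards.loc[keep].reset_index(drop=True)
        return retained, ExclusionReport(len(cards), int((~keep).sum()))
    cards = list(cards)
    retained_list = [c for c in cards if c.coverage_pct <= threshold]
    return retained_list, ExclusionReport(len(cards), len(cards) - len(retained_list))
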