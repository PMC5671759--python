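"""Normality-gated group comparisons and metric-outcome correlations.

Every metric is compared between two label groups (recalled vs
forgotten ads, liked vs disliked ads).  A Shapiro-Wilk gate decides the
test: one-way ANOVA when both groups look normal, Mann-Whitney U
otherwise.  Significance uses a fixed corrected threshold of p < 0.005
to absorb the multiple comparisons.  Metric-outcome association uses
Pearson correlation against the (linear-scale) online view count and
Spearman correlation against the (rank-scale) ACE survey score, flagged
at p < 0.01.

Rows are subject x ad observations pooled across subjects; no
mixed-effects structure is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import InsufficientDataError

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "normality_gate",
    "group_compare",
    "correlate",
    "compare_all",
    "correlate_all",
    "GROUP_LABELS",
]

GROUP_LABELS = {"recall": ("RMB", "FRG"), "liking": ("LIKE", "DISLIKE")}
CORR_METHOD = {"views": "pearson", "ace": "spearman"}


@dataclass
class ComparisonResult:
    metric: str
    condition: str
    test_used: str           # "anova" | "mann_whitney"
    statistic: float
    p: float
    significant: bool
    group_stats: dict[str, tuple[float, float, int]]  # label -> (mean, sd, n)


@dataclass
class CorrelationResult:
    metric: str
    target: str              # "views" | "ace"
    method: str              # "pearson" | "spearman"
    coefficient: float
    p: float
    significant: bool
    n: int


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> bool:
    """True (parametric branch) when Shapiro-Wilk does not reject."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    if np.ptp(v) == 0:
        warnings.warn("constant sample: routing to non-parametric branch",
                      stacklevel=2)
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sst.shapiro(v)
    return bool(p >= alpha)


def group_compare(table: pd.DataFrame, metric: str, condition: str,
                  p_threshold: float = 0.005,
                  gate_alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison of one metric under one labelling."""
    lab_a, lab_b = GROUP_LABELS[condition]
    col = table[condition]
    a = table.loc[col == lab_a, metric].dropna().to_numpy(dtype=float)
    b = table.loc[col == lab_b, metric].dropna().to_numpy(dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"{metric}/{condition}: group sizes {a.size}/{b.size} < 3")
    parametric = normality_gate(a, gate_alpha) and normality_gate(b, gate_alpha)
    if parametric:
        stat, p = sst.f_oneway(a, b)
        test = "anova"
    else:
        stat, p = sst.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return ComparisonResult(
        metric=metric, condition=condition, test_used=test,
        statistic=float(stat), p=float(p),
        significant=bool(p < p_threshold),
        group_stats={
            lab_a: (float(a.mean()), float(a.std(ddof=1)), a.size),
            lab_b: (float(b.mean()), float(b.std(ddof=1)), b.size),
        },
    )


def correlate(table: pd.DataFrame, metric: str, target: str,
              p_threshold: float = 0.01) -> CorrelationResult:
    """Pearson (views) or Spearman (ace) metric-outcome correlation."""
    method = CORR_METHOD[target]
    sub = table[[metric, target]].dropna()
    x = sub[metric].to_numpy(dtype=float)
    y = sub[target].to_numpy(dtype=float)
    if x.size < 4:
        raise InsufficientDataError(f"{metric}/{target}: fewer than 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(metric, target, method,
                                 np.nan, np.nan, False, x.size)
    if method == "pearson":
        r, p = sst.pearsonr(x, y)
    else:
        r, p = sst.spearmanr(x, y)
    return CorrelationResult(metric, target, method, float(r), float(p),
                             bool(p < p_threshold), x.size)


def compare_all(table: pd.DataFrame, metrics: list[str] | None = None,
                conditions: tuple[str, ...] = ("recall", "liking"),
                p_threshold: float = 0.005) -> pd.DataFrame:
    """Comparison table mirroring the per-metric mean/SD/test layout."""
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in ("subject", "ad", "views", "rank", "ace",
                                "gender", *GROUP_LABELS)
                   and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for cond in conditions:
        lab_a, lab_b = GROUP_LABELS[cond]
        for m in metrics:
            try:
                r = group_compare(table, m, cond, p_threshold)
            except InsufficientDataError:
                continue
            rows.append({
                "metric": m, "condition": cond, "test": r.test_used,
                f"mean_{lab_a}": r.group_stats[lab_a][0],
                f"sd_{lab_a}": r.group_stats[lab_a][1],
                f"mean_{lab_b}": r.group_stats[lab_b][0],
                f"sd_{lab_b}": r.group_stats[lab_b][1],
                "statistic": r.statistic, "p": r.p,
                "significant": r.significant,
            })
    return pd.DataFrame(rows)


def correlate_all(table: pd.DataFrame, metrics: list[str] | None = None,
                  targets: tuple[str, ...] = ("views", "ace"),
                  p_threshold: float = 0.01) -> pd.DataFrame:
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in ("subject", "ad", "views", "rank", "ace",
                                "gender", *GROUP_LABELS)
                   and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for target in targets:
        if target not in table.columns:
            continue
        for m in metrics:
            try:
                r = correlate(table, m, target, p_threshold)
            except InsufficientDataError:
                continue
            rows.append({
                "metric": m, "target": target, "method": r.method,
                "coefficient": r.coefficient, "p": r.p,
                "significant": r.significant, "n": r.n,
            })
    return pd.DataFrame(rows)
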