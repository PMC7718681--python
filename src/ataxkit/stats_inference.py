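"""Group-difference statistics, validity correlations, and power analysis.

Per feature: Shapiro-Wilk normality gate, then either the two-sample t-test
(both groups normal) or the Wilcoxon rank-sum test; effect size is Cohen's d
with pooled SD regardless of the test chosen.  Spearman correlation measures
validity against the clinical SARA scores.  The power routine inverts the
noncentral-t power function to give the minimum detectable effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SubjectRecord, catalog_frame


@dataclass
class GroupComparison:
    p_value: float
    test_used: str          # "t" | "ranksum"
    effect_size: float      # Cohen's d, pooled SD, sign by (a - b)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    pooled = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                     / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def group_compare(values_a: np.ndarray, values_b: np.ndarray,
                  alpha: float = 0.05) -> GroupComparison:
    """Compare two groups with a normality-gated test plus Cohen's d."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) \
            and np.isclose(a.mean(), b.mean()):
        return GroupComparison(p_value=1.0, test_used="t", effect_size=0.0)
    normal = all(stats.shapiro(g).pvalue > alpha for g in (a, b)
                 if not np.allclose(g, g.mean()))
    if normal and not (np.allclose(a, a.mean()) or np.allclose(b, b.mean())):
        res = stats.ttest_ind(a, b)
        used = "t"
    else:
        res = stats.ranksums(a, b)
        used = "ranksum"
    return GroupComparison(p_value=float(res.pvalue), test_used=used,
                           effect_size=cohens_d(a, b))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# power analysis
# --------------------------------------------------------------------------

def t_test_power(d: float, n1: int, n2: int, alpha: float = 0.05,
                 two_sided: bool = True) -> float:
    """Power of the two-sample t-test at Cohen's d, via the noncentral t."""
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, ncp)
                     + stats.nct.cdf(-tc, df, ncp))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, ncp))


def min_detectable_effect(n1: int, n2: int, power: float = 0.80,
                          alpha: float = 0.05,
                          two_sided: bool = True) -> float:
    """Smallest Cohen's d detectable at the target power, by bisection.

    Solves power(d) = power to 1e-6 on d; power is strictly increasing in d,
    so plain bisection on [0, 20] suffices.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    lo, hi = 0.0, 20.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if t_test_power(mid, n1, n2, alpha, two_sided) < power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# cohort-level summary table
# --------------------------------------------------------------------------

def feature_statistics(features: pd.DataFrame,
                       subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Per-feature group means, effect size, p-value and SARA correlations.

    One row per catalog feature: mean +/- SD in each group, Cohen's d with
    the gated test's p-value (ataxic vs control), and Spearman rho against
    SARA-total and SARA-UL.  No multiple-testing correction is applied; the
    per-feature alpha = 0.05 convention is kept.
    """
    by_id = {s.subject_id: s for s in subjects}
    groups = features.index.map(lambda i: by_id[i].group)
    sara_total = np.array([by_id[i].sara_total for i in features.index])
    sara_ul = np.array([by_id[i].sara_ul_sum for i in features.index])
    rows = []
    for name in features.columns:
        col = features[name]
        ok = col.notna()
        a = col[ok & (groups == "ataxic")].to_numpy()
        c = col[ok & (groups == "control")].to_numpy()
        row = {"feature": name,
               "ataxic_mean": a.mean() if a.size else np.nan,
               "ataxic_sd": a.std(ddof=1) if a.size > 1 else np.nan,
               "control_mean": c.mean() if c.size else np.nan,
               "control_sd": c.std(ddof=1) if c.size > 1 else np.nan}
        try:
            cmp_ = group_compare(a, c)
            row.update(effect_size=abs(cmp_.effect_size),
                       p_value=cmp_.p_value, test_used=cmp_.test_used)
        except ValueError:
            row.update(effect_size=np.nan, p_value=np.nan, test_used="")
        for label, target in (("sara_total", sara_total), ("sara_ul", sara_ul)):
            try:
                rho, p = spearman(col[ok].to_numpy(), target[ok.to_numpy()])
            except ValueError:
                rho, p = np.nan, np.nan
            row[f"rho_{label}"] = rho
            row[f"p_{label}"] = p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    return table.join(catalog_frame()[["test", "star"]], how="left")
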