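"""Cohort-level statistics on per-field DOPU summaries.

Group comparisons use the two-sample Student's t-test (pooled variance;
Welch by flag) at a 5% significance level per field, without multiple-
testing correction — a Benjamini-Hochberg option is available.
Neighboring-ring contrasts within one group are paired t-tests by
default, since the same subjects contribute both rings.  Age trends are
ordinary least-squares regressions of ring-mean DOPU on age, reported as
slope (DOPU/year), intercept, R^2 and p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "RegressionResult", "compare_groups",
           "neighbor_ring_tests", "ring_age_regression", "bh_adjust"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    field: str
    t: float
    p: float
    n_a: int
    n_b: int
    significant: bool


@dataclass
class RegressionResult:
    slope: float          # DOPU per year
    intercept: float
    r2: float
    p: float
    stderr: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope (t distribution, n - 2 df)."""
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - tcrit * self.stderr, self.slope + tcrit * self.stderr)


def _ttest_ind(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    # degenerate zero-variance samples: identical means -> no evidence
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_groups(table: pd.DataFrame,
                   field: str,
                   group_a: str = "healthy",
                   group_b: str = "glaucoma",
                   group_col: str = "group",
                   min_age: float | None = None,
                   min_age_groups: tuple[str, ...] | None = None,
                   equal_var: bool = True,
                   alpha: float = ALPHA) -> GroupComparison | None:
    """Unpaired Student's t-test between two groups on one field column.

    ``min_age`` drops younger subjects before testing — either from all
    groups or only from those named in ``min_age_groups`` (used to
    age-match a healthy reference group against patients).  Returns None
    when fewer than two subjects per group remain.
    """
    col = field if field in table.columns else f"ring_{field}"
    sub = table.dropna(subset=[col])
    if min_age is not None:
        affected = sub[group_col].isin(min_age_groups) if min_age_groups \
            else pd.Series(True, index=sub.index)
        sub = sub[~affected | (sub["age"] >= min_age)]
    a = sub.loc[sub[group_col] == group_a, col].to_numpy(dtype=float)
    b = sub.loc[sub[group_col] == group_b, col].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    t, p = _ttest_ind(a, b, equal_var)
    return GroupComparison(field=field, t=t, p=p, n_a=len(a), n_b=len(b),
                           significant=bool(p < alpha))


def neighbor_ring_tests(table: pd.DataFrame,
                        rings: str = "ABCDEFG",
                        group: str | None = None,
                        group_col: str = "group",
                        paired: bool = True,
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Significance of each adjacent ring pair within one group.

    Paired t-tests by default (each subject contributes both rings);
    ``paired=False`` gives the unpaired reading.  Rows with a missing
    value in either ring of a pair are dropped for that pair; pairs with
    fewer than two complete subjects are reported with NaN.
    """
    sub = table if group is None else table[table[group_col] == group]
    rows = []
    for r1, r2 in zip(rings[:-1], rings[1:]):
        c1 = r1 if r1 in sub.columns else f"ring_{r1}"
        c2 = r2 if r2 in sub.columns else f"ring_{r2}"
        pair = sub[[c1, c2]].dropna()
        a, b = pair[c1].to_numpy(dtype=float), pair[c2].to_numpy(dtype=float)
        if len(a) < 2:
            rows.append({"ring_a": r1, "ring_b": r2, "t": np.nan, "p": np.nan,
                         "n": len(a), "significant": False})
            continue
        if paired:
            diff = a - b
            if np.std(diff) == 0:
                t, p = (0.0, 1.0) if np.all(diff == 0) else (np.inf * np.sign(diff[0]), 0.0)
            else:
                t, p = sps.ttest_rel(a, b)
        else:
            t, p = _ttest_ind(a, b, equal_var=True)
        rows.append({"ring_a": r1, "ring_b": r2, "t": float(t), "p": float(p),
                     "n": len(a), "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def ring_age_regression(table: pd.DataFrame,
                        ring: str,
                        min_age: float | None = None,
                        group: str | None = None,
                        group_col: str = "group") -> RegressionResult | None:
    """OLS of ring-mean DOPU on age for a subject subset.

    The subsets of interest are the full healthy group, the healthy group
    age-restricted (e.g. >= 39 years) and the patient group.  Returns
    None with fewer than three subjects or degenerate age variance.
    """
    col = ring if ring in table.columns else f"ring_{ring}"
    sub = table.dropna(subset=[col, "age"])
    if group is not None:
        sub = sub[sub[group_col] == group]
    if min_age is not None:
        sub = sub[sub["age"] >= min_age]
    if len(sub) < 3 or np.std(sub["age"].to_numpy()) == 0:
        return None
    res = sps.linregress(sub["age"].to_numpy(dtype=float),
                         sub[col].to_numpy(dtype=float))
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue**2), p=float(res.pvalue),
                            stderr=float(res.stderr), n=len(sub))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default elsewhere)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
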