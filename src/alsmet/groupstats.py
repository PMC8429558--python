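"""Between-group comparison machinery: Fisher exact, Mann-Whitney U,
Spearman rank correlation and median [IQR] summaries.

The two-sided Fisher p-value uses the minimum-likelihood convention (sum of
hypergeometric point probabilities no larger than the observed table's),
which is the convention that reproduces the published contingency-table
p-values exactly. The Mann-Whitney test switches from exact enumeration to
the tie- and continuity-corrected normal approximation following the usual
clinical-statistics platform behaviour (exact when both samples are small
and tie-free). Standard numerics are delegated to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankTestResult",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "spearman",
    "median_iqr",
    "compare_groups",
]

#: Largest per-sample size for which the Mann-Whitney p is computed by exact
#: enumeration (tie-free data only).
EXACT_MWU_MAX_N = 10


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p: float
    n_used: tuple


def _as_clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[np.isfinite(a)]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Rows are groups, columns outcome yes/no. Minimum-likelihood two-sided
    convention over all tables with the observed margins.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("empty table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test after missing-value removal.

    Exact enumeration when both samples have n <= 10 and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x, y = _as_clean(x), _as_clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty after missing removal")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = ("exact"
              if tie_free and x.size <= EXACT_MWU_MAX_N and y.size <= EXACT_MWU_MAX_N
              else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                          (int(x.size), int(y.size)))


def spearman(x, y) -> RankTestResult:
    """Spearman rank correlation with the t-approximation p (n-2 df).

    Pairs with a missing member are dropped; requires >= 4 complete pairs
    and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant input")
    rs, p = stats.spearmanr(x, y)
    return RankTestResult(float(rs), float(p), (int(x.size),) * 2)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quantiles."""
    a = _as_clean(values)
    if a.size == 0:
        return (math.nan,) * 3
    q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

def _is_binary(s: pd.Series) -> bool:
    vals = set(s.dropna().unique().tolist())
    return vals <= {0, 1, True, False}


def compare_groups(table: pd.DataFrame, group_col: str, variables,
                   *, categorical=None) -> pd.DataFrame:
    """Two-group comparison table: median [IQR] or count/total, plus p.

    For each variable, rows with a missing value (or missing group label)
    are dropped pairwise; continuous variables get Mann-Whitney p and
    per-group ``median [q1, q3] (n)`` summaries, categorical (binary)
    variables get Fisher p and ``positives/total`` summaries. ``categorical``
    optionally forces variable types; by default a variable whose non-missing
    values are all 0/1 is treated as categorical.

    Returns a DataFrame indexed by variable with columns
    ``group0``, ``group1`` (labels), ``summary0``, ``summary1``, ``p``,
    ``n0``, ``n1``, ``test``.
    """
    categorical = set(categorical or ())
    g = table[group_col]
    levels = sorted(g.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"grouping variable {group_col!r} must be binary, "
                         f"found levels {levels}")
    rows = []
    for var in variables:
        if var not in table.columns:
            raise KeyError(f"unknown variable {var!r}")
        v = pd.to_numeric(table[var], errors="coerce")
        keep = v.notna() & g.notna()
        sub_v, sub_g = v[keep], g[keep]
        parts = [sub_v[sub_g == lev] for lev in levels]
        n0, n1 = (int(p.size) for p in parts)
        is_cat = var in categorical or _is_binary(table[var].dropna())
        if n0 == 0 or n1 == 0:
            rows.append((var, levels[0], levels[1], f"n={n0}", f"n={n1}",
                         math.nan, n0, n1, "none"))
            continue
        if is_cat:
            pos = [int((p == 1).sum()) for p in parts]
            p_val = fisher_exact_2x2(pos[0], n0 - pos[0], pos[1], n1 - pos[1])
            summ = [f"{k}/{n}" for k, n in zip(pos, (n0, n1))]
            test = "fisher"
        else:
            if np.array_equal(np.sort(parts[0]), np.sort(parts[1])):
                p_val = 1.0  # identical samples: no evidence by symmetry
            else:
                p_val = mann_whitney_u(parts[0], parts[1]).p
            summ = []
            for part in parts:
                med, q1, q3 = median_iqr(part)
                summ.append(f"{med:g} [{q1:g}, {q3:g}] (n={part.size})")
            test = "mann-whitney"
        rows.append((var, levels[0], levels[1], summ[0], summ[1],
                     p_val, n0, n1, test))
    return pd.DataFrame(rows, columns=[
        "variable", "group0", "group1", "summary0", "summary1",
        "p", "n0", "n1", "test",
    ]).set_index("variable")
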