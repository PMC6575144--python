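"""Decedent characterization tables with group tests and cell suppression.

Continuous variables are compared across the three LTC subgroups with a
Kruskal–Wallis test (tie-corrected); categorical variables with a Pearson
chi-square without continuity correction, excluding the "missing" category.
Small cells (0 < count < threshold) are masked with "S", with complementary
suppression so a masked cell cannot be recovered by subtraction from a row
margin.  Zero counts are not disclosive and are shown as 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import LTC_SUBGROUPS, CaseCategory

__all__ = [
    "Chi2Result",
    "GroupTestResult",
    "pearson_chi2",
    "kruskal_wallis",
    "group_test",
    "summarize_groups",
    "suppress_cells",
    "SUPPRESSED",
    "DEFAULT_SUPPRESSION_THRESHOLD",
]

SUPPRESSED = "S"
DEFAULT_SUPPRESSION_THRESHOLD = 6

GROUP_ORDER = (
    CaseCategory.NOT_ASSOCIATED,
    "all_ltc",
    CaseCategory.IN_LTC,
    CaseCategory.TRANSITIONING,
    CaseCategory.OTHERWISE_ASSOCIATED,
)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    flagged: bool = False  # some expected cell < 1


def pearson_chi2(observed: Sequence[Sequence[float]] | np.ndarray) -> Chi2Result:
    """Pearson chi-square without continuity correction.

    ``X^2 = sum (O - E)^2 / E`` with ``E`` from the margin outer product and
    ``df = (r - 1)(c - 1)``.  Rows/columns with zero margin are dropped before
    computing; an expected cell below 1 flags the result rather than
    suppressing it.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be 2-dimensional")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("chi-square needs at least a 2x2 table after pruning")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(stat, df))
    return Chi2Result(
        statistic=stat, df=df, p_value=p, expected=expected,
        flagged=bool((expected < 1).any()),
    )


@dataclass
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    test: str
    flagged: bool = False


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Tie-corrected Kruskal–Wallis test across groups."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 nonempty groups")
    stat, p = stats.kruskal(*groups)
    return GroupTestResult(
        statistic=float(stat), df=len(groups) - 1, p_value=float(p),
        test="kruskal-wallis",
    )


def _anova(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    stat, p = stats.f_oneway(*groups)
    return GroupTestResult(
        statistic=float(stat), df=len(groups) - 1, p_value=float(p), test="anova"
    )


def group_test(
    df: pd.DataFrame,
    variable: str,
    kind: str,
    groups: Sequence[CaseCategory] = LTC_SUBGROUPS,
    category_col: str = "category",
    exclude_levels: Iterable[Hashable] = ("missing",),
    use_anova: bool = False,
) -> GroupTestResult:
    """Compare ``variable`` across the LTC subgroups.

    ``kind`` is "continuous" (Kruskal–Wallis, or one-way ANOVA behind the
    ``use_anova`` flag) or "categorical" (Pearson chi-square, excluding the
    levels in ``exclude_levels``).
    """
    cats = [c.value if isinstance(c, CaseCategory) else c for c in groups]
    sub = df[df[category_col].isin(cats)]
    if kind == "continuous":
        arrays = [
            sub.loc[sub[category_col] == c, variable].dropna().to_numpy()
            for c in cats
        ]
        arrays = [a for a in arrays if len(a)]
        if len(arrays) < 2:
            raise ValueError("need at least 2 nonempty groups")
        return _anova(arrays) if use_anova else kruskal_wallis(arrays)
    if kind != "categorical":
        raise ValueError(f"unknown kind {kind!r}")
    col = sub[variable]
    mask = ~col.isin(set(exclude_levels)) & col.notna()
    table = pd.crosstab(col[mask], sub.loc[mask, category_col])
    table = table.reindex(columns=cats, fill_value=0)
    res = pearson_chi2(table.to_numpy())
    return GroupTestResult(
        statistic=res.statistic, df=res.df, p_value=res.p_value,
        test="pearson-chi2", flagged=res.flagged,
    )


def _col_name(g) -> str:
    return g if isinstance(g, str) else g.value


def summarize_groups(
    df: pd.DataFrame,
    categorical: Sequence[str],
    continuous: Sequence[str] = ("age",),
    category_col: str = "category",
    flag_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Characterization table: one column per group, one row per statistic.

    Continuous rows report ``median (IQR)``; categorical and flag rows report
    ``count (pct)`` with percentages computed within the column.  Flag
    columns are booleans reported for their True level.  Empty groups yield
    flagged empty columns rather than errors.
    """
    frames: Dict[str, pd.DataFrame] = {}
    for g in GROUP_ORDER:
        name = _col_name(g)
        if g == "all_ltc":
            block = df[df[category_col].isin([c.value for c in LTC_SUBGROUPS])]
        else:
            block = df[df[category_col] == g.value]
        frames[name] = block

    rows: List[Tuple[str, Dict[str, str]]] = []
    for var in continuous:
        cells = {}
        for name, block in frames.items():
            vals = block[var].dropna()
            if len(vals) == 0:
                cells[name] = "(empty)"
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cells[name] = f"{med:g} ({q3 - q1:g})"
        rows.append((f"{var}, median (IQR)", cells))
    for var in categorical:
        levels = sorted(df[var].dropna().unique(), key=str)
        for level in levels:
            cells = {}
            for name, block in frames.items():
                n = len(block)
                cnt = int((block[var] == level).sum())
                cells[name] = f"{cnt} ({100 * cnt / n:.1f})" if n else "(empty)"
            rows.append((f"{var}={level}", cells))
    for var in flag_cols:
        cells = {}
        for name, block in frames.items():
            n = len(block)
            cnt = int(block[var].astype(bool).sum())
            cells[name] = f"{cnt} ({100 * cnt / n:.1f})" if n else "(empty)"
        rows.append((var, cells))

    out = pd.DataFrame(
        {name: {label: cells[name] for label, cells in rows} for name in frames}
    )
    return out.loc[[label for label, _ in rows]]


def suppress_cells(
    table: pd.DataFrame,
    threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
    complementary: bool = True,
) -> pd.DataFrame:
    """Mask small counts in a table of nonnegative integers.

    Counts strictly between 0 and ``threshold`` become ``"S"``.  When
    ``complementary`` is set and a row margin is assumed printed, a row with
    exactly one masked cell gets its smallest remaining positive cell masked
    too, so the first cannot be recovered by subtraction.  Unsuppressed
    values are never altered.
    """
    values = table.to_numpy()
    if (np.asarray(values, dtype=float) < 0).any():
        raise ValueError("counts must be nonnegative")
    out = table.copy().astype(object)
    mask = (table.to_numpy() > 0) & (table.to_numpy() < threshold)
    for i in range(table.shape[0]):
        row_mask = mask[i].copy()
        if complementary and row_mask.sum() == 1:
            candidates = [
                (table.iat[i, j], j)
                for j in range(table.shape[1])
                if not row_mask[j] and table.iat[i, j] > 0
            ]
            if candidates:
                row_mask[min(candidates)[1]] = True
        for j in range(table.shape[1]):
            if row_mask[j]:
                out.iat[i, j] = SUPPRESSED
    return out
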