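"""Annual counts of care-associated deaths and Poisson trend regression.

The trend model is ``log E[count] = alpha + beta * year`` fitted by
iteratively reweighted least squares implemented here directly (working
response ``z = eta + (y - mu)/mu``, weights ``mu``), with the year covariate
centered at its mean for numerical stability.  Inference on ``beta`` is a
Wald test from the inverse weighted information matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import LTC_SUBGROUPS, CaseCategory

__all__ = ["TrendFit", "annual_counts", "poisson_trend", "plot_trend"]

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 50


def annual_counts(
    df: pd.DataFrame,
    first_report_year: Mapping[str, int],
    years: Tuple[int, int] = (2005, 2015),
    max_first_year: int = 2004,
    category_col: str = "category",
    valid_years: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Count LTC-associated deaths by year and subgroup, zero-filled.

    Restricted to states whose first reporting year is at most
    ``max_first_year`` (the early-reporting states).  ``df`` needs columns
    ``year``, ``state`` and ``category_col``.  If ``valid_years`` is given,
    any record year outside it raises ``ValueError``.
    """
    y0, y1 = years
    if y0 > y1:
        raise ValueError("years must be (first, last) with first <= last")
    if valid_years is not None:
        bad = df[(df["year"] < valid_years[0]) | (df["year"] > valid_years[1])]
        if len(bad):
            raise ValueError(
                f"{len(bad)} records outside valid year range {valid_years}"
            )
    qualifying = {s for s, fy in first_report_year.items() if fy <= max_first_year}
    sub = df[
        df["state"].isin(qualifying)
        & df["year"].between(y0, y1)
        & df[category_col].isin([c.value for c in LTC_SUBGROUPS])
    ]
    index = pd.Index(range(y0, y1 + 1), name="year")
    out = pd.DataFrame(0, index=index, columns=[c.value for c in LTC_SUBGROUPS])
    grouped = sub.groupby(["year", category_col]).size()
    for (year, cat), n in grouped.items():
        out.loc[year, cat] = int(n)
    out["all_ltc"] = out.sum(axis=1)
    return out


@dataclass
class TrendFit:
    beta_year: float
    se: float
    p_value: float
    alpha: float
    fitted: Dict[int, float]
    converged: bool
    iterations: int
    deviance_trace: List[float] = field(default_factory=list)
    flagged: bool = False
    note: str = ""


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_trend(counts: Mapping[int, int] | pd.Series | Sequence[int]) -> TrendFit:
    """Fit the log-linear Poisson trend to a year -> count series.

    Accepts a mapping/Series keyed by year or a plain sequence (years then
    taken as 0..n-1).  Needs at least 3 years of nonnegative integer counts.
    An all-zero series has no finite intercept and returns a flagged fit.
    """
    if isinstance(counts, pd.Series):
        years = np.asarray(counts.index, dtype=float)
        y = counts.to_numpy(dtype=float)
    elif isinstance(counts, Mapping):
        keys = sorted(counts)
        years = np.asarray(keys, dtype=float)
        y = np.asarray([counts[k] for k in keys], dtype=float)
    else:
        y = np.asarray(list(counts), dtype=float)
        years = np.arange(len(y), dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 years of counts")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if y.sum() == 0:
        return TrendFit(
            beta_year=float("nan"), se=float("nan"), p_value=float("nan"),
            alpha=float("-inf"), fitted={int(t): 0.0 for t in years},
            converged=False, iterations=0, flagged=True,
            note="all-zero series: no finite fit",
        )

    x = years - years.mean()  # centering: beta unchanged, intercept shifted
    X = np.column_stack([np.ones_like(x), x])
    beta = np.array([np.log(y.mean()), 0.0])
    trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = X @ beta
        mu = np.exp(eta)
        trace.append(_deviance(y, mu))
        z = eta + (y - mu) / mu
        W = mu
        XtW = X.T * W
        new_beta = np.linalg.solve(XtW @ X, XtW @ z)
        step = np.max(np.abs(new_beta - beta) / (np.abs(beta) + 1.0))
        beta = new_beta
        if step < IRLS_TOL:
            converged = True
            break
    eta = X @ beta
    mu = np.exp(eta)
    trace.append(_deviance(y, mu))
    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    se = float(np.sqrt(cov[1, 1]))
    zstat = beta[1] / se if se > 0 else float("inf")
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    # Report the intercept on the original (uncentered) year scale.
    alpha = float(beta[0] - beta[1] * years.mean())
    return TrendFit(
        beta_year=float(beta[1]), se=se, p_value=p, alpha=alpha,
        fitted={int(t): float(m) for t, m in zip(years, mu)},
        converged=converged, iterations=it, deviance_trace=trace,
        flagged=not converged,
        note="" if converged else f"IRLS did not converge in {it} iterations",
    )


def plot_trend(
    counts: pd.DataFrame, path: Optional[str] = None
):  # pragma: no cover - plotting convenience
    """Plot the annual subgroup series (matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for col in counts.columns:
        if col == "all_ltc":
            continue
        ax.plot(counts.index, counts[col], marker="o", label=col)
    ax.set_xlabel("Year")
    ax.set_ylabel("Deaths")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
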