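"""Agreement analysis between labelings: contingency tables, Cohen's kappa
with its large-sample standard error, and sensitivity/specificity against a
designated criterion standard.

The kappa standard error is the Fleiss–Cohen–Everitt large-sample formula;
the 95% CI is the Wald interval ``kappa +/- 1.96 * se``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "RateEstimate",
    "build_crosstab",
    "cohens_kappa",
    "sensitivity_specificity",
]


@dataclass
class ContingencyTable:
    """Cross-tabulation of two categorical labelings with fixed margins."""

    row_labels: List[Hashable]
    col_labels: List[Hashable]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            row_labels=list(self.col_labels),
            col_labels=list(self.row_labels),
            counts=self.counts.T.copy(),
        )

    def collapse(
        self,
        axis: int,
        mapping: Mapping[Hashable, Hashable],
        order: Optional[Sequence[Hashable]] = None,
    ) -> "ContingencyTable":
        """Pool categories along ``axis`` according to ``mapping``.

        Categories absent from ``mapping`` keep their own label.  The total
        count is conserved.
        """
        labels = self.row_labels if axis == 0 else self.col_labels
        new_of = {lab: mapping.get(lab, lab) for lab in labels}
        new_labels = list(dict.fromkeys(new_of.values())) if order is None else list(order)
        index = {lab: i for i, lab in enumerate(new_labels)}
        if axis == 0:
            out = np.zeros((len(new_labels), len(self.col_labels)), dtype=np.int64)
            for i, lab in enumerate(self.row_labels):
                out[index[new_of[lab]]] += self.counts[i]
            return ContingencyTable(new_labels, list(self.col_labels), out)
        out = np.zeros((len(self.row_labels), len(new_labels)), dtype=np.int64)
        for j, lab in enumerate(self.col_labels):
            out[:, index[new_of[lab]]] += self.counts[:, j]
        return ContingencyTable(list(self.row_labels), new_labels, out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Optional[Sequence[Hashable]] = None,
        col_labels: Optional[Sequence[Hashable]] = None,
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=np.int64)
        rows = list(row_labels) if row_labels is not None else list(range(arr.shape[0]))
        cols = list(col_labels) if col_labels is not None else list(range(arr.shape[1]))
        return cls(rows, cols, arr)


def build_crosstab(
    labels_a: Mapping[str, Hashable],
    labels_b: Mapping[str, Hashable],
    row_order: Optional[Sequence[Hashable]] = None,
    col_order: Optional[Sequence[Hashable]] = None,
) -> ContingencyTable:
    """Exact cross-counts of two labelings over the same id universe."""
    if set(labels_a) != set(labels_b):
        only_a = len(set(labels_a) - set(labels_b))
        only_b = len(set(labels_b) - set(labels_a))
        raise ValueError(
            f"id universes differ ({only_a} only in A, {only_b} only in B)"
        )
    ids = sorted(labels_a)
    a = pd.Categorical(
        [labels_a[i] for i in ids],
        categories=row_order if row_order is not None else None,
    )
    b = pd.Categorical(
        [labels_b[i] for i in ids],
        categories=col_order if col_order is not None else None,
    )
    xt = pd.crosstab(a, b, dropna=False)
    if row_order is not None:
        xt = xt.reindex(index=list(row_order), fill_value=0)
    if col_order is not None:
        xt = xt.reindex(columns=list(col_order), fill_value=0)
    return ContingencyTable(
        row_labels=list(xt.index),
        col_labels=list(xt.columns),
        counts=xt.to_numpy(),
    )


@dataclass
class AgreementResult:
    kappa: float
    se: float
    ci95: Tuple[float, float]
    observed_agreement: float
    expected_agreement: float
    flagged: bool = False
    note: str = ""


def cohens_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa for a square contingency table.

    ``kappa = (po - pe) / (1 - pe)`` with the Fleiss–Cohen–Everitt
    large-sample standard error.  Degenerate margins (``pe = 1``) leave kappa
    undefined and return a flagged result.
    """
    if table.total <= 0:
        raise ValueError("table total must be positive")
    c = table.counts
    if c.shape[0] != c.shape[1]:
        raise ValueError("kappa requires a square table")
    n = table.total
    p = c / n
    pi_ = p.sum(axis=1)
    p_j = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(np.dot(pi_, p_j))
    if pe >= 1.0 - 1e-15:
        return AgreementResult(
            kappa=float("nan"), se=float("nan"),
            ci95=(float("nan"), float("nan")),
            observed_agreement=po, expected_agreement=pe,
            flagged=True, note="degenerate margins: chance agreement is 1",
        )
    kappa = (po - pe) / (1.0 - pe)

    k = c.shape[0]
    term1 = sum(
        p[i, i] * ((1 - pe) - (p_j[i] + pi_[i]) * (1 - po)) ** 2 for i in range(k)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i, j] * (p_j[i] + pi_[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(
        kappa=float(kappa),
        se=se,
        ci95=(float(kappa - 1.96 * se), float(kappa + 1.96 * se)),
        observed_agreement=po,
        expected_agreement=pe,
    )


@dataclass
class RateEstimate:
    value: float
    ci95: Tuple[float, float]
    numerator: int
    denominator: int
    flagged: bool = False


def _clopper_pearson(x: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def sensitivity_specificity(
    table: ContingencyTable,
    gold_axis: str = "columns",
    positive_index: int = 0,
) -> Dict[str, RateEstimate]:
    """Sensitivity and specificity of the row labeling against the gold one.

    ``gold_axis`` names the axis holding the criterion standard;
    ``positive_index`` is the position of the positive category on both axes.
    CIs are exact (Clopper–Pearson) binomial intervals.  With zero gold
    positives (or negatives) the corresponding rate is undefined and flagged.
    """
    c = table.counts
    if c.shape != (2, 2):
        raise ValueError("sensitivity/specificity requires a 2x2 table")
    if gold_axis == "rows":
        c = c.T
    elif gold_axis != "columns":
        raise ValueError("gold_axis must be 'rows' or 'columns'")
    i = positive_index
    j = 1 - i
    tp, fn = int(c[i, i]), int(c[j, i])
    fp, tn = int(c[i, j]), int(c[j, j])

    out: Dict[str, RateEstimate] = {}
    npos, nneg = tp + fn, tn + fp
    if npos:
        out["sensitivity"] = RateEstimate(
            value=tp / npos, ci95=_clopper_pearson(tp, npos),
            numerator=tp, denominator=npos,
        )
    else:
        out["sensitivity"] = RateEstimate(
            value=float("nan"), ci95=(float("nan"), float("nan")),
            numerator=0, denominator=0, flagged=True,
        )
    if nneg:
        out["specificity"] = RateEstimate(
            value=tn / nneg, ci95=_clopper_pearson(tn, nneg),
            numerator=tn, denominator=nneg,
        )
    else:
        out["specificity"] = RateEstimate(
            value=float("nan"), ci95=(float("nan"), float("nan")),
            numerator=0, denominator=0, flagged=True,
        )
    return out
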