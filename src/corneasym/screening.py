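"""Cohort-level statistics for VBS-based keratoconus screening.

Two operations: a Welch (unequal-variance) t comparison of group mean VBS
with a Welch-Satterthwaite confidence interval, and a threshold sweep
producing confusion counts, sensitivity/specificity/PPV/NPV, and ROC points.
The unit of analysis is the eye pair: one VBS value per pair.

Decision rule at a threshold t: screen-positive iff VBS > t (strict), so a
cohort in which no control exceeds t tests all-negative at t exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DimensionError

POSITIVE_LABELS = frozenset({"keratoconus", "kc", "case", "1", "true", "positive"})


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    mean_diff: float  # mean_a - mean_b
    ci95_low: float
    ci95_high: float
    t_statistic: float
    df: float
    p_value: float


@dataclass
class ScreeningTable:
    """One row per threshold with confusion counts and derived rates."""

    table: pd.DataFrame  # columns: threshold_um, TP, FP, TN, FN, sensitivity, ...
    n_positive: int
    n_negative: int

    @property
    def roc_points(self) -> List[tuple]:
        """(false positive rate, sensitivity) per threshold."""
        return [
            (1.0 - row.specificity, row.sensitivity)
            for row in self.table.itertuples()
        ]


def compare_groups(vbs_a: Sequence[float], vbs_b: Sequence[float]) -> GroupComparison:
    """Welch two-sample t comparison of mean VBS, with 95% CI of the
    difference via the Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(vbs_a, dtype=float)
    b = np.asarray(vbs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError(
            f"each group needs n >= 2, got {a.size} and {b.size}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DegenerateDataError("non-finite VBS value in group comparison")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateDataError(
            "both groups have zero variance; the t statistic is undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    se = np.sqrt(va / a.size + vb / b.size)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    diff = a.mean() - b.mean()
    half = stats.t.ppf(0.975, df) * se
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        mean_diff=float(diff),
        ci95_low=float(diff - half),
        ci95_high=float(diff + half),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, (bool, np.bool_)):
            out.append(bool(lab))
        elif isinstance(lab, (int, np.integer)) and lab in (0, 1):
            out.append(bool(lab))
        else:
            out.append(str(lab).strip().lower() in POSITIVE_LABELS)
    return np.asarray(out, dtype=bool)


def screen(
    vbs_values: Sequence[float],
    labels: Sequence,
    thresholds: Sequence[float],
) -> ScreeningTable:
    """Confusion counts and rates at each VBS threshold (positive iff
    VBS > threshold).  PPV/NPV are None when their denominator is zero."""
    v = np.asarray(vbs_values, dtype=float)
    y = _as_binary(labels)
    if v.size != y.size:
        raise DimensionError(
            f"{v.size} VBS values but {y.size} labels"
        )
    if y.all() or not y.any():
        raise DegenerateDataError(
            "screening needs both classes present; got a single-class label set"
        )
    rows = []
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    for t in thresholds:
        pred = v > t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        tn = int((~pred & ~y).sum())
        fn = int((~pred & y).sum())
        ppv: Optional[float] = tp / (tp + fp) if (tp + fp) > 0 else None
        npv: Optional[float] = tn / (tn + fn) if (tn + fn) > 0 else None
        rows.append(
            dict(
                threshold_um=float(t),
                TP=tp,
                FP=fp,
                TN=tn,
                FN=fn,
                sensitivity=tp / n_pos,
                specificity=tn / n_neg,
                ppv=ppv,
                npv=npv,
            )
        )
    return ScreeningTable(table=pd.DataFrame(rows), n_positive=n_pos, n_negative=n_neg)
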