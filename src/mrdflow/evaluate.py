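"""Evaluation statistics for the MRD workflow.

Per-class diagnostic metrics from one-vs-rest confusion counts, rank-based
ROC AUC, exact (Clopper–Pearson) binomial confidence intervals, case-level
MRD-status 2x2 tables, Passing–Bablok method-comparison regression, Pearson
correlation, and the serial-dilution error rules (absolute delta below 1000
expert events, proportionate percent error at or above).

Passing–Bablok here is the original procedure: the slope is the shifted
median of all pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i), with slopes
exactly -1 discarded, 0/0 pairs discarded, the offset K counting slopes
below -1, and rank-order confidence bounds from the Kendall-type normal
approximation. It assumes positively correlated methods measuring the same
quantity; it is scale-invariant and resistant to outliers, which is why it
is the standard for clinical method comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import (
    CLASSES,
    OTHER_CATEGORY_CLASSES,
    OTHER_CATEGORY_NAME,
)

__all__ = [
    "REPORTED_POPULATIONS",
    "population_of",
    "confusion",
    "class_metrics",
    "exact_binomial_ci",
    "roc_auc",
    "status_table",
    "PBRegression",
    "passing_bablok",
    "pearson_r",
    "dilution_errors",
]

#: Display names of the reported populations, in table order.
_DISPLAY = {
    "CLL_cells": "CLL cells",
    "B_cells": "Polytypic B cells",
    "hematogones": "Hematogones",
    "plasma_cells": "Plasma cells",
    "T_cells": "T cells",
    "aggregates": "Aggregates",
    "debris": "Debris",
}

REPORTED_POPULATIONS: tuple[str, ...] = (
    "CLL cells",
    "Polytypic B cells",
    "Hematogones",
    "Plasma cells",
    "T cells",
    "Aggregates",
    "Debris",
    OTHER_CATEGORY_NAME,
)


def population_of(label: str, grouping: bool = True) -> str:
    """Map a raw ontology class to its reported population name."""
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}")
    if grouping and label in OTHER_CATEGORY_CLASSES:
        return OTHER_CATEGORY_NAME
    return _DISPLAY.get(label, label)


def confusion(
    truth: Sequence[str] | np.ndarray,
    predicted: Sequence[str] | np.ndarray,
    grouping: bool = True,
) -> pd.DataFrame:
    """One-vs-rest TP/TN/FP/FN per reported population.

    With ``grouping`` (the default) the seven minor classes (basophils/
    dendritic cells, blasts, erythroblasts, granulocytes, monocytes, NK
    cells, unknown) are merged into "Other cell categories", matching how
    results are reported; each remaining class is its own population.
    """
    t = np.asarray(truth, dtype=object).astype(str)
    p = np.asarray(predicted, dtype=object).astype(str)
    if t.shape != p.shape:
        raise ValueError("truth and prediction must have equal length")
    tt = np.array([population_of(x, grouping) for x in t])
    pp = np.array([population_of(x, grouping) for x in p])
    pops = (
        REPORTED_POPULATIONS
        if grouping
        else tuple(population_of(c, False) for c in CLASSES)
    )
    n = len(t)
    rows = []
    for pop in pops:
        t_is = tt == pop
        p_is = pp == pop
        tp = int(np.sum(t_is & p_is))
        fn = int(np.sum(t_is & ~p_is))
        fp = int(np.sum(~t_is & p_is))
        tn = n - tp - fn - fp
        rows.append({"population": pop, "TP": tp, "TN": tn, "FP": fp, "FN": fn})
    return pd.DataFrame(rows).set_index("population")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def class_metrics(counts: pd.DataFrame | Mapping[str, int]) -> pd.DataFrame:
    """Derive accuracy/sensitivity/specificity/PPV/NPV/F1 from count cells.

    Accepts a confusion DataFrame (per-population rows) or one mapping with
    TP/TN/FP/FN. Ratios with empty denominators (0/0) are NaN rather than
    0, so empty classes do not silently inflate a metric.
    """
    if isinstance(counts, Mapping):
        counts = pd.DataFrame([dict(counts)])
    out = counts.copy()
    tp = counts["TP"].astype(float)
    tn = counts["TN"].astype(float)
    fp = counts["FP"].astype(float)
    fn = counts["FN"].astype(float)
    n = tp + tn + fp + fn
    out["accuracy"] = (tp + tn) / n.where(n > 0, np.nan)
    out["sensitivity"] = tp / (tp + fn).where(tp + fn > 0, np.nan)
    out["specificity"] = tn / (tn + fp).where(tn + fp > 0, np.nan)
    out["PPV"] = tp / (tp + fp).where(tp + fp > 0, np.nan)
    out["NPV"] = tn / (tn + fn).where(tn + fn > 0, np.nan)
    out["F1"] = 2 * tp / (2 * tp + fp + fn).where(2 * tp + fp + fn > 0, np.nan)
    return out


def exact_binomial_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact binomial confidence interval for k/n.

    Beta-quantile formulation; the lower bound is 0 when k = 0 and the
    upper bound is 1 when k = n. Returned as proportions in [0, 1].
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC of a score against binary truth.

    ``truth`` is boolean/0-1 one-vs-rest membership; tied scores receive
    average ranks, so a completely uninformative score gives 0.5.
    """
    y = np.asarray(truth).astype(bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative examples")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Case-level MRD status comparison


def status_table(
    dnn_positive: Sequence[bool] | np.ndarray,
    expert_positive: Sequence[bool] | np.ndarray,
    level: float = 0.95,
) -> dict:
    """2x2 MRD-status comparison (DNN vs expert) with exact CIs.

    Returns the count matrix plus accuracy/sensitivity/specificity/PPV/NPV
    as percents, each with its Clopper–Pearson interval (percent scale).
    The expert call is the reference: sensitivity is the fraction of
    expert-positive cases the DNN also calls positive.
    """
    d = np.asarray(dnn_positive).astype(bool)
    e = np.asarray(expert_positive).astype(bool)
    if d.shape != e.shape:
        raise ValueError("aligned case lists required")
    tp = int(np.sum(d & e))
    tn = int(np.sum(~d & ~e))
    fp = int(np.sum(d & ~e))
    fn = int(np.sum(~d & e))
    n = len(d)

    def prop(k: int, m: int) -> dict:
        if m == 0:
            return {"value": math.nan, "ci": (math.nan, math.nan), "k": k, "n": m}
        lo, hi = exact_binomial_ci(k, m, level)
        return {
            "value": 100.0 * k / m,
            "ci": (100.0 * lo, 100.0 * hi),
            "k": k,
            "n": m,
        }

    return {
        "matrix": pd.DataFrame(
            [[tn, fn], [fp, tp]],
            index=pd.Index(["MRD_negative", "MRD_positive"], name="DNN"),
            columns=pd.Index(["MRD_negative", "MRD_positive"], name="Expert"),
        ),
        "accuracy": prop(tp + tn, n),
        "sensitivity": prop(tp, tp + fn),
        "specificity": prop(tn, tn + fp),
        "PPV": prop(tp, tp + fp),
        "NPV": prop(tn, tn + fn),
    }


# --------------------------------------------------------------------------
# Passing–Bablok regression


@dataclass(frozen=True)
class PBRegression:
    """Passing–Bablok fit: slope and intercept with rank-based 95% CIs."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_points: int
    n_slopes: int
    level: float = 0.95


def _shifted_median(sorted_slopes: np.ndarray, k_offset: int) -> float:
    # The K shift assumes mostly positive correlation; clamp so pathological
    # inputs (almost all slopes below -1) stay in range.
    n = len(sorted_slopes)
    if n % 2 == 1:
        idx = min((n + 1) // 2 + k_offset, n)
        return float(sorted_slopes[idx - 1])
    i1 = min(n // 2 + k_offset, n - 1)
    return float(0.5 * (sorted_slopes[i1 - 1] + sorted_slopes[i1]))


def passing_bablok(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    level: float = 0.95,
) -> PBRegression:
    """Original Passing–Bablok method-comparison regression.

    Pairwise slopes over all C(n,2) point pairs; 0/0 pairs (identical
    points) and slopes exactly -1 are discarded; slopes with zero
    denominator but nonzero numerator enter as signed infinity. The slope
    estimate is the median shifted by K, the number of slopes below -1,
    making the estimator invariant to swapping the two methods. The
    intercept is median(y - slope*x). Confidence bounds use the rank
    indices M1 = round((N - C)/2), M2 = N - M1 + 1 with
    C = z * sqrt(n(n-1)(2n+5)/18); intercept bounds re-use the slope
    bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Passing–Bablok needs at least 3 points")
    if np.unique(x).size == 1:
        raise ValueError("degenerate input: all x values identical")

    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    s[(dx == 0) & (dy > 0)] = np.inf
    s[(dx == 0) & (dy < 0)] = -np.inf
    valid = ~np.isnan(s) & (s != -1.0)
    s = np.sort(s[valid])
    n_slopes = len(s)
    if n_slopes == 0:
        raise ValueError("no valid pairwise slopes")
    k_off = int(np.sum(s < -1.0))

    slope = _shifted_median(s, k_off)
    intercept = (
        float(np.median(y - slope * x)) if math.isfinite(slope) else math.nan
    )

    z = stats.norm.ppf(0.5 + level / 2)
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((n_slopes - c) / 2.0))
    m2 = n_slopes - m1 + 1
    lo_idx = max(m1 + k_off, 1)
    hi_idx = min(m2 + k_off, n_slopes)
    slope_lo = float(s[lo_idx - 1])
    slope_hi = float(s[hi_idx - 1])
    int_lo = float(np.median(y - slope_hi * x)) if np.isfinite(slope_hi) else -math.inf
    int_hi = float(np.median(y - slope_lo * x)) if np.isfinite(slope_lo) else math.inf
    return PBRegression(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope_lo, slope_hi),
        intercept_ci=(int_lo, int_hi),
        n_points=n,
        n_slopes=n_slopes,
        level=level,
    )


def pearson_r(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


# --------------------------------------------------------------------------
# Serial-dilution error analysis

#: Expert counts at or above this use proportionate (%) error; below it,
#: absolute event delta.
PROPORTIONATE_ERROR_THRESHOLD = 1000


def dilution_errors(rows: pd.DataFrame) -> pd.DataFrame:
    """Error columns for a dilution comparison table.

    Input columns: ``expert_count``, ``dnn_count`` and optionally
    ``expert_pct_wbc``, ``dnn_pct_wbc``. For each row, if the expert count
    is >= 1000 the count error is proportionate, 100*(dnn-expert)/expert
    (percent, ``error_type`` = "proportionate"); otherwise it is the
    absolute event delta dnn-expert (``error_type`` = "absolute"). The
    %WBC error is always the absolute difference dnn - expert.
    """
    req = {"expert_count", "dnn_count"}
    if not req.issubset(rows.columns):
        raise ValueError(f"missing columns: {sorted(req - set(rows.columns))}")
    if (rows["expert_count"] < 0).any() or (rows["dnn_count"] < 0).any():
        raise ValueError("counts must be non-negative")
    out = rows.copy()
    expert = out["expert_count"].astype(float)
    dnn = out["dnn_count"].astype(float)
    prop = expert >= PROPORTIONATE_ERROR_THRESHOLD
    out["error_type"] = np.where(prop, "proportionate", "absolute")
    out["error"] = np.where(
        prop,
        100.0 * (dnn - expert) / expert.where(expert > 0, np.nan),
        dnn - expert,
    )
    if {"expert_pct_wbc", "dnn_pct_wbc"}.issubset(out.columns):
        out["abs_error_pct_wbc"] = out["dnn_pct_wbc"] - out["expert_pct_wbc"]
    return out
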