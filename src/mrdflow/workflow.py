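"""Hybrid F-DNN/L-DNN case-level decision logic and MRD quantification.

The cascade: the full-cohort network (F-DNN) classifies every event of a
case. If it finds >= 1000 CLL events, its labels are final. Otherwise the
low-count network (L-DNN) re-classifies all events of the case and its
labels are final. MRD status is positive iff the deciding network's CLL
event count reaches the positivity threshold (20 events — the minimum
reliably defining an abnormal population). The white-cell denominator is
the event count after removing aggregates and debris; CLL burden is
reported as a percent of that denominator and as a count normalized to a
1-million-WBC case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .classifier import TrainedModel, predict
from .fcs_io import CaseSample
from .ontology import CLASSES, WBC_EXCLUDED_CLASSES

__all__ = [
    "HybridConfig",
    "MRDResult",
    "count_class",
    "wbc_denominator",
    "designate_status",
    "analytic_sensitivity",
    "upsample_to_case",
    "hybrid_classify",
    "results_table",
]


@dataclass(frozen=True)
class HybridConfig:
    """Thresholds and denominators of the hybrid decision rule."""

    low_count_threshold: int = 1000
    positivity_threshold: int = 20
    wbc_exclusion_classes: frozenset[str] = WBC_EXCLUDED_CLASSES
    normalization_wbc: int = 1_000_000

    def __post_init__(self) -> None:
        if not self.positivity_threshold < self.low_count_threshold:
            raise ValueError(
                "positivity_threshold must be below low_count_threshold"
            )
        if self.positivity_threshold < 0 or self.normalization_wbc <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(eq=False)
class MRDResult:
    """Per-case MRD call: counts, burden, status, deciding network."""

    case_id: str
    cll_events: int
    wbc_events: int
    pct_wbc: float  # 100 * cll / wbc; NaN when wbc == 0
    normalized_count: float  # cll per 1e6 WBC; NaN when wbc == 0
    status: Literal["MRD_positive", "MRD_negative"]
    deciding_network: Literal["F", "L"]
    f_dnn_cll_events: int | None = None
    predicted_labels: np.ndarray | None = field(default=None, repr=False)


def count_class(labels: Sequence[str] | np.ndarray, cls: str) -> int:
    """Number of events carrying one class label."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    return int(np.sum(np.asarray(labels, dtype=object) == cls))


def wbc_denominator(
    labels: Sequence[str] | np.ndarray, cfg: HybridConfig = HybridConfig()
) -> int:
    """White-cell denominator: total events minus aggregates and debris."""
    arr = np.asarray(labels, dtype=object)
    excluded = np.isin(arr.astype(str), list(cfg.wbc_exclusion_classes))
    return int(len(arr) - excluded.sum())


def designate_status(
    cll_events: int, cfg: HybridConfig = HybridConfig()
) -> Literal["MRD_positive", "MRD_negative"]:
    """MRD-positive iff the CLL event count reaches the 20-event threshold."""
    if cll_events < 0:
        raise ValueError("event count must be >= 0")
    return (
        "MRD_positive"
        if cll_events >= cfg.positivity_threshold
        else "MRD_negative"
    )


def analytic_sensitivity(cfg: HybridConfig = HybridConfig()) -> float:
    """Assay analytic sensitivity in percent of WBC.

    With the defaults (20 events out of 1e6 analyzed white cells) this is
    0.002%.
    """
    return 100.0 * cfg.positivity_threshold / cfg.normalization_wbc


def upsample_to_case(
    count_in_test_split: int,
    wbc_in_test_split: int,
    cfg: HybridConfig = HybridConfig(),
) -> float:
    """Normalize a within-split CLL count to a 1-million-WBC case.

    Test-split events are only ~10% of a case, so counts are first taken as
    a fraction of the split's own WBC denominator, then scaled to the
    normalization denominator. Scale-invariant in the pair of inputs.
    """
    if wbc_in_test_split <= 0:
        raise ValueError("WBC denominator must be > 0")
    return cfg.normalization_wbc * count_in_test_split / wbc_in_test_split


def _quantify(
    case_id: str,
    labels: np.ndarray,
    deciding: Literal["F", "L"],
    f_count: int,
    cfg: HybridConfig,
    keep_labels: bool,
) -> MRDResult:
    cll = count_class(labels, "CLL_cells")
    wbc = wbc_denominator(labels, cfg)
    if wbc > 0:
        pct = 100.0 * cll / wbc
        norm = cfg.normalization_wbc * cll / wbc
    else:  # all-aggregate/debris case: burden undefined, status from raw count
        pct = math.nan
        norm = math.nan
    return MRDResult(
        case_id=case_id,
        cll_events=cll,
        wbc_events=wbc,
        pct_wbc=pct,
        normalized_count=norm,
        status=designate_status(cll, cfg),
        deciding_network=deciding,
        f_dnn_cll_events=f_count,
        predicted_labels=labels if keep_labels else None,
    )


def hybrid_classify(
    case: CaseSample,
    f_model: TrainedModel,
    l_model: TrainedModel,
    cfg: HybridConfig = HybridConfig(),
    *,
    keep_labels: bool = False,
) -> MRDResult:
    """Run the hybrid cascade on one case.

    F-DNN classifies all events; with >= ``low_count_threshold`` predicted
    CLL events its labels are final (deciding network F). Below the
    threshold the L-DNN re-classifies all events and its labels are final
    (deciding network L). Status, %WBC and the normalized count come from
    the deciding network's labels.
    """
    f_pred = predict(f_model, case.events)
    f_labels = f_pred.predicted_labels
    f_count = count_class(f_labels, "CLL_cells")
    if f_count >= cfg.low_count_threshold:
        return _quantify(case.case_id, f_labels, "F", f_count, cfg, keep_labels)
    l_pred = predict(l_model, case.events)
    return _quantify(
        case.case_id, l_pred.predicted_labels, "L", f_count, cfg, keep_labels
    )


def results_table(results: Sequence[MRDResult]) -> pd.DataFrame:
    """Tabulate MRD results, one row per case."""
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "cll_events": r.cll_events,
                "wbc_events": r.wbc_events,
                "pct_wbc": r.pct_wbc,
                "normalized_count": r.normalized_count,
                "status": r.status,
                "deciding_network": r.deciding_network,
                "f_dnn_cll_events": r.f_dnn_cll_events,
            }
            for r in results
        ]
    )
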