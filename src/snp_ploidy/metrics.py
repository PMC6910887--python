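"""Confusion-matrix performance metrics and batch evaluation.

Sensitivity, specificity and accuracy follow the standard clinical
definitions on counts (tp, fp, fn, tn): sensitivity tp/(tp+fn),
specificity tn/(fp+tn), accuracy (tp+tn)/total, each as a percentage to
two decimals.  Inconclusive calls are excluded from the matrix (the
clinical path for them is a retest, not a verdict) and reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classifier import PloidyCall


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Percentages to 2 d.p.; None where the denominator is zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]


def confusion_metrics(cc: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity, specificity and accuracy (percent, 2 d.p.)."""

    def pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else round(100.0 * num / den, 2)

    return PerformanceMetrics(
        sensitivity=pct(cc.tp, cc.tp + cc.fn),
        specificity=pct(cc.tn, cc.fp + cc.tn),
        accuracy=pct(cc.tp + cc.tn, cc.total),
    )


def evaluate_batch(
    calls: Mapping[str, PloidyCall] | Sequence[PloidyCall],
    truth: pd.DataFrame,
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Cross-tabulate ploidy calls against a truth table.

    ``truth`` needs columns sample_id and ploidy ("diploid"/"triploid").
    Triploid and triploid_low_confidence both count as positive calls;
    inconclusive samples are excluded from the counts but present in the
    returned per-sample join (column ``counted`` False).
    """
    if not isinstance(calls, Mapping):
        calls = {c.sample_id: c for c in calls}
    truth_map = dict(zip(truth["sample_id"], truth["ploidy"]))
    missing = set(calls) - set(truth_map)
    if missing:
        raise KeyError(f"samples without truth entries: {sorted(missing)}")

    rows = []
    tp = fp = fn = tn = 0
    for sid, call in calls.items():
        true_pos = truth_map[sid] == "triploid"
        counted = call.verdict != "inconclusive"
        if counted:
            called_pos = call.is_positive
            if called_pos and true_pos:
                tp += 1
            elif called_pos:
                fp += 1
            elif true_pos:
                fn += 1
            else:
                tn += 1
        rows.append({
            "sample_id": sid, "truth": truth_map[sid], "verdict": call.verdict,
            "ratio": call.ratio, "z": call.z, "counted": counted,
            "flags": ",".join(sorted(call.flags)),
        })
    join = pd.DataFrame(rows)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn), join
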