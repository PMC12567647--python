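"""Fertile-window construction, day-level classification and diagnostic metrics.

Every day of every evaluable cycle is labelled by its membership in the
predicted (temperature-derived) versus reference (LH-derived) fertile
window: TP (both), FP (predicted only), FN (reference only), TN
(neither).  Pooled counts feed the usual diagnostic proportions —
sensitivity, specificity, accuracy, PPV, NPV — each with an exact
Clopper–Pearson 95% interval, plus a cycle-level concordance summary of
the temperature-vs-LH ovulation-day differences.

Two window conventions are supported:

``SURGE10``
    Reference window spans surge−6 .. surge+3 (10 days); the predicted
    window is the temperature ovulation estimate ±2 days plus the five
    preceding days, i.e. a_edo−7 .. a_edo+2.
``WILCOX6``
    The classical six fertile days: the day of ovulation and the five
    preceding days, applied symmetrically to both estimates.

Both windows are closed day-index intervals clipped to the cycle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "WindowMode",
    "WindowKind",
    "DayLabel",
    "FertileWindow",
    "ConfusionTable",
    "MetricEstimate",
    "ConcordanceSummary",
    "predicted_fertile_window",
    "peri_ovulatory_period",
    "classify_days",
    "accumulate",
    "exact_binomial_interval",
    "performance_metrics",
    "concordance",
    "percent_str",
]

#: Cycle-level concordance band: a_edo − surge_day within [−1, +3] counts as
#: agreement, i.e. the temperature estimate within ±2 days of the LH-derived
#: ovulation day (surge + 1).
CONCORDANCE_DIFF_RANGE = (-1, 3)


class WindowMode(enum.Enum):
    SURGE10 = "surge10"
    WILCOX6 = "wilcox6"


class WindowKind(enum.Enum):
    PREDICTED = "predicted"
    REFERENCE = "reference"


class DayLabel(enum.Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


def clip_interval(start: int, end: int, length: int | None) -> tuple[int, int]:
    """Clip a closed day interval to [1, length] (no upper clip if length is None)."""
    lo = max(1, start)
    hi = end if length is None else min(end, length)
    return lo, hi


@dataclass(frozen=True)
class FertileWindow:
    """Closed interval of fertile day indices within one cycle."""

    start_day: int
    end_day: int
    kind: WindowKind
    mode: WindowMode

    def __post_init__(self) -> None:
        if not (1 <= self.start_day <= self.end_day):
            raise ValueError(
                f"invalid window [{self.start_day}, {self.end_day}]"
            )

    @property
    def days(self) -> range:
        return range(self.start_day, self.end_day + 1)

    def __contains__(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day

    def __len__(self) -> int:
        return self.end_day - self.start_day + 1


def predicted_fertile_window(
    a_edo: int, mode: WindowMode, cycle_length: int
) -> FertileWindow:
    """Predicted fertile window around the temperature ovulation estimate.

    SURGE10: a_edo ±2 days plus the five days before that band, i.e.
    [a_edo−7, a_edo+2].  WILCOX6: [a_edo−5, a_edo].  Clipped to the cycle.
    """
    if mode is WindowMode.SURGE10:
        lo, hi = a_edo - 7, a_edo + 2
    elif mode is WindowMode.WILCOX6:
        lo, hi = a_edo - 5, a_edo
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(mode)
    lo, hi = clip_interval(lo, hi, cycle_length)
    return FertileWindow(lo, hi, WindowKind.PREDICTED, mode)


def peri_ovulatory_period(
    a_edo: int, cycle_length: int | None = None
) -> tuple[int, int]:
    """The peri-ovulatory period: ovulation estimate ±2 days, clipped."""
    return clip_interval(a_edo - 2, a_edo + 2, cycle_length)


def classify_days(
    cycle_length: int, predicted: FertileWindow, reference: FertileWindow
) -> list[DayLabel]:
    """Label every day 1..cycle_length by predicted/reference window membership."""
    labels = []
    for day in range(1, cycle_length + 1):
        in_p = day in predicted
        in_r = day in reference
        if in_p and in_r:
            labels.append(DayLabel.TP)
        elif in_p:
            labels.append(DayLabel.FP)
        elif in_r:
            labels.append(DayLabel.FN)
        else:
            labels.append(DayLabel.TN)
    return labels


@dataclass(frozen=True)
class ConfusionTable:
    """Pooled day-level counts."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_labels(cls, labels: Iterable[DayLabel]) -> "ConfusionTable":
        counts = {lab: 0 for lab in DayLabel}
        for lab in labels:
            counts[lab] += 1
        return cls(
            tp=counts[DayLabel.TP],
            tn=counts[DayLabel.TN],
            fp=counts[DayLabel.FP],
            fn=counts[DayLabel.FN],
        )


def accumulate(label_sequences: Iterable[Sequence[DayLabel]]) -> ConfusionTable:
    """Sum per-cycle label sequences into one pooled table."""
    table = ConfusionTable()
    for labels in label_sequences:
        table = table + ConfusionTable.from_labels(labels)
    return table


def exact_binomial_interval(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided exact (Clopper–Pearson) confidence interval for a proportion.

    The bounds invert the binomial tail probabilities; successes = 0
    gives a lower bound of exactly 0 and successes = trials an upper
    bound of exactly 1.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN rather than the exact boundary at 0 or n
    low = 0.0 if successes == 0 else float(low)
    high = 1.0 if successes == trials else float(high)
    return low, high


def percent_str(p: float, decimals: int = 1) -> str:
    """Format a proportion as a percentage, round-half-up."""
    q = Decimal(p * 100).quantize(Decimal(f"0.{'0' * decimals}") if decimals else Decimal("1"),
                                  rounding=ROUND_HALF_UP)
    return f"{q}"


@dataclass(frozen=True)
class MetricEstimate:
    """A diagnostic proportion with its counts and exact 95% interval.

    ``point``/``ci_low``/``ci_high`` are None when the denominator is
    zero (the metric is undefined, not a number).
    """

    name: str
    numerator: int
    denominator: int
    point: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.point is not None

    def formatted(self) -> str:
        """Render as e.g. ``96.8% (95.6; 97.7)`` (one decimal, round-half-up)."""
        if not self.defined:
            return "undefined"
        return (
            f"{percent_str(self.point)}% "
            f"({percent_str(self.ci_low)}; {percent_str(self.ci_high)})"
        )


METRIC_DEFS: Mapping[str, tuple[str, str]] = {
    # metric -> (numerator count attr, denominator = num + other attr)
    "sensitivity": ("tp", "fn"),
    "specificity": ("tn", "fp"),
    "ppv": ("tp", "fp"),
    "npv": ("tn", "fn"),
}


def performance_metrics(
    table: ConfusionTable, level: float = 0.95
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, accuracy, PPV and NPV from pooled counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total; PPV = TP/(TP+FP); NPV = TN/(TN+FN).
    Each carries an exact Clopper–Pearson interval at ``level``.
    """
    out: dict[str, MetricEstimate] = {}

    def make(name: str, num: int, den: int) -> MetricEstimate:
        if den == 0:
            return MetricEstimate(name, num, den, None, None, None)
        low, high = exact_binomial_interval(num, den, level)
        return MetricEstimate(name, num, den, num / den, low, high)

    for name, (num_attr, other_attr) in METRIC_DEFS.items():
        num = getattr(table, num_attr)
        den = num + getattr(table, other_attr)
        out[name] = make(name, num, den)
    out["accuracy"] = make("accuracy", table.tp + table.tn, table.total)
    # canonical reporting order
    order = ["sensitivity", "specificity", "accuracy", "ppv", "npv"]
    return {k: out[k] for k in order}


@dataclass(frozen=True)
class ConcordanceSummary:
    """Cycle-level agreement between temperature and LH ovulation estimates.

    ``diffs`` holds a_edo − surge_day per evaluable cycle.  A cycle is
    concordant ("within") when the difference lies in [−1, +3], delayed
    above, early below.
    """

    diffs: tuple[int, ...]
    mean_diff: float
    sd_diff: float
    n_within: int
    n_delayed: int
    n_early: int
    histogram: dict[int, int]

    @property
    def n(self) -> int:
        return len(self.diffs)

    @property
    def proportion_within(self) -> float:
        return self.n_within / self.n


def concordance(pairs: Iterable[tuple[int, int]]) -> ConcordanceSummary:
    """Summarise per-cycle (a_edo, surge_day) pairs.

    Parameters
    ----------
    pairs
        One (temperature ovulation day, LH surge day) pair per cycle with
        both a valid surge call and a detected temperature estimate.
    """
    diffs = tuple(int(a) - int(s) for a, s in pairs)
    if not diffs:
        raise ValueError("concordance requires at least one evaluable cycle")
    arr = np.asarray(diffs, dtype=float)
    lo, hi = CONCORDANCE_DIFF_RANGE
    n_within = int(np.sum((arr >= lo) & (arr <= hi)))
    n_delayed = int(np.sum(arr > hi))
    n_early = int(np.sum(arr < lo))
    hist: dict[int, int] = {}
    for d in sorted(diffs):
        hist[d] = hist.get(d, 0) + 1
    return ConcordanceSummary(
        diffs=diffs,
        mean_diff=float(arr.mean()),
        sd_diff=float(arr.std(ddof=1)) if len(diffs) > 1 else 0.0,
        n_within=n_within,
        n_delayed=n_delayed,
        n_early=n_early,
        histogram=hist,
    )
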