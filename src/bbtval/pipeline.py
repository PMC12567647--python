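"""End-to-end validation pipeline: screening -> surge calling -> detection
-> windows -> day-level metrics -> concordance -> luteal profiles.

The pipeline never drops a cycle silently: every run produces a manifest
whose counts reconcile exactly (read = eligible + ineligible; eligible =
evaluable + excluded-with-reason).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .cycle_model import Cycle, eligibility_filter, EligibilityDecision
from .edo_detection import (
    DetectionStatus,
    DetectorConfig,
    OvulationEstimate,
    detect_edo,
    impute_missing,
    pad_to_35,
    PADDED_LENGTH,
)
from .lh_reference import LHSurgeCall, SurgeStatus, find_lh_surge, reference_fertile_window
from .luteal_profiling import LutealConfig, luteal_profile
from .window_validation import (
    ConcordanceSummary,
    ConfusionTable,
    DayLabel,
    WindowMode,
    accumulate,
    classify_days,
    concordance,
    performance_metrics,
    predicted_fertile_window,
)

__all__ = ["PipelineConfig", "CycleResult", "ValidationResult", "validate_cycles", "write_outputs"]


@dataclass(frozen=True)
class PipelineConfig:
    window_mode: WindowMode = WindowMode.SURGE10
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    luteal: LutealConfig = field(default_factory=LutealConfig)
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "window_mode": self.window_mode.value,
            "detector": {
                "min_shift_c": self.detector.min_shift_c,
                "search_start": self.detector.search_start,
                "search_end_offset": self.detector.search_end_offset,
            },
            "luteal": {
                "amplitude_low_cut": self.luteal.amplitude_low_cut,
                "amplitude_high_cut": self.luteal.amplitude_high_cut,
                "rapid_rise_days": self.luteal.rapid_rise_days,
                "fluctuation_cut": self.luteal.fluctuation_cut,
                "terminal_days": self.luteal.terminal_days,
                "min_amplitude_for_decline": self.luteal.min_amplitude_for_decline,
            },
            "ci_level": self.ci_level,
        }


@dataclass
class CycleResult:
    """Everything the pipeline decided about one cycle."""

    cycle: Cycle
    eligibility: EligibilityDecision
    surge: LHSurgeCall
    estimate: OvulationEstimate | None
    labels: list[DayLabel] | None
    exclusion: str | None  # None iff the cycle contributed to the metrics

    @property
    def evaluable(self) -> bool:
        return self.exclusion is None


@dataclass
class ValidationResult:
    per_cycle: list[CycleResult]
    confusion: ConfusionTable
    metrics: dict
    concord: ConcordanceSummary | None
    luteal: pd.DataFrame
    manifest: dict

    def per_cycle_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_cycle:
            est = r.estimate
            rows.append(
                {
                    "cycle_id": r.cycle.cycle_id,
                    "woman_id": r.cycle.woman_id,
                    "length": r.cycle.length,
                    "eligible": r.eligibility.eligible,
                    "eligibility_reasons": ";".join(
                        sorted(x.value for x in r.eligibility.reasons)
                    ),
                    "surge_status": r.surge.status.value,
                    "surge_day": r.surge.surge_day,
                    "lh_edo": r.surge.lh_edo,
                    "detection_status": "" if est is None else est.status.value,
                    "a_edo": None if est is None else est.a_edo,
                    "shift_c": None if est is None else est.shift_estimate,
                    "fit_score": None if est is None else est.fit_score,
                    "exclusion": r.exclusion or "",
                }
            )
        return pd.DataFrame(rows)

    def labels_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_cycle:
            if r.labels is None:
                continue
            for day, lab in enumerate(r.labels, start=1):
                rows.append({"cycle_id": r.cycle.cycle_id, "day": day, "label": lab.value})
        return pd.DataFrame(rows, columns=["cycle_id", "day", "label"])

    def concordance_frame(self) -> pd.DataFrame:
        rows = []
        lo, hi = -1, 3
        for r in self.per_cycle:
            if not r.evaluable:
                continue
            diff = r.estimate.a_edo - r.surge.surge_day
            cat = "within" if lo <= diff <= hi else ("delayed" if diff > hi else "early")
            rows.append(
                {
                    "cycle_id": r.cycle.cycle_id,
                    "a_edo": r.estimate.a_edo,
                    "surge_day": r.surge.surge_day,
                    "diff": diff,
                    "category": cat,
                }
            )
        return pd.DataFrame(rows, columns=["cycle_id", "a_edo", "surge_day", "diff", "category"])


def _detect(cycle: Cycle, config: PipelineConfig) -> OvulationEstimate | None:
    """Run imputation -> padding -> detection when the series admits it."""
    if cycle.n_recorded == 0 or cycle.length > PADDED_LENGTH:
        return None
    series = impute_missing(cycle)
    return detect_edo(pad_to_35(series), config.detector)


def validate_cycles(
    cycles: Iterable[Cycle],
    config: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> ValidationResult:
    """Run the full validation over a cohort of cycles.

    Per cycle: call the LH surge; estimate the luteal length (from the
    LH-derived ovulation day when the surge is valid, else from the
    temperature estimate, else unknown) for the screening step; if
    eligible, estimate the temperature ovulation day, build the
    predicted and reference fertile windows, and label every day.
    Cycles with no valid surge, an ambiguous surge, or no detected
    temperature rise are excluded from the pooled metrics, with the
    exclusion recorded.
    """
    results: list[CycleResult] = []
    luteal_rows = []

    for cycle in cycles:
        surge = find_lh_surge(cycle)
        estimate = _detect(cycle, config)

        if surge.status is SurgeStatus.VALID:
            luteal_len = cycle.length - surge.lh_edo + 1
        elif estimate is not None and estimate.status is DetectionStatus.DETECTED:
            luteal_len = cycle.length - estimate.a_edo + 1
        else:
            luteal_len = None
        decision = eligibility_filter(cycle, luteal_len)

        labels = None
        exclusion: str | None = None
        if not decision.eligible:
            exclusion = "ineligible:" + ";".join(sorted(x.value for x in decision.reasons))
        elif surge.status is not SurgeStatus.VALID:
            exclusion = f"surge:{surge.status.value}"
        elif estimate is None or estimate.status is not DetectionStatus.DETECTED:
            exclusion = "detection:NOT_DETECTED"
        else:
            predicted = predicted_fertile_window(
                estimate.a_edo, config.window_mode, cycle.length
            )
            reference = reference_fertile_window(surge, config.window_mode, cycle.length)
            labels = classify_days(cycle.length, predicted, reference)

            anchor = surge.surge_day
            if anchor >= 8 and cycle.length - anchor >= 5:
                prof = luteal_profile(cycle, anchor, config.luteal)
                luteal_rows.append(
                    {
                        "cycle_id": cycle.cycle_id,
                        "anchor_day": anchor,
                        "amplitude_c": prof.amplitude,
                        "amplitude_class": prof.amplitude_class.value,
                        "rise_class": prof.rise_class.value,
                        "premature_decline": prof.premature_decline,
                        "fluctuation_index_c": prof.fluctuation_index,
                        "fluctuation_class": prof.fluctuation_class.value,
                    }
                )

        results.append(CycleResult(cycle, decision, surge, estimate, labels, exclusion))

    evaluable = [r for r in results if r.evaluable]
    confusion = accumulate(r.labels for r in evaluable)
    metrics = performance_metrics(confusion, config.ci_level) if confusion.total else {}
    concord = (
        concordance((r.estimate.a_edo, r.surge.surge_day) for r in evaluable)
        if evaluable
        else None
    )

    n_read = len(results)
    n_eligible = sum(r.eligibility.eligible for r in results)
    excl_counts: dict[str, int] = {}
    for r in results:
        if r.exclusion and r.eligibility.eligible:
            excl_counts[r.exclusion] = excl_counts.get(r.exclusion, 0) + 1
    manifest = {
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
        "config": config.to_dict(),
        "counts": {
            "read": n_read,
            "ineligible": n_read - n_eligible,
            "eligible": n_eligible,
            "evaluable": len(evaluable),
            "excluded": excl_counts,
        },
    }
    luteal_df = pd.DataFrame(
        luteal_rows,
        columns=[
            "cycle_id",
            "anchor_day",
            "amplitude_c",
            "amplitude_class",
            "rise_class",
            "premature_decline",
            "fluctuation_index_c",
            "fluctuation_class",
        ],
    )
    return ValidationResult(results, confusion, metrics, concord, luteal_df, manifest)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def metrics_to_dict(metrics: dict) -> dict:
    out = {}
    for name, m in metrics.items():
        out[name] = {
            "numerator": m.numerator,
            "denominator": m.denominator,
            "point": m.point,
            "ci_low": m.ci_low,
            "ci_high": m.ci_high,
            "formatted": m.formatted(),
        }
    return out


def write_outputs(result: ValidationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard output files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["metrics"] = outdir / "metrics.json"
    payload = {
        "confusion": {
            "tp": result.confusion.tp,
            "tn": result.confusion.tn,
            "fp": result.confusion.fp,
            "fn": result.confusion.fn,
            "total": result.confusion.total,
        },
        "metrics": metrics_to_dict(result.metrics),
    }
    if result.concord is not None:
        payload["concordance"] = {
            "n": result.concord.n,
            "n_within": result.concord.n_within,
            "n_delayed": result.concord.n_delayed,
            "n_early": result.concord.n_early,
            "proportion_within": result.concord.proportion_within,
            "mean_diff": result.concord.mean_diff,
            "sd_diff": result.concord.sd_diff,
        }
    paths["metrics"].write_text(json.dumps(payload, indent=2))

    paths["per_cycle"] = outdir / "per_cycle.csv"
    result.per_cycle_frame().to_csv(paths["per_cycle"], index=False)
    paths["labels"] = outdir / "per_day_labels.csv"
    result.labels_frame().to_csv(paths["labels"], index=False)
    paths["concordance"] = outdir / "concordance.csv"
    result.concordance_frame().to_csv(paths["concordance"], index=False)
    paths["luteal"] = outdir / "luteal_profiles.csv"
    result.luteal.to_csv(paths["luteal"], index=False)

    if result.concord is not None:
        hist = pd.DataFrame(
            sorted(result.concord.histogram.items()), columns=["diff", "count"]
        )
    else:
        hist = pd.DataFrame(columns=["diff", "count"])
    paths["histogram"] = outdir / "histogram.csv"
    hist.to_csv(paths["histogram"], index=False)

    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2))
    return paths
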