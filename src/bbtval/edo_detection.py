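"""Temperature-based ovulation-day estimation (A-EDO).

The biphasic BBT curve — follicular baseline, post-ovulatory rise of
roughly 0.1–0.5 degC to a luteal plateau — is summarised by a two-level
step model.  For every candidate rise day tau the series is split into a
low segment (days before tau) and a high segment (day tau to the end of
the cycle); the tau minimising the residual sum of squares of the
two-mean fit is the estimated first elevated day, and the A-EDO.  A
detection is reported only when the fitted step height reaches a minimum
shift (default 0.10 degC, the smallest luteal plateau amplitude seen in
practice).

Series are imputed to a complete daily grid and padded to a fixed length
of 35 values (repeating the final observation) to match the fixed-length
input convention of deployed cycle-analysis models; padded days carry no
weight in the fit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cycle_model import Cycle

__all__ = [
    "PADDED_LENGTH",
    "DetectionStatus",
    "DetectorConfig",
    "PaddedSeries",
    "OvulationEstimate",
    "impute_missing",
    "pad_to_35",
    "detect_edo",
]

#: Fixed input length: one value per day of the longest admissible cycle.
PADDED_LENGTH = 35


class DetectionStatus(enum.Enum):
    DETECTED = "DETECTED"
    NOT_DETECTED = "NOT_DETECTED"


@dataclass(frozen=True)
class DetectorConfig:
    """Settings for the step-fit detector.

    min_shift_c
        Smallest step height (degC) accepted as a genuine luteal rise.
    search_start
        First candidate rise day; keeps at least 5 follicular days in
        the low segment.
    search_end_offset
        Candidate rise days stop this many days before the cycle end,
        keeping at least that many luteal days in the high segment.
    """

    min_shift_c: float = 0.10
    search_start: int = 6
    search_end_offset: int = 4


@dataclass(frozen=True)
class PaddedSeries:
    """A complete temperature series padded to exactly 35 daily values."""

    values: tuple[float, ...]
    original_length: int

    def __post_init__(self) -> None:
        if len(self.values) != PADDED_LENGTH:
            raise ValueError(f"padded series must have {PADDED_LENGTH} values")
        if not (1 <= self.original_length <= PADDED_LENGTH):
            raise ValueError("original_length must be in 1..35")
        tail = self.values[self.original_length:]
        if any(v != self.values[self.original_length - 1] for v in tail):
            raise ValueError("padding must repeat the final observed value")


@dataclass(frozen=True)
class OvulationEstimate:
    """Step-fit result: the estimated first elevated day and diagnostics.

    ``rise_day`` and ``shift_estimate`` are populated whenever a fit was
    possible (also for NOT_DETECTED, as diagnostics); ``a_edo`` only for
    DETECTED.  ``fit_score`` is the residual sum-of-squares reduction of
    the two-level fit relative to a single flat mean.
    """

    status: DetectionStatus
    a_edo: int | None = None
    rise_day: int | None = None
    shift_estimate: float | None = None
    fit_score: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.status is DetectionStatus.DETECTED:
            if self.a_edo is None or self.a_edo != self.rise_day:
                raise ValueError("DETECTED requires a_edo == rise_day")


def impute_missing(cycle: Cycle) -> np.ndarray:
    """Complete daily temperature sequence for one cycle.

    Interior gaps are filled by linear interpolation between the nearest
    recorded neighbours; leading/trailing gaps take the nearest recorded
    value.  Recorded values pass through untouched.
    """
    temps = cycle.temperatures
    recorded = ~np.isnan(temps)
    if not recorded.any():
        raise ValueError(f"cycle {cycle.cycle_id!r}: no recorded temperatures")
    days = np.arange(1, cycle.length + 1, dtype=float)
    # np.interp is linear inside the recorded range and constant outside it
    return np.interp(days, days[recorded], temps[recorded])


def pad_to_35(series: Sequence[float]) -> PaddedSeries:
    """Pad a complete series to 35 values by repeating the final temperature."""
    values = [float(v) for v in series]
    n = len(values)
    if not (1 <= n <= PADDED_LENGTH):
        raise ValueError(f"series length {n} outside 1..{PADDED_LENGTH}")
    values.extend([values[-1]] * (PADDED_LENGTH - n))
    return PaddedSeries(values=tuple(values), original_length=n)


def _step_fit(x: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-mean fit: for each tau return (RSS, high−low shift).

    Day tau (1-based) starts the high segment; the low segment is days
    1..tau−1.  RSS(tau) = sum(x²) − n1·m1² − n2·m2².
    """
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    n1 = taus - 1
    n2 = n - n1
    s1 = csum[n1]
    s2 = csum[n] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    rss = csq[n] - n1 * m1**2 - n2 * m2**2
    return rss, m2 - m1


def detect_edo(
    series: PaddedSeries, config: DetectorConfig = DetectorConfig()
) -> OvulationEstimate:
    """Estimate the ovulation day from a padded temperature series.

    Fits the two-level step model at every candidate rise day in
    ``[search_start, original_length − search_end_offset]`` over the
    observed days only (padding excluded), picks the residual-minimising
    day (ties to the earliest), and reports DETECTED when the fitted
    upward shift is at least ``min_shift_c``.
    """
    n = series.original_length
    lo = config.search_start
    hi = n - config.search_end_offset
    if hi < lo:
        return OvulationEstimate(
            DetectionStatus.NOT_DETECTED,
            note=f"cycle of {n} days too short for search range [{lo}, {hi}]",
        )
    x = np.asarray(series.values[:n], dtype=float)
    taus = np.arange(lo, hi + 1)
    rss, shifts = _step_fit(x, taus)
    best = int(np.argmin(rss))  # argmin takes the first minimum: earliest tau
    tau = int(taus[best])
    shift = float(shifts[best])
    rss_flat = float(np.sum((x - x.mean()) ** 2))
    score = rss_flat - float(rss[best])
    if shift >= config.min_shift_c:
        return OvulationEstimate(
            DetectionStatus.DETECTED,
            a_edo=tau,
            rise_day=tau,
            shift_estimate=shift,
            fit_score=score,
        )
    return OvulationEstimate(
        DetectionStatus.NOT_DETECTED,
        rise_day=tau,
        shift_estimate=shift,
        fit_score=score,
        note=f"best step {shift:.3f} degC below min_shift {config.min_shift_c:.3f}",
    )
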