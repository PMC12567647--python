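"""Domain types for daily menstrual-cycle records, CSV IO, and eligibility screening.

A cycle is a 1-based sequence of days starting on the first day of
menstruation.  Each day carries an overnight basal body temperature (BBT,
degrees Celsius, possibly missing) and an LH urine-test result.  Cycles
enter the validation analysis only if they satisfy the screening rules:
at least 80% of days with a recorded temperature, total length between
24 and 35 days, and (when estimable) a post-ovulatory phase of 9 to 20
days.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LHResult",
    "DailyRecord",
    "Cycle",
    "EligibilityDecision",
    "CycleFormatError",
    "read_cycles",
    "write_cycles",
    "eligibility_filter",
    "COVERAGE_MIN",
    "LENGTH_RANGE",
    "LUTEAL_RANGE",
]

#: Inclusive screening bounds.
COVERAGE_MIN = 0.80
LENGTH_RANGE = (24, 35)
LUTEAL_RANGE = (9, 20)

#: Physiological plausibility bounds for a recorded BBT, degrees Celsius.
TEMP_BOUNDS = (30.0, 42.0)

#: Decimal places kept in the CSV interchange format.
CSV_TEMP_DECIMALS = 2

CSV_COLUMNS = ["cycle_id", "woman_id", "day", "temperature_c", "lh_result"]


class LHResult(enum.Enum):
    """Outcome of a daily urine LH test."""

    POSITIVE = "pos"
    NEGATIVE = "neg"
    NOT_TESTED = ""


class CycleFormatError(ValueError):
    """Raised for malformed cycle tables (duplicate or non-contiguous days)."""


@dataclass(frozen=True)
class DailyRecord:
    """One day of a cycle: day index, temperature (or None), LH result."""

    day: int
    temperature: float | None
    lh_result: LHResult = LHResult.NOT_TESTED

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        t = self.temperature
        if t is not None:
            if not math.isfinite(t):
                raise ValueError("temperature must be finite or None")
            if not (TEMP_BOUNDS[0] <= t <= TEMP_BOUNDS[1]):
                raise ValueError(
                    f"temperature {t} degC outside plausible range {TEMP_BOUNDS}"
                )


@dataclass(frozen=True)
class Cycle:
    """A complete menstrual cycle: one :class:`DailyRecord` per day 1..length."""

    cycle_id: str
    woman_id: str
    records: tuple[DailyRecord, ...]

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        if not days:
            raise ValueError("cycle must contain at least one day")
        if days != list(range(1, len(days) + 1)):
            raise CycleFormatError(
                f"cycle {self.cycle_id!r}: days must be exactly 1..length, got {days[:5]}..."
            )

    @property
    def length(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        """Temperatures as a float array with NaN on missing days."""
        return np.array(
            [np.nan if r.temperature is None else r.temperature for r in self.records],
            dtype=float,
        )

    @property
    def n_recorded(self) -> int:
        return sum(r.temperature is not None for r in self.records)

    @property
    def coverage_fraction(self) -> float:
        return self.n_recorded / self.length

    def positive_days(self) -> list[int]:
        return [r.day for r in self.records if r.lh_result is LHResult.POSITIVE]


class EligibilityReason(enum.Enum):
    COVERAGE = "COVERAGE"
    LENGTH = "LENGTH"
    LUTEAL = "LUTEAL"


@dataclass(frozen=True)
class EligibilityDecision:
    """Screening outcome; ``eligible`` iff no criterion failed."""

    eligible: bool
    reasons: frozenset[EligibilityReason]
    coverage_fraction: float
    luteal_length: int | None

    def __post_init__(self) -> None:
        assert self.eligible == (not self.reasons)


def eligibility_filter(cycle: Cycle, luteal_length: int | None = None) -> EligibilityDecision:
    """Apply the inclusion criteria to one cycle.

    Parameters
    ----------
    cycle
        The cycle under screening.
    luteal_length
        Estimated post-ovulatory phase length in days, or None when no
        ovulation estimate exists; the luteal criterion then passes
        vacuously.

    Returns
    -------
    EligibilityDecision
        ``eligible`` is True iff temperature coverage >= 80%, length is
        within 24..35 days and, when known, the luteal length is within
        9..20 days.  All bounds inclusive.
    """
    reasons: set[EligibilityReason] = set()
    cov = cycle.coverage_fraction
    if cov < COVERAGE_MIN:
        reasons.add(EligibilityReason.COVERAGE)
    if not (LENGTH_RANGE[0] <= cycle.length <= LENGTH_RANGE[1]):
        reasons.add(EligibilityReason.LENGTH)
    if luteal_length is not None and not (
        LUTEAL_RANGE[0] <= luteal_length <= LUTEAL_RANGE[1]
    ):
        reasons.add(EligibilityReason.LUTEAL)
    return EligibilityDecision(
        eligible=not reasons,
        reasons=frozenset(reasons),
        coverage_fraction=cov,
        luteal_length=luteal_length,
    )


def _parse_lh(cell: object) -> LHResult:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return LHResult.NOT_TESTED
    s = str(cell).strip().lower()
    if s in ("", "nan"):
        return LHResult.NOT_TESTED
    if s in ("pos", "positive", "+"):
        return LHResult.POSITIVE
    if s in ("neg", "negative", "-"):
        return LHResult.NEGATIVE
    raise CycleFormatError(f"unrecognised lh_result value {cell!r}")


def read_cycles(source: str | IO[str]) -> list[Cycle]:
    """Read cycles from a long-format CSV.

    Expected header: ``cycle_id, woman_id, day, temperature_c, lh_result``
    with an empty temperature cell for missing days and lh_result in
    {pos, neg, ""}.  Days per cycle must be exactly 1..length.
    """
    df = pd.read_csv(
        source,
        dtype={"cycle_id": str, "woman_id": str},
        keep_default_na=True,
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CycleFormatError(f"missing required columns: {missing}")

    cycles: list[Cycle] = []
    # sort=False keeps first-appearance order so writes round-trip.
    for cid, grp in df.groupby("cycle_id", sort=False):
        if grp["day"].duplicated().any():
            dup = int(grp.loc[grp["day"].duplicated(), "day"].iloc[0])
            raise CycleFormatError(f"cycle {cid!r}: duplicate day {dup}")
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise CycleFormatError(
                f"cycle {cid!r}: day range is not contiguous 1..length"
            )
        woman_ids = grp["woman_id"].unique()
        if len(woman_ids) != 1:
            raise CycleFormatError(f"cycle {cid!r}: multiple woman_id values")
        records = tuple(
            DailyRecord(
                day=int(row.day),
                temperature=None if pd.isna(row.temperature_c) else float(row.temperature_c),
                lh_result=_parse_lh(row.lh_result),
            )
            for row in grp.itertuples()
        )
        cycles.append(Cycle(cycle_id=str(cid), woman_id=str(woman_ids[0]), records=records))
    return cycles


def cycles_to_frame(cycles: Iterable[Cycle]) -> pd.DataFrame:
    """Long-format DataFrame view of a cycle collection (CSV schema)."""
    rows = []
    for c in cycles:
        for r in c.records:
            rows.append(
                {
                    "cycle_id": c.cycle_id,
                    "woman_id": c.woman_id,
                    "day": r.day,
                    "temperature_c": (
                        "" if r.temperature is None
                        else f"{r.temperature:.{CSV_TEMP_DECIMALS}f}"
                    ),
                    "lh_result": r.lh_result.value,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cycles(cycles: Iterable[Cycle], dest: str | IO[str]) -> None:
    """Write cycles to CSV at two-decimal temperature precision (round-trip exact)."""
    cycles_to_frame(cycles).to_csv(dest, index=False)
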