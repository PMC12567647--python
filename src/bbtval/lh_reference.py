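"""LH-surge calling and the reference ovulation-day estimate.

The urine LH test is the reference standard: one positive test per cycle
is considered valid, except that a pair of positives on consecutive days
is resolved to the second day.  The reference estimated day of ovulation
(LH-EDO) is the day after the surge.  Any other positive pattern is
ambiguous and the cycle is excluded from validation rather than guessed
at.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cycle_model import Cycle
from .window_validation import FertileWindow, WindowKind, WindowMode, clip_interval

__all__ = ["SurgeStatus", "LHSurgeCall", "find_lh_surge", "reference_fertile_window"]


class SurgeStatus(enum.Enum):
    VALID = "VALID"
    NO_POSITIVE = "NO_POSITIVE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class LHSurgeCall:
    """The called surge day (if any) and the derived reference ovulation day."""

    status: SurgeStatus
    positive_days: tuple[int, ...]
    surge_day: int | None = None

    def __post_init__(self) -> None:
        if (self.status is SurgeStatus.VALID) != (self.surge_day is not None):
            raise ValueError("surge_day present iff status is VALID")

    @property
    def lh_edo(self) -> int | None:
        """Reference estimated day of ovulation: the day after the surge."""
        return None if self.surge_day is None else self.surge_day + 1


def find_lh_surge(cycle: Cycle) -> LHSurgeCall:
    """Call the LH surge from the daily test series.

    Zero positives: NO_POSITIVE.  A single positive on day d: surge on d.
    Exactly two positives on consecutive days (d, d+1): surge on d+1 (the
    second of the pair).  Every other pattern — two non-adjacent
    positives, three or more positives — is AMBIGUOUS.  Negative and
    not-tested days are interchangeable here: only positives matter.
    """
    pos = tuple(cycle.positive_days())
    if len(pos) == 0:
        return LHSurgeCall(SurgeStatus.NO_POSITIVE, pos)
    if len(pos) == 1:
        return LHSurgeCall(SurgeStatus.VALID, pos, surge_day=pos[0])
    if len(pos) == 2 and pos[1] == pos[0] + 1:
        return LHSurgeCall(SurgeStatus.VALID, pos, surge_day=pos[1])
    return LHSurgeCall(SurgeStatus.AMBIGUOUS, pos)


def reference_fertile_window(
    call: LHSurgeCall, mode: WindowMode, cycle_length: int
) -> FertileWindow:
    """Reference fertile window anchored on the called surge.

    SURGE10: surge−6 .. surge+3 (10 days).  WILCOX6: the reference
    ovulation day and the five preceding days, i.e. lh_edo−5 .. lh_edo
    (6 days).  Clipped to [1, cycle_length].
    """
    if call.status is not SurgeStatus.VALID:
        raise ValueError(f"reference window requires a VALID surge call, got {call.status}")
    surge = call.surge_day
    assert surge is not None
    if mode is WindowMode.SURGE10:
        lo, hi = surge - 6, surge + 3
    elif mode is WindowMode.WILCOX6:
        lo, hi = call.lh_edo - 5, call.lh_edo
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(mode)
    lo, hi = clip_interval(lo, hi, cycle_length)
    return FertileWindow(lo, hi, WindowKind.REFERENCE, mode)
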