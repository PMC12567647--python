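"""Luteal-phase temperature-profile classification.

After ovulation the BBT settles on a plateau whose height, rise speed
and stability vary between cycles: low (~0.1–0.2 degC), moderate
(~0.3 degC) or high (~0.5 degC) amplitude; a rapid step or a slow,
delayed climb; an occasional premature decline days before menstruation;
and a plateau that is either steady or visibly fluctuating.  This module
quantifies those qualitative classes with explicit, configurable
thresholds (the class boundaries are conventions of this package, chosen
to bisect the anchor amplitudes above).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .cycle_model import Cycle
from .edo_detection import impute_missing

__all__ = [
    "AmplitudeClass",
    "RiseClass",
    "FluctuationClass",
    "LutealConfig",
    "LutealProfile",
    "luteal_profile",
]


class AmplitudeClass(enum.Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


class RiseClass(enum.Enum):
    RAPID = "RAPID"
    SLOW_DELAYED = "SLOW_DELAYED"


class FluctuationClass(enum.Enum):
    REGULAR = "REGULAR"
    FLUCTUATING = "FLUCTUATING"


@dataclass(frozen=True)
class LutealConfig:
    """Thresholds for the luteal profile classes (degC and days)."""

    #: amplitude < low_cut -> LOW; <= high_cut -> MODERATE; above -> HIGH
    amplitude_low_cut: float = 0.25
    amplitude_high_cut: float = 0.40
    #: RAPID if half-amplitude is reached within this many days after the anchor
    rapid_rise_days: int = 2
    #: s.d. of detrended luteal residuals above this -> FLUCTUATING
    fluctuation_cut: float = 0.10
    #: number of terminal cycle days checked for a premature decline
    terminal_days: int = 3
    #: premature decline is only meaningful when there was a rise to decline from
    min_amplitude_for_decline: float = 0.15


@dataclass(frozen=True)
class LutealProfile:
    """Quantified luteal-phase profile of one cycle."""

    amplitude: float
    amplitude_class: AmplitudeClass
    rise_class: RiseClass
    premature_decline: bool
    fluctuation_index: float
    fluctuation_class: FluctuationClass


def luteal_profile(
    cycle: Cycle, anchor: int, config: LutealConfig = LutealConfig()
) -> LutealProfile:
    """Profile the luteal phase of one cycle.

    Parameters
    ----------
    cycle
        The cycle (missing temperatures are imputed).
    anchor
        Day index the phases pivot on — the LH surge day or, failing
        that, the temperature-derived ovulation day.  Must leave at
        least 7 pre-anchor days (baseline window) and 5 post-anchor days.
    config
        Class thresholds.

    Notes
    -----
    The follicular baseline is the mean over days [anchor−7, anchor−1]
    and the plateau the mean over days [anchor+3, min(anchor+9, length)];
    amplitude is their difference.  The rise is RAPID when the
    half-amplitude level (baseline + amplitude/2) is first reached within
    ``rapid_rise_days`` days after the anchor.  A premature decline means
    the final ``terminal_days`` days average below half-amplitude despite
    a material rise.  The fluctuation index is the standard deviation of
    luteal residuals about a 3-day centred moving average, so a smooth
    plateau of any shape scores 0.
    """
    if anchor < 8:
        raise ValueError(f"anchor {anchor} leaves fewer than 7 baseline days")
    if cycle.length - anchor < 5:
        raise ValueError(
            f"cycle {cycle.cycle_id!r}: only {cycle.length - anchor} luteal days after anchor"
        )
    temps = impute_missing(cycle)  # 0-based index = day − 1

    baseline = float(np.mean(temps[anchor - 8 : anchor - 1]))
    plateau_end = min(anchor + 9, cycle.length)
    plateau = float(np.mean(temps[anchor + 2 : plateau_end]))
    amplitude = plateau - baseline

    if amplitude < config.amplitude_low_cut:
        amp_class = AmplitudeClass.LOW
    elif amplitude <= config.amplitude_high_cut:
        amp_class = AmplitudeClass.MODERATE
    else:
        amp_class = AmplitudeClass.HIGH

    half_level = baseline + amplitude / 2
    post = temps[anchor:]  # days anchor+1 .. length
    reached = np.nonzero(post >= half_level)[0]
    rise_class = (
        RiseClass.RAPID
        if reached.size and reached[0] + 1 <= config.rapid_rise_days
        else RiseClass.SLOW_DELAYED
    )

    terminal_mean = float(np.mean(temps[-config.terminal_days :]))
    premature = (
        amplitude >= config.min_amplitude_for_decline and terminal_mean < half_level
    )

    luteal = temps[anchor:]
    if luteal.size >= 3:
        ma = np.convolve(luteal, np.ones(3) / 3, mode="valid")
        resid = luteal[1:-1] - ma
        fluct = float(np.std(resid, ddof=0))
    else:  # pragma: no cover - excluded by the 5-luteal-day precondition
        fluct = 0.0
    fluct_class = (
        FluctuationClass.FLUCTUATING
        if fluct > config.fluctuation_cut
        else FluctuationClass.REGULAR
    )

    return LutealProfile(
        amplitude=amplitude,
        amplitude_class=amp_class,
        rise_class=rise_class,
        premature_decline=premature,
        fluctuation_index=fluct,
        fluctuation_class=fluct_class,
    )
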