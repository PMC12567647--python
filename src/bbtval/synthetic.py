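"""Synthetic menstrual-cycle cohorts with known ground truth.

Each simulated cycle follows the canonical biphasic BBT template: a
follicular baseline, a pre-ovulatory nadir dip on the two days before
ovulation (the estrogen peak), and a post-ovulatory rise to a luteal
plateau 0.15–0.50 degC above baseline, driven by progesterone.  The LH
surge is placed the day before ovulation, so the LH-derived ovulation
day (surge + 1) coincides with true ovulation; with some probability the
test is also positive on the preceding day, giving the consecutive-pair
pattern whose second member is the surge.  On top of the template sit
i.i.d. Gaussian measurement noise (optionally AR(1)), missing days, and
rare discordance modes in which the temperature rise lags behind or
precedes the surge — the two failure patterns seen in real cycles.

Every quantity the pipeline later estimates (ovulation day, surge day,
rise day, amplitude, shape class) is recorded per cycle in a truth
table, and the whole cohort is a deterministic function of the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .cycle_model import Cycle, DailyRecord, LHResult

__all__ = [
    "ShapeClass",
    "DiscordanceMode",
    "SimulationConfig",
    "SimTruth",
    "noiseless_template",
    "simulate_cycle",
    "simulate_cohort",
    "truth_to_frame",
]

#: Length of the linear ramp (days) for the slow/delayed rise shape.
SLOW_RISE_DAYS = 7
#: Days over which a premature-decline plateau falls back to baseline.
DECLINE_DAYS = 3
#: Days of follicular phase required before ovulation (keeps the surge,
#: the detector search floor and the baseline window feasible).
MIN_FOLLICULAR_DAYS = 9


class ShapeClass(enum.Enum):
    RAPID = "RAPID"
    SLOW_DELAYED = "SLOW_DELAYED"
    PREMATURE_DECLINE = "PREMATURE_DECLINE"


class DiscordanceMode(enum.Enum):
    NONE = "NONE"
    DELAYED = "DELAYED"  # temperature rise lags days behind the surge
    EARLY = "EARLY"  # temperature rise precedes the surge


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative settings (temperatures in degC)."""

    n_cycles: int = 200
    seed: int = 0
    length_range: tuple[int, int] = (24, 35)
    luteal_range: tuple[int, int] = (9, 20)
    baseline_mean: float = 36.40
    baseline_sd: float = 0.10  # between-cycle baseline spread
    amplitude_choices: tuple[tuple[float, float], ...] = (
        (0.15, 1 / 3),
        (0.30, 1 / 3),
        (0.50, 1 / 3),
    )
    noise_sd: float = 0.05
    ar_coeff: float = 0.0  # AR(1) noise memory; 0 = independent days
    nadir_depth: float = 0.10
    missing_prob: float = 0.05
    double_positive_prob: float = 0.10
    p_delayed_rise: float = 0.03
    p_early_rise: float = 0.03
    delayed_rise_lag: int = 3
    shape_mix: tuple[tuple[ShapeClass, float], ...] = (
        (ShapeClass.RAPID, 0.70),
        (ShapeClass.SLOW_DELAYED, 0.15),
        (ShapeClass.PREMATURE_DECLINE, 0.15),
    )

    def __post_init__(self) -> None:
        for name in ("missing_prob", "double_positive_prob", "p_delayed_rise", "p_early_rise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_delayed_rise + self.p_early_rise > 1.0:
            raise ValueError("discordance probabilities sum above 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for rng_name in ("length_range", "luteal_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} is empty")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded for one simulated cycle."""

    cycle_id: str
    woman_id: str
    length: int
    true_ovulation_day: int
    true_surge_day: int
    true_rise_day: int
    amplitude: float
    baseline: float
    shape_class: ShapeClass
    discordance_mode: DiscordanceMode

    def __post_init__(self) -> None:
        assert self.true_surge_day == self.true_ovulation_day - 1


def noiseless_template(
    length: int,
    ovulation_day: int,
    rise_day: int,
    baseline: float,
    amplitude: float,
    nadir_depth: float,
    shape: ShapeClass,
) -> np.ndarray:
    """The deterministic daily BBT template (degC), one value per day 1..length.

    Baseline before the rise, a nadir dip of ``nadir_depth`` on the two
    days before ovulation, then a plateau at baseline + amplitude from
    ``rise_day`` on: an immediate step (RAPID), a linear climb over
    7 days (SLOW_DELAYED), or a step that falls back to baseline over
    the final 3 cycle days (PREMATURE_DECLINE).
    """
    days = np.arange(1, length + 1)
    temps = np.full(length, baseline, dtype=float)

    in_nadir = (days >= ovulation_day - 2) & (days <= ovulation_day - 1) & (days < rise_day)
    temps[in_nadir] = baseline - nadir_depth

    post = days >= rise_day
    if shape is ShapeClass.SLOW_DELAYED:
        frac = np.minimum(1.0, (days - rise_day + 1) / SLOW_RISE_DAYS)
        temps[post] = baseline + amplitude * frac[post]
    else:
        temps[post] = baseline + amplitude
        if shape is ShapeClass.PREMATURE_DECLINE:
            # last DECLINE_DAYS days ramp linearly down, ending at baseline
            for k in range(DECLINE_DAYS):
                d = length - k  # day index; k=0 is the final day
                if d >= rise_day:
                    temps[d - 1] = baseline + amplitude * k / DECLINE_DAYS
    return temps


def _draw_lengths(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Draw (length, luteal) with enough follicular days; redraw if infeasible."""
    lo_l, hi_l = config.length_range
    lo_p, hi_p = config.luteal_range
    while True:
        length = int(rng.integers(lo_l, hi_l + 1))
        luteal = int(rng.integers(lo_p, hi_p + 1))
        if length - luteal >= MIN_FOLLICULAR_DAYS:
            return length, luteal


def simulate_cycle(
    config: SimulationConfig,
    rng: np.random.Generator,
    cycle_id: str = "C0001",
    woman_id: str = "W0001",
) -> tuple[Cycle, SimTruth]:
    """Draw one cycle and its ground truth from the generative model."""
    length, luteal = _draw_lengths(config, rng)
    ovulation = length - luteal + 1
    surge = ovulation - 1

    baseline = float(np.clip(rng.normal(config.baseline_mean, config.baseline_sd), 35.5, 37.5))
    amps, probs = zip(*config.amplitude_choices)
    amplitude = float(rng.choice(amps, p=np.asarray(probs) / np.sum(probs)))
    shapes, sprobs = zip(*config.shape_mix)
    shape = rng.choice(np.asarray(shapes, dtype=object), p=np.asarray(sprobs) / np.sum(sprobs))

    u = rng.random()
    rise = ovulation
    mode = DiscordanceMode.NONE
    if u < config.p_delayed_rise:
        mode = DiscordanceMode.DELAYED
        rise = ovulation + config.delayed_rise_lag
    elif u < config.p_delayed_rise + config.p_early_rise:
        mode = DiscordanceMode.EARLY
        rise = ovulation - config.delayed_rise_lag
    # keep the shifted rise inside the usable part of the cycle
    rise = int(np.clip(rise, 3, length - 3))

    temps = noiseless_template(
        length, ovulation, rise, baseline, amplitude, config.nadir_depth, shape
    )
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=length)
        if config.ar_coeff:
            for i in range(1, length):
                eps[i] += config.ar_coeff * eps[i - 1]
        temps = temps + eps
    temps = np.round(temps, 2)  # device-class 0.01 degC resolution

    missing = rng.random(length) < config.missing_prob
    if missing.all():
        missing[0] = False

    lh = [LHResult.NOT_TESTED] * length
    for d in range(max(1, surge - 2), min(length, surge + 2) + 1):
        lh[d - 1] = LHResult.NEGATIVE
    lh[surge - 1] = LHResult.POSITIVE
    if surge >= 2 and rng.random() < config.double_positive_prob:
        lh[surge - 2] = LHResult.POSITIVE

    records = tuple(
        DailyRecord(
            day=d,
            temperature=None if missing[d - 1] else float(temps[d - 1]),
            lh_result=lh[d - 1],
        )
        for d in range(1, length + 1)
    )
    cycle = Cycle(cycle_id=cycle_id, woman_id=woman_id, records=records)
    truth = SimTruth(
        cycle_id=cycle_id,
        woman_id=woman_id,
        length=length,
        true_ovulation_day=ovulation,
        true_surge_day=surge,
        true_rise_day=rise,
        amplitude=amplitude,
        baseline=baseline,
        shape_class=ShapeClass(shape.value if isinstance(shape, ShapeClass) else shape),
        discordance_mode=mode,
    )
    return cycle, truth


def simulate_cohort(config: SimulationConfig) -> tuple[list[Cycle], pd.DataFrame]:
    """Generate ``config.n_cycles`` independent cycles plus their truth table.

    Fully reproducible: the same config (including seed) yields
    byte-identical CSV output.
    """
    rng = np.random.default_rng(config.seed)
    cycles: list[Cycle] = []
    truths: list[SimTruth] = []
    for i in range(config.n_cycles):
        cid = f"C{i + 1:04d}"
        wid = f"W{i + 1:04d}"
        cycle, truth = simulate_cycle(config, rng, cycle_id=cid, woman_id=wid)
        cycles.append(cycle)
        truths.append(truth)
    return cycles, truth_to_frame(truths)


def truth_to_frame(truths: Iterable[SimTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        d = asdict(t)
        d["shape_class"] = t.shape_class.value
        d["discordance_mode"] = t.discordance_mode.value
        d["amplitude_c"] = d.pop("amplitude")
        rows.append(d)
    cols = [
        "cycle_id",
        "woman_id",
        "length",
        "true_ovulation_day",
        "true_surge_day",
        "true_rise_day",
        "amplitude_c",
        "baseline",
        "shape_class",
        "discordance_mode",
    ]
    return pd.DataFrame(rows, columns=cols)
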