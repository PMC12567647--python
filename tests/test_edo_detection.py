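"""Imputation, fixed-length padding, and the step-fit ovulation detector."""

import numpy as np
import pytest

from bbtval.edo_detection import (
    DetectionStatus,
    DetectorConfig,
    PaddedSeries,
    detect_edo,
    impute_missing,
    pad_to_35,
)
from bbtval.synthetic import (
    ShapeClass,
    SimulationConfig,
    noiseless_template,
    simulate_cohort,
)

from conftest import build_cycle


def brute_force_scan(x: np.ndarray, config: DetectorConfig):
    """Independent exhaustive two-mean fit: direct residual sums per tau."""
    best = None
    for tau in range(config.search_start, len(x) - config.search_end_offset + 1):
        low, high = x[: tau - 1], x[tau - 1 :]
        rss = np.sum((low - low.mean()) ** 2) + np.sum((high - high.mean()) ** 2)
        if best is None or rss < best[1] - 1e-12:  # strict: keeps the earliest tie
            best = (tau, rss, high.mean() - low.mean())
    return best


class TestImputation:
    def test_interior_gap_is_linear(self):
        c = build_cycle([36.4, None, 36.6])
        assert impute_missing(c) == pytest.approx([36.4, 36.5, 36.6])

    def test_edges_take_nearest_value(self):
        c = build_cycle([None, 36.4, 36.4, None, None])
        assert impute_missing(c) == pytest.approx([36.4] * 5)

    def test_recorded_values_pass_through(self, rng):
        cycles, truth = simulate_cohort(SimulationConfig(n_cycles=20, seed=1, missing_prob=0.15))
        for c in cycles:
            filled = impute_missing(c)
            for r in c.records:
                if r.temperature is not None:
                    assert filled[r.day - 1] == r.temperature

    def test_imputation_error_bounded_by_noise_and_slope(self):
        """On 15% missingness the imputed values stay near the noiseless template."""
        config = SimulationConfig(
            n_cycles=50, seed=2, missing_prob=0.15, noise_sd=0.05,
            p_delayed_rise=0.0, p_early_rise=0.0,
        )
        cycles, truth = simulate_cohort(config)
        for c, t in zip(cycles, truth.itertuples()):
            template = noiseless_template(
                t.length, t.true_ovulation_day, t.true_rise_day,
                t.baseline, t.amplitude_c, config.nadir_depth, ShapeClass(t.shape_class),
            )
            err = np.abs(impute_missing(c) - np.round(template, 2))
            # worst case: a gap spanning the 0.5 degC step plus noise on both ends
            assert err.max() <= 0.5 + 6 * config.noise_sd

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            impute_missing(build_cycle([None, None, None]))


class TestPadding:
    def test_short_series_repeats_final_value(self):
        padded = pad_to_35([36.4] * 27 + [36.9])
        assert padded.original_length == 28
        assert padded.values[27:] == (36.9,) * 8

    def test_full_length_series_is_unchanged(self):
        x = list(np.linspace(36.3, 36.9, 35))
        assert pad_to_35(x).values == pytest.approx(tuple(x))

    def test_single_value_pads_to_constant(self):
        assert pad_to_35([36.5]).values == (36.5,) * 35

    def test_overlong_series_rejected(self):
        with pytest.raises(ValueError):
            pad_to_35([36.5] * 36)

    def test_inconsistent_padding_rejected(self):
        with pytest.raises(ValueError):
            PaddedSeries(values=(36.5,) * 34 + (37.0,), original_length=28)


class TestDetector:
    def test_noiseless_step_detected_exactly(self):
        x = [36.40] * 14 + [36.90] * 14
        est = detect_edo(pad_to_35(x))
        assert est.status is DetectionStatus.DETECTED
        assert est.a_edo == 15
        assert est.shift_estimate == pytest.approx(0.50)

    def test_flat_series_not_detected(self):
        est = detect_edo(pad_to_35([36.50] * 28))
        assert est.status is DetectionStatus.NOT_DETECTED
        assert est.shift_estimate == pytest.approx(0.0)

    def test_shift_below_threshold_not_detected(self):
        x = [36.40] * 14 + [36.45] * 14
        est = detect_edo(pad_to_35(x))
        assert est.status is DetectionStatus.NOT_DETECTED
        assert est.rise_day == 15  # diagnostics still report the best fit

    def test_too_short_series_reports_diagnostic(self):
        est = detect_edo(pad_to_35([36.5] * 8))
        assert est.status is DetectionStatus.NOT_DETECTED
        assert "search range" in est.note

    def test_location_invariance(self, rng):
        x = 36.4 + 0.4 * (np.arange(30) >= 17) + rng.normal(0, 0.05, 30)
        a = detect_edo(pad_to_35(x))
        b = detect_edo(pad_to_35(x + 1.7))
        assert a.a_edo == b.a_edo
        assert a.shift_estimate == pytest.approx(b.shift_estimate)

    @pytest.mark.parametrize("amplitude", [0.10, 0.15, 0.30, 0.50])
    def test_zero_noise_recovers_rise_day_exactly(self, amplitude):
        """Any step at or above min_shift is recovered exactly without noise."""
        for rise in (10, 16, 22):
            x = noiseless_template(28, rise, rise, 36.4, amplitude, 0.10, ShapeClass.RAPID)
            est = detect_edo(pad_to_35(x))
            assert est.status is DetectionStatus.DETECTED
            assert est.a_edo == rise
            assert est.shift_estimate >= amplitude - 0.05  # nadir pulls the low mean down

    def test_padding_carries_no_weight(self, rng):
        """The fit over the observed days alone decides the estimate."""
        x = 36.4 + 0.3 * (np.arange(28) >= 16) + rng.normal(0, 0.05, 28)
        est = detect_edo(pad_to_35(x))
        tau, _, shift = brute_force_scan(x, DetectorConfig())
        assert est.rise_day == tau
        assert est.shift_estimate == pytest.approx(shift)

    def test_matches_brute_force_scan_on_random_cycles(self):
        cycles, _ = simulate_cohort(SimulationConfig(n_cycles=100, seed=13, missing_prob=0.0))
        config = DetectorConfig()
        for c in cycles:
            x = c.temperatures
            est = detect_edo(pad_to_35(x), config)
            tau, _, shift = brute_force_scan(x, config)
            assert est.rise_day == tau
            assert est.shift_estimate == pytest.approx(shift)

    def test_monte_carlo_recovery_step_template(self):
        """Step cycles at 0.30 degC amplitude, noise 0.05: rise day within +-1."""
        config = SimulationConfig(
            n_cycles=200, seed=17, amplitude_choices=((0.30, 1.0),),
            shape_mix=((ShapeClass.RAPID, 1.0),),
            p_delayed_rise=0.0, p_early_rise=0.0, missing_prob=0.0,
        )
        cycles, truth = simulate_cohort(config)
        hits = 0
        shifts = []
        for c, t in zip(cycles, truth.itertuples()):
            est = detect_edo(pad_to_35(c.temperatures))
            assert est.status is DetectionStatus.DETECTED
            hits += abs(est.a_edo - t.true_rise_day) <= 1
            shifts.append(est.shift_estimate)
        assert hits / len(cycles) >= 0.95
        # the fitted step tracks the simulated amplitude (nadir biases it up slightly)
        assert np.mean(shifts) == pytest.approx(0.30, abs=0.05)
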