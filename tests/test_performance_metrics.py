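"""Metric arithmetic, zone segmentation vs brute force, table assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from exostrength import (
    RepetitionSeries,
    SignalTrace,
    SimulationConfig,
    constant_speed_zone,
    detect_rep_peaks,
    generate_session,
    get_protocol,
    iemg_delta,
    initial_speed,
    metric_columns,
    number_of_repetitions,
    semg_amplitude_delta,
)
from exostrength.performance_metrics import SessionInputs, build_metric_table

FS = 2000.0


def series_from_intervals(intervals):
    return RepetitionSeries(np.concatenate([[0.0], np.cumsum(intervals)]))


def brute_force_zone_reps(intervals, target, rel_tol, persistence):
    """Exhaustive scan: first window of `persistence` consecutive
    deviating intervals ends the zone."""
    n_reps = len(intervals) + 1
    dev = [abs(i - target) > rel_tol * target for i in intervals]
    for start in range(len(dev) - persistence + 1):
        if all(dev[start : start + persistence]):
            return start + 1
    return n_reps


class TestCounts:
    def test_count_equals_peaks(self):
        assert number_of_repetitions(series_from_intervals([1.0] * 89)) == 90

    def test_empty_series_counts_zero(self):
        assert number_of_repetitions(RepetitionSeries(np.empty(0))) == 0

    def test_max_effort_session_count_matches_planted(self, sim_config, cohort):
        proto = get_protocol("squat", "max")
        bundle = generate_session(cohort[2], proto, config=sim_config)
        series = detect_rep_peaks(bundle.torque, proto)
        assert number_of_repetitions(series) == len(bundle.rep_times)


class TestInitialSpeed:
    def test_metronome_pace_in_per10s_units(self):
        s = series_from_intervals([1.0] * 20)
        assert initial_speed(s, 10) == pytest.approx(10.0)

    def test_mean_of_alternating_intervals(self):
        s = series_from_intervals([1.0, 1.25] * 10)
        assert initial_speed(s, 10) == pytest.approx(np.mean([10.0, 8.0]))

    def test_undefined_below_two_peaks(self):
        assert math.isnan(initial_speed(RepetitionSeries(np.array([1.0])), 10))

    def test_paced_kneeup_session_near_132_rpm(self, sim_config, cohort):
        proto = get_protocol("kneeup", "const")
        bundle = generate_session(cohort[0], proto, config=sim_config)
        series = detect_rep_peaks(bundle.torque, proto)
        # 132 RPM = 22 reps per 10 s
        assert initial_speed(series, 30) == pytest.approx(22.0, rel=0.05)

    def test_antitone_in_interval_length(self):
        slow = series_from_intervals([1.4] * 12)
        fast = series_from_intervals([1.1] * 12)
        assert initial_speed(fast, 10) > initial_speed(slow, 10)


class TestConstantSpeedZone:
    def test_all_on_target_keeps_whole_series(self):
        s = series_from_intervals([1.0] * 30)
        zone = constant_speed_zone(s, target_rpm=60.0)
        assert zone.constant_zone_reps == 31

    def test_immediately_deviating_keeps_first_peak_only(self):
        s = series_from_intervals([1.3, 1.3, 1.3, 1.0, 1.0])
        zone = constant_speed_zone(s, 60.0, rel_tol=0.10, persistence=3)
        assert zone.constant_zone_reps == 1

    def test_flags_length_matches_intervals(self):
        s = series_from_intervals([1.0, 1.2, 1.0])
        zone = constant_speed_zone(s, 60.0)
        assert zone.deviation_flags.size == 3

    def test_invalid_tolerance_rejected(self):
        s = series_from_intervals([1.0] * 3)
        with pytest.raises(ValueError):
            constant_speed_zone(s, 60.0, rel_tol=1.5)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        intervals=hst.lists(
            hst.floats(min_value=0.5, max_value=2.0), min_size=1, max_size=40
        ),
        persistence=hst.integers(min_value=1, max_value=4),
    )
    def test_matches_brute_force_oracle(self, intervals, persistence):
        s = series_from_intervals(intervals)
        zone = constant_speed_zone(s, 60.0, rel_tol=0.10, persistence=persistence)
        # the oracle sees the same float-round-tripped intervals the
        # implementation derives from the peak times
        expected = brute_force_zone_reps(np.diff(s.peak_times), 1.0, 0.10, persistence)
        assert zone.constant_zone_reps == expected

    def test_zone_never_exceeds_rep_count(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            intervals = rng.uniform(0.8, 1.4, rng.integers(2, 40))
            s = series_from_intervals(intervals)
            zone = constant_speed_zone(s, 60.0)
            assert zone.constant_zone_reps <= len(s)


class TestSemgDeltas:
    def test_stationary_signal_near_zero_amp_delta(self):
        rng = np.random.default_rng(5)
        tr = SignalTrace(rng.standard_normal(60000), FS, kind="semg_mvic")
        assert semg_amplitude_delta(tr) == pytest.approx(0.0, abs=0.02)

    def test_doubled_amplitude_gives_unit_delta(self):
        # unit initial RMS, final RMS 2 -> delta +1
        n = 60000
        x = np.ones(n)
        x[-20000:] = 2.0
        tr = SignalTrace(x, FS, kind="semg_mvic")
        assert semg_amplitude_delta(tr) == pytest.approx(1.0)

    def test_too_short_trace_undefined(self):
        tr = SignalTrace(np.ones(1000), FS, kind="semg_mvic")
        assert math.isnan(semg_amplitude_delta(tr))

    def test_amp_delta_sign_matches_configured_drift(self, sim_config, squat_const_session, cohort):
        from exostrength.performance_metrics import build_mvic_reference, mvic_envelopes
        from exostrength.synthetic_data import generate_rest_recording

        rest = generate_rest_recording(cohort[0], sim_config)
        ref = build_mvic_reference([squat_const_session.semg], rest)
        envs = mvic_envelopes(squat_const_session.semg, ref)
        deltas = [semg_amplitude_delta(e) for e in envs.values()]
        assert np.sign(np.mean(deltas)) == np.sign(sim_config.fatigue.emg_amp_drift)

    def test_constant_level_zero_iemg_delta(self):
        tr = SignalTrace(np.full(60000, 0.3), FS, kind="semg_mvic")
        assert iemg_delta(tr) == pytest.approx(0.0, abs=1e-12)

    def test_step_level_iemg_delta(self):
        c = 0.4
        x = np.full(60000, c)
        x[-20000:] = 2 * c
        tr = SignalTrace(x, FS, kind="semg_mvic")
        assert iemg_delta(tr) == pytest.approx(10 * c, rel=1e-3)

    def test_iemg_matches_dense_riemann_oracle(self):
        # smooth random signal sampled 10x finer as the reference integral
        rng = np.random.default_rng(6)
        fine_fs = 10 * FS
        t_fine = np.arange(int(25 * fine_fs)) / fine_fs
        coeffs = rng.standard_normal(6)
        freqs = rng.uniform(0.05, 0.5, 6)
        y_fine = 1.5 + sum(c * np.sin(2 * np.pi * f * t_fine) for c, f in zip(coeffs, freqs))
        y = y_fine[::10]
        nw = int(10 * fine_fs)
        oracle = (
            np.trapezoid(np.abs(y_fine[-nw:]), dx=1 / fine_fs)
            - np.trapezoid(np.abs(y_fine[:nw]), dx=1 / fine_fs)
        )
        tr = SignalTrace(y, FS, kind="semg_mvic")
        assert iemg_delta(tr) == pytest.approx(oracle, abs=1e-3 * max(1.0, abs(oracle)))


class TestMetricTable:
    def test_has_27_columns(self):
        assert len(metric_columns()) == 27

    def _inputs(self, times):
        return SessionInputs(torque_series=RepetitionSeries(times), envelopes={})

    def test_single_perfect_participant(self):
        sessions = {"P1": {"squat:const": self._inputs(np.arange(0.5, 90.0, 1.0))}}
        table = build_metric_table(sessions)
        assert table.loc["P1", "Squat_NR_Const"] == 90
        assert table.loc["P1", "Squat_CZ"] == 90
        assert math.isnan(table.loc["P1", "Lunge_NR_Const"])

    def test_missing_session_leaves_cells_missing(self):
        sessions = {
            "P1": {
                "squat:max": self._inputs(np.arange(0.6, 45.0, 1.2)),
                # lunge const absent
            }
        }
        table = build_metric_table(sessions)
        assert not math.isnan(table.loc["P1", "Squat_NR_Max"])
        assert math.isnan(table.loc["P1", "Lunge_NR_Const"])

    def test_permutation_equivariant(self, fast_metric_cohort):
        sessions = {
            pid: {"squat:max": self._inputs(t)} for pid, t in fast_metric_cohort.items()
        }
        rev = dict(reversed(list(sessions.items())))
        a = build_metric_table(sessions)
        b = build_metric_table(rev)
        assert a.sort_index().equals(b.sort_index())

    def test_nr_and_is_positively_correlated_across_cohort(self, fast_metric_cohort):
        # both are monotone images of the planted self-selected pace
        sessions = {
            pid: {"squat:max": self._inputs(t)} for pid, t in fast_metric_cohort.items()
        }
        table = build_metric_table(sessions)
        r = table["Squat_NR_Max"].corr(table["Squat_IS_Max"])
        assert r > 0.5

    def test_cz_bounded_by_nr_const(self, sim_config, squat_const_session):
        proto = get_protocol("squat", "const")
        series = detect_rep_peaks(squat_const_session.torque, proto)
        sessions = {"P1": {"squat:const": SessionInputs(series, {})}}
        table = build_metric_table(sessions)
        assert table.loc["P1", "Squat_CZ"] <= table.loc["P1", "Squat_NR_Const"]
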