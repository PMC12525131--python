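"""Bateman kinetics, protocol construction and evaluation, PK fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pilotle as p
from pilotle.exceptions import (
    InputError,
    InsufficientDataError,
    InvalidParameterError,
)

from conftest import bateman_grid_oracle


class TestUnitBateman:
    def test_zero_at_and_before_onset(self, default_params):
        assert p.unit_bateman(0.0, default_params) == 0.0
        assert p.unit_bateman(-5.0, default_params) == 0.0

    def test_unit_peak(self, default_params):
        tstar = p.peak_time(default_params)
        assert p.unit_bateman(tstar, default_params) == pytest.approx(1.0, abs=1e-12)

    def test_value_at_45_min_matches_grid_oracle(self, default_params):
        t, unit, _ = bateman_grid_oracle(6.9, 100.0)
        expected = unit[np.searchsorted(t, 45.0)]
        assert expected == pytest.approx(0.833, abs=5e-4)  # frozen from the oracle
        assert p.unit_bateman(45.0, default_params) == pytest.approx(expected, abs=1e-5)

    def test_nonnegative_unimodal_max_one(self, default_params):
        grid = np.linspace(-10, 600, 4000)
        u = p.unit_bateman(grid, default_params)
        assert np.all(u >= 0)
        assert u.max() <= 1.0 + 1e-12
        i = int(np.argmax(u))
        assert np.all(np.diff(u[:i]) >= -1e-12)
        assert np.all(np.diff(u[i:]) <= 1e-12)


class TestPeakTime:
    def test_closed_form_small_case(self):
        params = p.PKParams(tau_abs=1.0, tau_decay=2.0)
        assert p.peak_time(params) == pytest.approx(2 * math.log(2), rel=1e-12)

    @pytest.mark.parametrize("ta,td", [(6.9, 100.0), (1.0, 2.0), (3.0, 50.0)])
    def test_matches_grid_maximization(self, ta, td):
        _, _, t_grid_peak = bateman_grid_oracle(ta, td)
        assert p.peak_time(p.PKParams(tau_abs=ta, tau_decay=td)) == pytest.approx(
            t_grid_peak, abs=0.01
        )

    def test_default_peak_near_20_min(self, default_params):
        assert p.peak_time(default_params) == pytest.approx(19.8, abs=0.1)

    def test_degenerate_taus_rejected(self):
        with pytest.raises(InvalidParameterError):
            p.PKParams(tau_abs=5.0, tau_decay=5.0)


class TestConcentration:
    def test_superposition_two_equal_doses(self, default_params):
        t = np.linspace(0, 300, 601)
        one = p.concentration(p.DoseSchedule([p.DoseEvent(0.0, 332.0)]), t, default_params)
        two = p.concentration(
            p.DoseSchedule([p.DoseEvent(0.0, 166.0), p.DoseEvent(0.0, 166.0)]),
            t, default_params,
        )
        np.testing.assert_allclose(two, one, rtol=0, atol=1e-12)

    def test_single_dose_peak_is_alpha_times_dose(self, default_params,
                                                  single_dose_schedule):
        tstar = p.peak_time(default_params)
        assert p.concentration(single_dose_schedule, tstar, default_params) == (
            pytest.approx(166.0, rel=1e-12)
        )

    def test_superposed_peak_matches_dense_grid_oracle(self, default_params):
        # independent oracle: raw two-exponential formula on a 0.01-min grid
        ta, td = 6.9, 100.0
        tstar = ta * td / (td - ta) * math.log(td / ta)
        norm = math.exp(-tstar / td) - math.exp(-tstar / ta)

        def u(t):
            t = np.asarray(t, float)
            return np.where(t > 0, (np.exp(-t / td) - np.exp(-t / ta)) / norm, 0.0)

        t = np.arange(0, 240, 0.01)
        oracle = 166 * u(t) + 83 * u(t - 45)
        i = int(np.argmax(oracle))
        sched = p.DoseSchedule([p.DoseEvent(0.0, 166.0), p.DoseEvent(45.0, 83.0)])
        got = p.concentration(sched, t, default_params)
        np.testing.assert_allclose(got, oracle, rtol=0, atol=1e-9)
        ev = p.evaluate_protocol(sched, p.TargetWindow(170, 230), default_params)
        assert ev.peak_concentration == pytest.approx(oracle[i], abs=0.01)
        assert ev.peak_time == pytest.approx(t[i], abs=0.1)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        doses=st.lists(
            st.tuples(
                st.floats(0.0, 120.0),
                st.floats(1.0, 400.0),
            ),
            min_size=1,
            max_size=5,
        ),
    )
    def test_superposition_property_random_schedules(self, doses):
        params = p.PKParams()
        t = np.linspace(0, 240, 97)
        events = [p.DoseEvent(time=tt, dose=d) for tt, d in doses]
        total = p.concentration(p.DoseSchedule(events), t, params)
        parts = sum(
            p.concentration(p.DoseSchedule([e]), t, params) for e in events
        )
        np.testing.assert_allclose(total, parts, rtol=0, atol=1e-10)

    def test_dose_monotonicity(self, default_params):
        t = np.linspace(0, 240, 481)
        lo = p.concentration(
            p.DoseSchedule([p.DoseEvent(0.0, 166.0), p.DoseEvent(45.0, 83.0)]),
            t, default_params)
        hi = p.concentration(
            p.DoseSchedule([p.DoseEvent(0.0, 200.0), p.DoseEvent(45.0, 83.0)]),
            t, default_params)
        assert np.all(hi >= lo - 1e-12)

    def test_non_pilocarpine_agents_do_not_contribute(self, default_params):
        sched = p.DoseSchedule([
            p.DoseEvent(-20.0, 1.75, p.Agent.SCOPOLAMINE),
            p.DoseEvent(0.0, 166.0),
            p.DoseEvent(120.0, 10.0, p.Agent.DIAZEPAM),
        ])
        only_pilo = p.DoseSchedule([p.DoseEvent(0.0, 166.0)])
        t = np.linspace(0, 240, 100)
        np.testing.assert_array_equal(
            p.concentration(sched, t, default_params),
            p.concentration(only_pilo, t, default_params),
        )


class TestConcentrationSeries:
    def test_no_pilocarpine_gives_zeros(self, default_params):
        sched = p.DoseSchedule([p.DoseEvent(0.0, 1.75, p.Agent.SCOPOLAMINE)])
        s = p.concentration_series(sched, np.linspace(0, 100, 11), default_params)
        np.testing.assert_array_equal(s.values, 0.0)

    def test_single_point_at_peak(self, default_params, single_dose_schedule):
        tstar = p.peak_time(default_params)
        s = p.concentration_series(single_dose_schedule, [tstar], default_params)
        assert s.values[0] == pytest.approx(166.0, rel=1e-12)

    def test_series_max_consistent_with_evaluate_protocol(self, default_params):
        sched = p.make_protocol(166.0, 1, 45.0)
        grid = np.arange(0.0, 240.0, 0.1)
        s = p.concentration_series(sched, grid, default_params)
        ev = p.evaluate_protocol(sched, p.TargetWindow(170, 230), default_params, 240.0)
        assert s.values.max() == pytest.approx(ev.peak_concentration, abs=0.05)

    def test_unsorted_grid_rejected(self, default_params, single_dose_schedule):
        with pytest.raises(InputError):
            p.concentration_series(single_dose_schedule, [3.0, 1.0, 2.0],
                                   default_params)


class TestMakeProtocol:
    def test_standard_induction_scheme(self):
        sched = p.make_protocol(166.0, 1, 45.0, 20.0)
        assert [(e.time, e.dose, e.agent) for e in sched.events] == [
            (-20.0, 1.75, p.Agent.SCOPOLAMINE),
            (0.0, 166.0, p.Agent.PILOCARPINE),
            (45.0, 83.0, p.Agent.PILOCARPINE),
        ]

    def test_no_boosters(self):
        sched = p.make_protocol(166.0, 0, 45.0, 20.0)
        assert len(sched.pilocarpine_events) == 1

    def test_high_dose_scheme(self):
        sched = p.make_protocol(300.0, 1, 30.0, 20.0)
        pilo = sched.pilocarpine_events
        assert (pilo[0].time, pilo[0].dose) == (0.0, 300.0)
        assert (pilo[1].time, pilo[1].dose) == (30.0, 150.0)

    @pytest.mark.parametrize("kwargs", [
        {"initial_dose": -1.0},
        {"n_boosters": -1},
        {"booster_interval": 0.0},
    ])
    def test_invalid_arguments(self, kwargs):
        base = dict(initial_dose=166.0, n_boosters=1, booster_interval=45.0)
        base.update(kwargs)
        with pytest.raises(InputError):
            p.make_protocol(**base)


class TestEvaluateProtocol:
    def test_single_dose_below_window(self, default_params, single_dose_schedule):
        ev = p.evaluate_protocol(single_dose_schedule, p.TargetWindow(170, 230),
                                 default_params)
        assert ev.minutes_in_window == 0.0
        assert ev.window_entry_time is None
        assert ev.peak_concentration < 170.0
        assert ev.peak_concentration == pytest.approx(166.0, abs=0.01)

    def test_boosted_protocol_enters_window_without_overshoot(self, default_params):
        sched = p.make_protocol(166.0, 1, 45.0)
        ev = p.evaluate_protocol(sched, p.TargetWindow(170, 230), default_params)
        assert ev.window_entry_time is not None
        assert ev.minutes_in_window > 0
        assert not ev.exceeded_high

    def test_tiny_low_bound_entered_at_first_dose(self, default_params,
                                                  single_dose_schedule):
        ev = p.evaluate_protocol(single_dose_schedule,
                                 p.TargetWindow(1e-4, 230.0), default_params)
        assert ev.window_entry_time == pytest.approx(0.0, abs=0.2)

    def test_invalid_window(self):
        with pytest.raises(InputError):
            p.TargetWindow(230.0, 170.0)

    def test_horizon_before_last_dose(self, default_params):
        sched = p.make_protocol(166.0, 1, 45.0)
        with pytest.raises(InputError):
            p.evaluate_protocol(sched, p.TargetWindow(170, 230), default_params,
                                horizon=30.0)


def _percentile_oracle(values, q):
    """Sort-based linear-interpolation percentile, independent of numpy."""
    v = sorted(values)
    h = (len(v) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestConcentrationAtEvents:
    def test_identical_times_zero_width_band(self, default_params,
                                             single_dose_schedule):
        res = p.concentration_at_events(single_dose_schedule, [30.0] * 5,
                                        default_params)
        assert res.q25 == res.q75

    def test_values_match_concentration_definition(self, default_params,
                                                   single_dose_schedule):
        res = p.concentration_at_events(single_dose_schedule, [10.0, 33.0],
                                        default_params)
        expected = [p.concentration(single_dose_schedule, t, default_params)
                    for t in (10.0, 33.0)]
        np.testing.assert_allclose(res.values, expected, rtol=1e-12)

    def test_percentiles_match_sort_oracle(self, default_params):
        rng = np.random.default_rng(2)
        times = rng.uniform(15.0, 75.0, 25)
        sched = p.make_protocol(166.0, 1, 45.0)
        res = p.concentration_at_events(sched, times, default_params)
        assert res.q25 == pytest.approx(_percentile_oracle(res.values, 25), rel=1e-12)
        assert res.q75 == pytest.approx(_percentile_oracle(res.values, 75), rel=1e-12)

    def test_empty_events_rejected(self, default_params, single_dose_schedule):
        with pytest.raises(InputError):
            p.concentration_at_events(single_dose_schedule, [], default_params)


class TestFitPK:
    def test_noise_free_recovery_within_one_percent(self):
        truth = p.PKParams(6.9, 100.0, 1.0)
        sched = p.DoseSchedule([p.DoseEvent(0.0, 300.0)])
        samples, _ = p.gen_pk_samples(truth, sched, cv=0.0, n=24, horizon=180.0,
                                      seed=0)
        res = p.fit_pk(samples, sched)
        assert res.params.tau_abs == pytest.approx(6.9, rel=0.01)
        assert res.params.tau_decay == pytest.approx(100.0, rel=0.01)
        assert res.params.alpha == pytest.approx(1.0, rel=0.01)
        assert res.r2 > 0.9999
        assert res.params.tau_abs < res.params.tau_decay

    def test_summary_mentions_estimates(self):
        truth = p.PKParams(6.9, 100.0, 1.0)
        sched = p.DoseSchedule([p.DoseEvent(0.0, 300.0)])
        samples, _ = p.gen_pk_samples(truth, sched, cv=0.0, n=24, seed=0)
        text = p.fit_pk(samples, sched).summary()
        assert "tau_abs" in text and "R^2" in text

    def test_too_few_samples(self, default_params, single_dose_schedule):
        s = p.ConcentrationSeries(times=np.array([1.0, 2.0, 3.0]),
                                  values=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InsufficientDataError):
            p.fit_pk(s, single_dose_schedule)
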