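"""Residence events, survival curves and double-exponential fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anionflux.compartments import INTERFACE, TETRAHEDRAL, LabelSeries
from anionflux.kinetics import (
    DegenerateFitError,
    DoubleExpFit,
    InsufficientStatisticsError,
    ResidenceEvent,
    find_events,
    fit_double_exp,
    mean_residence_time,
    survival_curve,
)


def _series(chars, dt=1.0):
    return LabelSeries.from_chars(np.array([list(c) for c in chars]), frame_dt=dt)


class TestFindEvents:
    def test_run_length_enumeration(self):
        # T T I I T -> (start 0, dur 2), (start 4, dur 1, censored)
        events = find_events(_series(["TTIIT"]), TETRAHEDRAL)
        assert [(e.start_frame, e.duration, e.censored) for e in events] == [
            (0, 2.0, False),
            (4, 1.0, True),
        ]

    def test_absent_label_gives_empty_list(self):
        assert find_events(_series(["IIIII"]), TETRAHEDRAL) == []

    def test_full_sequence_is_one_censored_event(self):
        events = find_events(_series(["TTTTT"]), TETRAHEDRAL)
        assert len(events) == 1
        assert events[0].duration == 5.0 and events[0].censored

    def test_duration_scales_with_frame_spacing(self):
        events = find_events(_series(["TTII"], dt=0.25), TETRAHEDRAL)
        assert events[0].duration == 0.5

    def test_gap_tolerance_bridges_single_frame_excursions(self):
        strict = find_events(_series(["TTITT"]), TETRAHEDRAL)
        assert len(strict) == 2
        bridged = find_events(_series(["TTITT"]), TETRAHEDRAL, gap_tolerance=1)
        assert len(bridged) == 1 and bridged[0].duration == 5.0


def _events(durations, censored=None, comp=INTERFACE):
    censored = censored or [False] * len(durations)
    return [
        ResidenceEvent(anion_id=i, compartment=comp, start_frame=0, duration=d, censored=c)
        for i, (d, c) in enumerate(zip(durations, censored))
    ]


class TestSurvivalCurve:
    def test_two_event_counting(self):
        curve = survival_curve(_events([3.0, 5.0]), frame_dt=1.0, min_events=1)
        t = curve.times
        C = curve.C
        assert C[t == 0.0] == 1.0
        assert C[t == 3.0] == 0.5
        assert C[t == 4.0] == 0.5
        assert C[t == 5.0] == 0.0

    def test_single_event_step(self):
        curve = survival_curve(_events([1.0]), frame_dt=1.0, min_events=1)
        assert curve.C[0] == 1.0 and curve.C[-1] == 0.0

    def test_identical_durations_step_function(self):
        curve = survival_curve(_events([4.0] * 10), frame_dt=1.0, min_events=1)
        assert np.all(curve.C[curve.times < 4.0] == 1.0)
        assert np.all(curve.C[curve.times >= 4.0] == 0.0)

    def test_min_events_enforced(self):
        with pytest.raises(InsufficientStatisticsError, match="interface"):
            survival_curve(_events([3.0, 5.0]), min_events=20)

    def test_all_censored_raises(self):
        with pytest.raises(InsufficientStatisticsError):
            survival_curve(_events([3.0], censored=[True]), min_events=1)

    def test_censored_events_leave_risk_set(self):
        # censored at 2 counts as surviving before 2 and is then removed
        curve = survival_curve(
            _events([1.0, 2.0, 5.0], censored=[False, True, False]),
            frame_dt=1.0,
            min_events=1,
        )
        C = dict(zip(curve.times.tolist(), curve.C.tolist()))
        assert C[0.0] == 1.0
        assert C[1.0] == pytest.approx(2.0 / 3.0)  # censored still at risk
        assert C[2.0] == pytest.approx(1.0 / 2.0)  # censored removed from both
        assert C[5.0] == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(1, 30), min_size=3, max_size=60),
        st.lists(st.booleans(), min_size=3, max_size=60),
    )
    def test_monotone_nonincreasing_between_0_and_1(self, durations, flags):
        flags = (flags * len(durations))[: len(durations)]
        if all(f for f in flags):
            flags[0] = False
        events = _events([float(d) for d in durations], censored=flags)
        curve = survival_curve(events, frame_dt=1.0, min_events=1)
        assert curve.C[0] == 1.0
        assert np.all(np.diff(curve.C) <= 1e-12)
        assert np.all((curve.C >= 0) & (curve.C <= 1))


class TestDoubleExpFit:
    def _curve_from_function(self, fn, tmax, dt=1.0):
        t = np.arange(0.0, tmax + dt / 2, dt)
        C = fn(t)
        n0 = 10000
        num = np.round(C * n0).astype(int)
        from anionflux.kinetics import SurvivalCurve

        return SurvivalCurve(times=t, N_t=num, n_at_risk=np.full_like(num, n0), N0=n0, C=C)

    def test_single_exponential_recovered(self):
        curve = self._curve_from_function(lambda t: np.exp(-t / 50.0), 200.0)
        fit = fit_double_exp(curve)
        assert fit.tau == pytest.approx(50.0, rel=0.02)

    def test_two_time_constants_recovered(self):
        curve = self._curve_from_function(
            lambda t: 0.5 * np.exp(-t / 10.0) + 0.5 * np.exp(-t / 100.0), 400.0
        )
        fit = fit_double_exp(curve)
        assert fit.selected_model == "double"
        assert fit.lambda1 == pytest.approx(10.0, rel=0.05)
        assert fit.lambda2 == pytest.approx(100.0, rel=0.05)
        assert fit.lambda1 <= fit.lambda2

    def test_fit_is_deterministic(self):
        curve = self._curve_from_function(
            lambda t: 0.6 * np.exp(-t / 5.0) + 0.4 * np.exp(-t / 40.0), 200.0
        )
        f1, f2 = fit_double_exp(curve), fit_double_exp(curve)
        assert (f1.A1, f1.lambda1, f1.A2, f1.lambda2) == (f2.A1, f2.lambda1, f2.A2, f2.lambda2)

    def test_sampled_mixture_tau_close_to_truth(self):
        rng = np.random.default_rng(0)
        n = 5000
        lam = np.where(rng.random(n) < 0.5, 10.0, 100.0)
        durations = np.ceil(rng.exponential(lam))
        events = _events(durations.tolist())
        curve = survival_curve(events, frame_dt=1.0)
        fit = fit_double_exp(curve)
        assert fit.tau == pytest.approx(55.0, rel=0.10)

    def test_too_few_points_raises(self):
        curve = self._curve_from_function(lambda t: np.exp(-t / 2.0), 4.0)
        with pytest.raises(InsufficientStatisticsError):
            fit_double_exp(curve)

    def test_tau_within_lambda_interval(self):
        curve = self._curve_from_function(
            lambda t: 0.3 * np.exp(-t / 8.0) + 0.7 * np.exp(-t / 30.0), 150.0
        )
        fit = fit_double_exp(curve)
        assert fit.lambda1 - 1e-9 <= fit.tau <= fit.lambda2 + 1e-9


class TestMeanResidenceTime:
    def _fit(self, a1, l1, a2, l2):
        return DoubleExpFit(
            A1=a1, lambda1=l1, A2=a2, lambda2=l2, tau=0.0, rss=0.0, selected_model="double"
        )

    def test_equal_amplitudes(self):
        assert mean_residence_time(self._fit(1.0, 10.0, 1.0, 100.0)) == pytest.approx(55.0)

    def test_single_mode_limit(self):
        assert mean_residence_time(self._fit(1.0, 10.0, 0.0, 77.0)) == pytest.approx(10.0)

    def test_weighted_combination(self):
        assert mean_residence_time(self._fit(2.0, 10.0, 1.0, 100.0)) == pytest.approx(40.0)

    def test_degenerate_amplitudes_raise(self):
        with pytest.raises(DegenerateFitError):
            mean_residence_time(self._fit(0.0, 10.0, 0.0, 100.0))

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.01, 5.0),
        st.floats(0.1, 50.0),
        st.floats(0.01, 5.0),
        st.floats(0.1, 50.0),
    )
    def test_tau_is_convex_combination(self, a1, l1, a2, l2):
        tau = mean_residence_time(self._fit(a1, l1, a2, l2))
        assert min(l1, l2) - 1e-9 <= tau <= max(l1, l2) + 1e-9
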