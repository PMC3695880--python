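"""Integration, steady states, delay model and trajectory metrics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import linear_decay_model, production_decay_model

import uprkit as uk
from uprkit import dynamics as dyn


class TestProtocol:
    def test_presets(self):
        assert dyn.StressProtocol.preset("mild").segments[0][0] == 12.0
        assert dyn.StressProtocol.preset("moderate").segments[0][0] == 15.0
        assert dyn.StressProtocol.preset("severe").segments[0][0] == 18.0

    def test_value_at_and_boundaries(self):
        p = dyn.StressProtocol.stepwise([12, 15, 18], 500.0)
        assert p.value_at(0.0) == 12.0
        assert p.value_at(750.0) == 15.0
        assert p.value_at(10_000.0) == 18.0  # last segment extends
        assert p.boundaries(1200.0) == [(0.0, 500.0, 12.0), (500.0, 1000.0, 15.0),
                                        (1000.0, 1200.0, 18.0)]

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            dyn.StressProtocol(((12.0, 0.0),))
        with pytest.raises(ValueError):
            dyn.StressProtocol(((-1.0, 10.0),))


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        m = linear_decay_model(k=3.0, x0=2.0)
        traj = dyn.integrate(m, t_end=2.0, n_points=200)
        expected = 2.0 * np.exp(-3.0 * traj.times)
        assert np.max(np.abs(traj.series("X") - expected)) < 1e-6

    def test_segment_boundary_switches_input(self, full_compiled, basal_state):
        proto = dyn.StressProtocol(((0.0, 50.0), (15.0, 50.0)))
        traj = dyn.integrate(full_compiled, basal_state, proto, n_points=400)
        ufpt = traj.series("UFPT")
        before = ufpt[traj.times < 49].max()
        after = ufpt[-1]
        assert before < 1.0  # unstressed segment stays basal
        assert after > 100.0  # stress builds after the boundary

    def test_halving_tolerances_changes_little(self, full_compiled, basal_state):
        kw = dict(t_end=150.0, overrides={"mUFPT": 12.0}, n_points=100)
        a = dyn.integrate(full_compiled, basal_state, rtol=1e-8, atol=1e-10, **kw)
        b = dyn.integrate(full_compiled, basal_state, rtol=5e-9, atol=5e-11, **kw)
        for name in ("BiPT", "CHOP", "eIF2a"):
            xa, xb = a.series(name), b.series(name)
            scale = np.maximum(np.abs(xa), np.abs(xa).max() * 1e-3)
            assert np.max(np.abs(xa - xb) / scale) < 1e-3

    def test_unbounded_protocol_requires_t_end(self, full_compiled):
        with pytest.raises(ValueError):
            dyn.integrate(full_compiled, protocol=dyn.StressProtocol.constant(12.0))


class TestSteadyState:
    def test_production_decay_fixed_point(self):
        m = production_decay_model(k=4.0, d=0.5)
        y, stable = dyn.steady_state(m)
        assert y[0] == pytest.approx(8.0, abs=1e-9)
        assert stable

    def test_perk_mid_window_point_is_unstable(self, perk_compiled):
        y, stable = dyn.steady_state(perk_compiled, overrides={"PERKA": 4.0})
        assert not stable
        # conserved eIF2alpha total is pinned to the configured value
        m = perk_compiled.model
        tot = y[m.index["eIF2a"]] + y[m.index["eIF2aP"]]
        assert tot == pytest.approx(m.parameters["eIF2aT"], rel=1e-6)

    def test_stable_point_stays_put_under_integration(self, full_compiled, basal_state):
        traj = dyn.integrate(full_compiled, basal_state, t_end=1000.0, n_points=100)
        drift = np.abs(traj.final_state - basal_state)
        assert np.max(drift / np.maximum(np.abs(basal_state), 1.0)) < 1e-6


class TestDde:
    def test_tau_zero_reproduces_ode_limit(self):
        f = lambda t, y, ylag: -0.7 * ylag
        traj = dyn.integrate_dde(f, np.array([1.0]), tau=0.0, t_end=5.0, n_points=100)
        sol = solve_ivp(lambda t, y: -0.7 * y, (0, 5.0), [1.0], method="LSODA",
                        rtol=1e-8, atol=1e-10, t_eval=traj.times)
        assert np.max(np.abs(traj.series("x0") - sol.y[0])) < 1e-7

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            dyn.integrate_dde(lambda t, y, yl: -yl, np.array([1.0]), tau=-1.0)

    def test_linear_dde_oscillation_onset_at_pi_over_two(self):
        """x'(t) = -x(t-tau) destabilises at tau = pi/2 (characteristic root)."""

        def growing(tau):
            traj = dyn.integrate_dde(lambda t, y, yl: -yl, np.array([1.0]),
                                     tau=tau, t_end=260.0, n_points=2600)
            x = np.abs(traj.series("x0"))
            early = x[800:1000].max()
            late = x[-200:].max()
            return late > early

        lo, hi = 1.3, 1.9
        assert not growing(lo) and growing(hi)
        for _ in range(8):
            mid = 0.5 * (lo + hi)
            if growing(mid):
                hi = mid
            else:
                lo = mid
        onset = 0.5 * (lo + hi)
        assert onset == pytest.approx(np.pi / 2, rel=0.02)

    def test_reduced_model_needs_delay_to_oscillate(self):
        hist = np.array([0.1, 0.1])
        none = dyn.integrate_dde(dyn.ReducedDelayModel(perka=4.0, tau=0.0),
                                 hist, t_end=1500.0)
        _, _, s0 = dyn.oscillation_metrics(none, "ATF4")
        assert not s0
        delayed = dyn.integrate_dde(dyn.ReducedDelayModel(perka=4.0, tau=25.0),
                                    hist, t_end=1500.0)
        f, _, s1 = dyn.oscillation_metrics(delayed, "ATF4")
        assert s1 and f > 0

    def test_reduced_model_period_increases_with_delay(self):
        hist = np.array([0.1, 0.1])
        periods = []
        for tau in (10.0, 25.0, 45.0):
            traj = dyn.integrate_dde(dyn.ReducedDelayModel(perka=4.0, tau=tau),
                                     hist, t_end=2500.0)
            f, _, sustained = dyn.oscillation_metrics(traj, "ATF4")
            assert sustained
            periods.append(1.0 / f)
        assert periods[0] < periods[1] < periods[2]

    def test_reduced_model_shows_three_states(self):
        hist = np.array([0.1, 0.1])
        labels = []
        for perka in (1.0, 4.0, 12.0):
            traj = dyn.integrate_dde(dyn.ReducedDelayModel(perka=perka, tau=25.0),
                                     hist, t_end=2000.0)
            _, _, sustained = dyn.oscillation_metrics(traj, "ATF4")
            atf4_late = traj.series("ATF4")[-1]
            labels.append("osc" if sustained else ("high" if atf4_late > 3 else "low"))
        assert labels == ["low", "osc", "high"]


class TestMetrics:
    def _traj(self, t, x):
        return dyn.Trajectory(t, np.asarray(x)[:, None], ["s"], check_negative=False)

    def test_constant_series_not_oscillating(self):
        t = np.linspace(0, 100, 1000)
        assert dyn.oscillation_metrics(self._traj(t, np.full_like(t, 2.0)), "s") == \
            (0.0, 0.0, False)

    def test_sine_frequency_within_one_percent(self):
        T = 7.0
        t = np.linspace(0, 120, 6000)
        f, amp, sustained = dyn.oscillation_metrics(
            self._traj(t, 2 + np.sin(2 * np.pi * t / T)), "s")
        assert sustained
        assert f == pytest.approx(1 / T, rel=0.01)
        assert amp > 0.5

    def test_damped_oscillation_not_sustained(self):
        t = np.linspace(0, 60, 6000)
        x = 2 + np.exp(-t / 10) * np.sin(2 * np.pi * t / 5)
        _, _, sustained = dyn.oscillation_metrics(self._traj(t, x), "s")
        assert not sustained

    def test_short_window_raises(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            dyn.oscillation_metrics(self._traj(t, np.sin(20 * t)), "s")

    def test_renormalisation_examples(self):
        t = np.array([0.0, 1.0, 2.0])
        tr = dyn.Trajectory(t, np.array([[1.0, 5.0], [3.0, 5.0], [5.0, 5.0]]),
                            ["a", "c"])
        out = dyn.renormalize_trajectory(tr, ["a", "c"])
        assert np.allclose(out["a"], [0.0, 50.0, 100.0])
        assert np.allclose(out["c"], 0.0)  # constant series maps to zero

    def test_renormalisation_empty_selection_rejected(self):
        tr = self._traj(np.array([0.0, 1.0]), [0.0, 1.0])
        with pytest.raises(ValueError):
            dyn.renormalize_trajectory(tr, [])

    def test_activation_timing_identical_series_cross_together(self):
        t = np.linspace(0, 10, 101)
        x = np.tanh(t - 5)
        tr = dyn.Trajectory(t, np.column_stack([x, x]), ["a", "b"],
                            check_negative=False)
        out = dyn.activation_timing(tr, ["a", "b"])
        assert out["a"] == out["b"]

    def test_activation_timing_reports_non_crossing_as_absent(self):
        t = np.linspace(0, 10, 101)
        tr = dyn.Trajectory(t, np.column_stack([t, np.ones_like(t)]), ["a", "c"])
        out = dyn.activation_timing(tr, ["a", "c"], threshold_percent=50.0)
        assert out["a"] is not None
        assert out["c"] is None  # constant renormalises to 0: never crosses
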