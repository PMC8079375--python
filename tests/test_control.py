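"""Control strategies: pulse trains, stop&go trigger semantics, reference
oscillator switching law, and closed-loop behaviour."""

import math

import numpy as np
import pytest

from cyclesync import (ControllerState, InputSignal, RefOscConfig,
                       StopAndGoConfig, cycling_params, non_cycling_params,
                       open_loop_input, refosc_step, run_closed_loop,
                       stop_and_go_step)

TWO_PI = 2 * math.pi


# --- open-loop pulse trains -------------------------------------------------


def test_pulse_train_layout():
    sig = open_loop_input(75.0, 30.0, 150.0)
    for t, expect in [(0, 1), (15, 1), (29.9, 1), (30, 0), (74.9, 0),
                      (75, 1), (104.9, 1), (105, 0), (149, 0)]:
        assert sig.value_at(t) == expect, t


def test_pulse_train_degenerate_durations():
    assert open_loop_input(75.0, 0.0, 100.0).value_at(50) == 0
    assert open_loop_input(75.0, 75.0, 100.0).value_at(50) == 1
    with pytest.raises(ValueError):
        open_loop_input(75.0, 80.0, 100.0)


# --- stop&go trigger --------------------------------------------------------


def test_stop_and_go_trigger_strictly_above_threshold():
    cfg = StopAndGoConfig(threshold_pct=50.0)
    g1s = math.pi / 2
    # 6 of 10 in G1: fires and schedules a pulse
    st = ControllerState()
    phases = np.array([0.1] * 6 + [3.0] * 4)
    assert stop_and_go_step(phases, g1s, cfg, st, 0.0) == 1
    assert st.pulse_end == pytest.approx(30.0)
    # 4 of 10: stays +MET
    st = ControllerState()
    assert stop_and_go_step(np.array([0.1] * 4 + [3.0] * 6), g1s, cfg,
                            st, 0.0) == 0
    # exactly at the threshold: "higher than" is strict
    st = ControllerState()
    assert stop_and_go_step(np.array([0.1] * 5 + [3.0] * 5), g1s, cfg,
                            st, 0.0) == 0


def test_stop_and_go_holds_pulse_without_reevaluating():
    cfg = StopAndGoConfig(threshold_pct=50.0, pulse_duration=30.0)
    st = ControllerState()
    g1s = math.pi / 2
    assert stop_and_go_step(np.array([0.1, 0.2]), g1s, cfg, st, 0.0) == 1
    # all cells budded now, but the pulse is still active
    assert stop_and_go_step(np.array([3.0, 3.1]), g1s, cfg, st, 28.0) == 1
    # first sample at/after pulse end re-evaluates
    assert stop_and_go_step(np.array([3.0, 3.1]), g1s, cfg, st, 30.0) == 0


def test_stop_and_go_no_measurement_stays_plus_met():
    st = ControllerState()
    assert stop_and_go_step(np.array([]), 1.0, StopAndGoConfig(), st, 0.0) == 0


def test_stop_and_go_pulses_non_overlapping_exact_duration():
    res = run_closed_loop(non_cycling_params(), "stop_and_go", 530.0,
                          stop_go=StopAndGoConfig(threshold_pct=100.0),
                          dt=0.5, capacity=300, seed=0)
    log = res.controller_state.log
    # reconstruct pulse intervals from the decision log
    pulses = []
    prev_u = 0
    for t, u, _ in log:
        if u == 1 and prev_u == 0:
            pulses.append([t, t])
        elif u == 1:
            pulses[-1][1] = t
        prev_u = u
    assert len(pulses) >= 3
    for (a0, a1), (b0, _) in zip(pulses[:-1], pulses[1:]):
        assert b0 - a0 >= 30.0          # no overlap
    # each pulse spans exactly D = 30 min of -MET (sampled every 2 min)
    for a0, a1 in pulses:
        assert a1 - a0 == pytest.approx(30.0 - 2.0)


def test_stop_and_go_input_becomes_quasi_periodic():
    """With the ideal (100%) threshold the emitted pulse train settles
    into a near-periodic rhythm and the population locks to it."""
    res = run_closed_loop(non_cycling_params(), "stop_and_go", 530.0,
                          stop_go=StopAndGoConfig(threshold_pct=100.0),
                          dt=0.5, capacity=300, seed=0)
    starts, prev = [], 0
    for t, u, _ in res.controller_state.log:
        if u == 1 and prev == 0:
            starts.append(t)
        prev = u
    spacing = np.diff(starts)
    assert len(spacing) >= 3
    assert (spacing >= 70).all() and (spacing <= 95).all()
    m = res.metrics
    assert m.R[m.times >= 400].mean() > 0.85


# --- reference oscillator ---------------------------------------------------


def test_refosc_switching_law_branches():
    cfg = RefOscConfig()
    g1s = 4 * math.pi / 5
    # one G1 cell lagging the reference by pi/2: S = -1 < 0 -> -MET
    u, _ = refosc_step(math.pi / 2, np.array([0.0]), g1s, cfg)
    assert u == 1
    # all cells budded: gated sum is empty -> +MET
    u, _ = refosc_step(0.0, np.array([3.0, 4.0]), g1s, cfg)
    assert u == 0


def test_refosc_reference_drift_when_locked():
    """Starting from the held population phase the coupling is zero, but
    it builds up as the reference drifts ahead, so the advance over the
    hold is positive yet below omega_r * dt; with vanishing coupling the
    free-running advance is recovered exactly."""
    th0 = 1.0
    phases = np.full(5, th0)
    cfg = RefOscConfig()
    _, th1 = refosc_step(th0, phases, 4 * math.pi / 5, cfg, dt_hold=2.0)
    assert 0.0 < th1 - th0 < cfg.omega_r * 2.0
    weak = RefOscConfig(gamma=1e-9)
    _, th2 = refosc_step(th0, phases, 4 * math.pi / 5, weak, dt_hold=2.0)
    assert th2 == pytest.approx(th0 + weak.omega_r * 2.0, abs=1e-7)


def test_refosc_empty_population_free_runs():
    cfg = RefOscConfig()
    u, th1 = refosc_step(0.5, np.array([]), 1.0, cfg, dt_hold=2.0)
    assert u == 0
    assert th1 == pytest.approx(0.5 + cfg.omega_r * 2.0)


def test_refosc_single_g1_cell_error_contracts():
    """With one permanently-G1 cell and strong coupling, the wrapped
    reference error decreases monotonically once below pi."""
    cfg = RefOscConfig(gamma=5.0)
    theta_m = 0.3
    theta_r = theta_m + 2.5  # reference ahead, error < pi
    errs = [2.5]
    for _ in range(30):
        _, theta_r = refosc_step(theta_r, np.array([theta_m]), 1.0, cfg,
                                 dt_hold=2.0)
        errs.append(abs(float(np.angle(np.exp(1j * (theta_r - theta_m))))))
    assert all(b <= a + 1e-9 for a, b in zip(errs[:-1], errs[1:]))
    assert errs[-1] < 0.1


# --- closed loop ------------------------------------------------------------


def test_zero_order_hold_constant_between_samples():
    res = run_closed_loop(cycling_params(), "refosc", 200.0, dt=0.5,
                          capacity=50, seed=0)
    sig = res.input
    # input breakpoints all lie on the 2-min sampling grid
    assert np.allclose(np.mod(sig.breakpoints, 2.0), 0.0)


def test_refosc_improves_coherence_over_uncontrolled():
    cyc = cycling_params()
    ctl = run_closed_loop(cyc, "refosc", 600.0, dt=0.5, capacity=300, seed=0)
    unc = run_closed_loop(cyc, InputSignal.constant(0, 700), 600.0, dt=0.5,
                          capacity=300, seed=0)
    w = ctl.metrics.times >= 300
    assert ctl.metrics.R[w].mean() > unc.metrics.R[w].mean() + 0.2
    assert ctl.metrics.rho is not None and ctl.metrics.rho > 0.8


def test_desynchronisation_after_controller_off():
    """Once the reference-oscillator controller is switched off, newly
    born daughters dilute the synchronised cohort and coherence decays."""
    res = run_closed_loop(cycling_params(), "refosc", 800.0,
                          control_end=500.0, dt=0.5, capacity=600, seed=0)
    m = res.metrics
    on = m.R[(m.times > 300) & (m.times <= 500)].mean()
    off = m.R[m.times > 500].mean()
    assert off < on
    late_off = m.R[m.times > 700].mean()
    assert late_off < on - 0.02


def test_estimated_mode_closes_the_loop_through_traces():
    from cyclesync import ReporterConfig
    res = run_closed_loop(cycling_params(), "refosc", 400.0,
                          mode="estimated",
                          reporter_cfg=ReporterConfig(kind="cdc10",
                                                      noise_sd=0.4, seed=3),
                          dt=0.5, capacity=100, seed=0)
    assert res.estimates_valid_frac is not None
    assert res.estimates_valid_frac > 0.5
    assert res.metrics.R_bar > 0.0


def test_duration_must_exceed_calibration():
    with pytest.raises(ValueError):
        run_closed_loop(cycling_params(), "refosc", 90.0, dt=0.5)
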