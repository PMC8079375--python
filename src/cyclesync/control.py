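"""Medium-switching control strategies and the sampled-data closed loop.

Three ways to drive the binary +MET/-MET input:

* **open loop** — a fixed pulse train: ``u = 1`` on ``[k*T_u, k*T_u + D)``.
* **stop&go** — event-triggered: when the share of cells currently in G1
  exceeds a threshold, release them all with one -MET pulse of fixed
  duration ``D``; the trigger is not re-evaluated while a pulse is active.
* **reference oscillator** — state feedback: a virtual phase oscillator
  ``d theta_r/dt = omega_r + gamma * sum_m sin(theta_m - theta_r)`` is
  coupled star-wise to the population; the medium is -MET exactly when
  the G1-gated phase-difference sum ``sum_m a_m sin(theta_m - theta_r)``
  is negative (the G1 cells lag the reference).

All strategies operate under zero-order hold: the input is constant
between consecutive sampling times.  The closed-loop runner couples a
controller to the agent-based simulator either on the true simulated
phases (*oracle* mode) or on phases re-estimated at every sampling time
from synthesized noisy fluorescence traces (*estimated* mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (TWO_PI, InputSignal, Simulation, StrainParams, Trajectory)
from .reporters import ReporterConfig, TraceSet
from .metrics import (SyncMetrics, kuramoto, psd_leading_peak, time_avg_R,
                      tracking_rho, radius_from_volume)
from . import estimation as est

__all__ = ["StopAndGoConfig", "RefOscConfig", "ControllerState",
           "open_loop_input", "stop_and_go_step", "refosc_step",
           "run_closed_loop", "run_open_loop", "open_loop_sweep",
           "ClosedLoopResult"]


@dataclass(frozen=True)
class StopAndGoConfig:
    """Stop&go parameters: trigger threshold nu (percent of cells in G1,
    strict inequality), -MET pulse duration D (min), sampling cadence and
    estimator warm-up."""

    threshold_pct: float = 50.0
    pulse_duration: float = 30.0
    sampling_interval: float = 2.0
    calibration_duration: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_pct <= 100.0:
            raise ValueError("threshold_pct must lie in (0, 100]")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")


@dataclass(frozen=True)
class RefOscConfig:
    """Reference-oscillator parameters.

    ``omega_r`` defaults to the cycling strain's nominal angular velocity
    2*pi/105 rad/min, ``gamma`` to 1/min per cell.  ``gated_coupling``
    applies the G1 gate of the switching law also inside the reference
    dynamics' coupling sum (off by default: the printed dynamics sum over
    all cells ungated, while the switching law is gated).
    """

    omega_r: float = TWO_PI / 105.0
    gamma: float = 1.0
    theta_r0: float = 0.0
    sampling_interval: float = 2.0
    calibration_duration: float = 100.0
    gated_coupling: bool = False

    def __post_init__(self) -> None:
        if self.omega_r <= 0 or self.gamma <= 0:
            raise ValueError("omega_r and gamma must be positive")


@dataclass
class ControllerState:
    """Mutable controller memory: active pulse end (stop&go), reference
    phase (refosc) and a decision log of (t_k, u, summary statistic)."""

    pulse_end: float | None = None
    theta_r: float = 0.0
    log: list[tuple[float, int, float]] = field(default_factory=list)


def open_loop_input(T_u: float, D_minus_met: float, duration: float
                    ) -> InputSignal:
    """Periodic pulse train: u = 1 on [k*T_u, k*T_u + D), else 0."""
    if T_u <= 0 or duration <= 0:
        raise ValueError("T_u and duration must be positive")
    if not 0.0 <= D_minus_met <= T_u:
        raise ValueError("pulse duration must lie in [0, T_u]")
    if D_minus_met == 0:
        return InputSignal.constant(0, duration)
    if D_minus_met == T_u:
        return InputSignal.constant(1, duration)
    bp, vals = [], []
    k = 0
    while k * T_u < duration:
        bp.extend([k * T_u, k * T_u + D_minus_met])
        vals.extend([1, 0])
        k += 1
    bp_arr = np.array(bp)
    keep = bp_arr < duration
    return InputSignal(bp_arr[keep], np.array(vals)[keep], duration + T_u)


def stop_and_go_step(phases: np.ndarray, theta_G1S: float,
                     cfg: StopAndGoConfig, state: ControllerState,
                     t_k: float) -> int:
    """One stop&go decision at sampling time t_k; mutates ``state``.

    While a pulse is active the trigger is not re-evaluated.  With no
    valid measurements the medium stays +MET and the event is logged with
    a NaN statistic.
    """
    if state.pulse_end is not None and t_k < state.pulse_end - 1e-9:
        state.log.append((t_k, 1, math.nan))
        return 1
    state.pulse_end = None
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        state.log.append((t_k, 0, math.nan))
        return 0
    pct = 100.0 * float((phases < theta_G1S).mean())
    # strict "higher than" comparison; the ideal nu = 100% variant must
    # fire when every cell is in G1, so the top end closes
    fired = (pct >= 100.0 if cfg.threshold_pct >= 100.0
             else pct > cfg.threshold_pct)
    if fired:
        state.pulse_end = t_k + cfg.pulse_duration
        state.log.append((t_k, 1, pct))
        return 1
    state.log.append((t_k, 0, pct))
    return 0


def refosc_step(theta_r: float, phases: np.ndarray, theta_G1S: float,
                cfg: RefOscConfig, dt_hold: float | None = None
                ) -> tuple[int, float]:
    """One reference-oscillator decision plus reference-phase update.

    The switching law uses the G1-gated sum S = sum a_m sin(theta_m -
    theta_r): u = 1 (-MET) iff S < 0.  The reference phase is advanced
    over the hold interval by integrating its coupled dynamics with the
    measured phases held constant (classical RK4; the held field is
    smooth), then wrapped to [0, 2*pi).
    """
    if dt_hold is None:
        dt_hold = cfg.sampling_interval
    phases = np.asarray(phases, dtype=float)
    if phases.size:
        gate = (phases < theta_G1S).astype(float)
        S = float((gate * np.sin(phases - theta_r)).sum())
    else:
        S = 0.0
    u = 1 if S < 0 else 0

    if phases.size:
        coup = gate if cfg.gated_coupling else np.ones_like(phases)

        def f(th_r: float) -> float:
            return cfg.omega_r + cfg.gamma * float(
                (coup * np.sin(phases - th_r)).sum())
    else:
        def f(th_r: float) -> float:
            return cfg.omega_r

    # the coupling slope scales with gamma * N, so the hold interval is
    # subdivided to keep each RK4 step well inside the stability region
    slope = cfg.omega_r + cfg.gamma * (float(coup.sum()) if phases.size else 0.0)
    n_sub = max(1, int(math.ceil(4.0 * dt_hold * max(slope, 1.0))))
    h = dt_hold / n_sub
    th = theta_r
    for _ in range(n_sub):
        k1 = f(th)
        k2 = f(th + 0.5 * h * k1)
        k3 = f(th + 0.5 * h * k2)
        k4 = f(th + h * k3)
        th = th + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return u, float(np.mod(th, TWO_PI))


# --------------------------------------------------------------------------
# closed-loop runner
# --------------------------------------------------------------------------


@dataclass
class ClosedLoopResult:
    trajectory: Trajectory
    input: InputSignal
    metrics: SyncMetrics
    controller_state: ControllerState | None = None
    theta_r: np.ndarray | None = None
    traces: TraceSet | None = None
    estimates_valid_frac: float | None = None


def _default_medium(params: StrainParams) -> tuple[int, int]:
    """(pre-control, post-control) medium defaults.

    Non-cycling runs grow overnight in -MET (u=1) and return to +MET when
    the controller stops; cycling runs the converse.
    """
    if params.mode == "non_cycling":
        return 1, 0
    return 0, 1


class _TraceAccumulator:
    """Grows noisy reporter traces sample by sample for estimated mode."""

    def __init__(self, cfg: ReporterConfig, params: StrainParams,
                 sample_interval: float, seed: int | None):
        self.cfg = cfg
        self.params = params
        self.sample_interval = sample_interval
        self.rng = np.random.default_rng(seed)
        self.rows: list[np.ndarray] = []
        self.times: list[float] = []

    def record(self, t: float, theta: np.ndarray) -> None:
        if self.cfg.kind == "cln2":
            clean = self.cfg.baseline + self.cfg.amplitude * (
                0.5 - 0.5 * np.cos(theta - math.pi / 2.0))
        else:
            clean = np.where(theta >= self.params.theta_G1S,
                             self.cfg.on_level, self.cfg.off_level)
        noisy = clean + self.rng.normal(0.0, self.cfg.noise_sd, theta.size) \
            if self.cfg.noise_sd > 0 else clean
        self.rows.append(noisy)
        self.times.append(t)

    def traceset(self) -> TraceSet:
        n = max(r.size for r in self.rows)
        vals = np.full((len(self.rows), n), np.nan)
        for i, r in enumerate(self.rows):
            vals[i, :r.size] = r
        return TraceSet(times=np.array(self.times), values=vals,
                        sample_interval=self.sample_interval)


def _estimated_phases(acc: _TraceAccumulator, params: StrainParams,
                      t_k: float) -> np.ndarray:
    """Phases of cells with a valid estimate at t_k, from traces so far."""
    traces = acc.traceset()
    if params.mode == "non_cycling":
        p = est.ReferenceSignalParams(T0=params.T,
                                      T_flat=30.0, dt=acc.sample_interval)
        n_win = p.window_len
        if traces.times.size < n_win:
            return np.empty(0)
        taus, refs = est._reference_windows(p)
        rc = refs - refs.mean(axis=1, keepdims=True)
        rnorm = np.sqrt((rc * rc).sum(axis=1))
        out = []
        for c in range(traces.n_cells):
            w = traces.values[-n_win:, c]
            if np.isnan(w).any():
                continue
            wc = w - w.mean()
            scale = max(np.abs(w).max(), 1.0)
            if float(wc @ wc) <= est._FLAT_TOL * scale * scale * w.size:
                out.append(0.0)  # arrested in G1
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (rc @ wc) / (rnorm * math.sqrt(float(wc @ wc)))
            r = np.where(np.isfinite(r), r, -np.inf)
            best = int(np.argmax(r))
            out.append(float(np.mod((TWO_PI / p.T0) * (taus[best] - p.T_flat)
                                    + math.pi / 2.0, TWO_PI)))
        return np.array(out)
    # cycling strain: trailing-window threshold refit + binarization
    try:
        bts = est.binarize_traces(traces)
    except ValueError:  # threshold not yet identifiable
        return np.empty(0)
    out = []
    for trs in bts.transitions:
        th = est.estimate_phase_cycling(trs, t_k, params.T, params.theta_G1S)
        if th is not None:
            out.append(th)
    return np.array(out)


def run_closed_loop(params: StrainParams,
                    controller: str | InputSignal,
                    duration: float, *,
                    mode: str = "oracle",
                    stop_go: StopAndGoConfig | None = None,
                    ref_osc: RefOscConfig | None = None,
                    reporter_cfg: ReporterConfig | None = None,
                    seed: int | None = None,
                    dt: float = 0.1,
                    N0: int = 3,
                    initial_phases="uniform",
                    capacity: int | None = None,
                    control_end: float | None = None,
                    precontrol_u: int | None = None,
                    postcontrol_u: int | None = None,
                    ar_order: int = 20) -> ClosedLoopResult:
    """Run a full sampled-data experiment.

    ``controller`` is ``"stop_and_go"``, ``"refosc"``, or an
    :class:`InputSignal` for open loop.  The controller acts from the end
    of the calibration window to ``control_end`` (default: the whole
    horizon); before and after, the medium is held at the strain's
    conventional pre/post-control value.  ``mode="oracle"`` feeds true
    simulated phases to the controller; ``mode="estimated"`` synthesizes
    noisy reporter traces and re-runs the phase estimator at every
    sampling time.  Synchronisation metrics are computed on the true
    phases over the control-active window.
    """
    if mode not in ("oracle", "estimated"):
        raise ValueError("mode must be 'oracle' or 'estimated'")
    open_loop = isinstance(controller, InputSignal)
    if controller == "stop_and_go":
        cfg_any = stop_go or StopAndGoConfig()
        sample_interval = cfg_any.sampling_interval
        calibration = cfg_any.calibration_duration
    elif controller == "refosc":
        cfg_any = ref_osc or RefOscConfig()
        sample_interval = cfg_any.sampling_interval
        calibration = cfg_any.calibration_duration
    elif open_loop:
        cfg_any = None
        sample_interval = 2.0
        calibration = 0.0
    else:
        raise ValueError(f"unknown controller {controller!r}")
    if duration <= calibration:
        raise ValueError("duration must exceed the calibration window")
    pre_u, post_u = _default_medium(params)
    if precontrol_u is not None:
        pre_u = precontrol_u
    if postcontrol_u is not None:
        post_u = postcontrol_u
    if control_end is None:
        control_end = duration
    if reporter_cfg is None:
        kind = "cln2" if params.mode == "non_cycling" else "cdc10"
        reporter_cfg = ReporterConfig(kind=kind, seed=seed)

    sim = Simulation(params, N0=N0, initial_phases=initial_phases, seed=seed,
                     capacity=capacity)
    state = ControllerState(theta_r=(cfg_any.theta_r0
                                     if controller == "refosc" else 0.0))
    acc = _TraceAccumulator(reporter_cfg, params, sample_interval, seed)

    n_samp = int(round(duration / sample_interval)) + 1
    times = np.arange(n_samp) * sample_interval
    snaps_theta = [sim.theta.copy()]
    snaps_V = [sim.V.copy()]
    theta_r_series = [state.theta_r]
    applied_bp: list[float] = []
    applied_u: list[int] = []
    valid_counts = []
    if acc is not None:
        acc.record(0.0, sim.theta)

    for k in range(n_samp - 1):
        t_k = float(times[k])
        h = float(times[k + 1] - times[k])
        if open_loop:
            for a, b, u in controller.segments(t_k, t_k + h):
                sim.advance_interval(u, b - a, dt)
                if not applied_u or applied_u[-1] != u:
                    applied_bp.append(a)
                    applied_u.append(u)
            snaps_theta.append(sim.theta.copy())
            snaps_V.append(sim.V.copy())
            if acc is not None:
                acc.record(float(times[k + 1]), sim.theta)
            continue
        in_control = calibration - 1e-9 <= t_k < control_end - 1e-9
        if t_k < calibration - 1e-9:
            u = pre_u
        elif not in_control:
            u = post_u
        else:
            if mode == "oracle":
                phases = sim.theta.copy()
            else:
                phases = _estimated_phases(acc, params, t_k)
            valid_counts.append((t_k, phases.size, sim.n))
            if controller == "stop_and_go":
                u = stop_and_go_step(phases, params.theta_G1S, cfg_any,
                                     state, t_k)
            else:
                u, state.theta_r = refosc_step(state.theta_r, phases,
                                               params.theta_G1S, cfg_any, h)
        if controller == "refosc" and not in_control:
            # keep the virtual oscillator free-running outside control
            state.theta_r = float(np.mod(state.theta_r + cfg_any.omega_r * h,
                                         TWO_PI))
        sim.advance_interval(u, h, dt)
        if not applied_u or applied_u[-1] != u:
            applied_bp.append(t_k)
            applied_u.append(u)
        snaps_theta.append(sim.theta.copy())
        snaps_V.append(sim.V.copy())
        theta_r_series.append(state.theta_r)
        if acc is not None:
            acc.record(float(times[k + 1]), sim.theta)

    n_final = sim.n
    theta = np.full((n_samp, n_final), np.nan)
    volume = np.full((n_samp, n_final), np.nan)
    for i, (th, vv) in enumerate(zip(snaps_theta, snaps_V)):
        theta[i, :th.size] = th
        volume[i, :vv.size] = vv
    signal = (controller if open_loop else
              InputSignal(applied_bp or [0.0], applied_u or [pre_u],
                          duration + sample_interval))
    traj = Trajectory(times=times, theta=theta, volume=volume,
                      birth_times=sim.birth_times.copy(),
                      parent_ids=sim.parent_ids.copy(), input=signal,
                      divisions=list(sim.divisions), params=params,
                      meta={"seed": seed, "dt": dt, "N0": N0,
                            "capacity": capacity, "mode": mode,
                            "sample_interval": sample_interval,
                            "controller": ("open_loop" if open_loop
                                           else controller),
                            "calibration": calibration,
                            "control_end": control_end})

    # --- metrics over the control-active window (true phases) ---
    active = (times >= calibration - 1e-9) & (times <= control_end + 1e-9)
    R = np.empty(n_samp)
    psi = np.empty(n_samp)
    for i in range(n_samp):
        R[i], psi[i] = kuramoto(traj.phases_at(i))
    R_bar = time_avg_R(R[active], times[active])
    vols = [traj.volumes_at(i) for i in np.nonzero(active)[0]]
    mean_vol = float(np.mean([v.mean() for v in vols]))
    mean_rad = float(np.mean([radius_from_volume(v).mean() for v in vols]))
    traces = acc.traceset() if acc is not None else None
    power_db = period_min = None
    if traces is not None:
        sig = traces.mean_signal()[active]
        peak = psd_leading_peak(sig, sample_interval, ar_order=ar_order)
        if peak is not None:
            power_db, period_min = peak
    rho = None
    theta_r_arr = None
    if controller == "refosc":
        theta_r_arr = np.array(theta_r_series)
        rho = tracking_rho(theta_r_arr[active], psi[active])
    metrics = SyncMetrics(R=R, psi=psi, times=times, R_bar=R_bar,
                          power_db=power_db, period_min=period_min, rho=rho,
                          mean_radius_bar=mean_rad, mean_volume_bar=mean_vol)
    frac = None
    if valid_counts:
        frac = float(np.mean([v / max(n, 1) for _, v, n in valid_counts]))
    return ClosedLoopResult(trajectory=traj, input=signal, metrics=metrics,
                            controller_state=(None if open_loop else state),
                            theta_r=theta_r_arr, traces=traces,
                            estimates_valid_frac=frac)


def run_open_loop(params: StrainParams, T_u: float, D: float,
                  duration: float, **kwargs) -> ClosedLoopResult:
    """Convenience wrapper: periodic pulse train experiment."""
    return run_closed_loop(params, open_loop_input(T_u, D, duration),
                           duration, **kwargs)


def open_loop_sweep(params: StrainParams, T_u_values, D: float,
                    duration: float, *, steady_window: float = 500.0,
                    dt: float = 0.1, N0: int = 3, capacity: int | None = 300,
                    seed: int | None = None) -> dict:
    """Steady-state coherence and volume versus the forcing period.

    For each T_u the model runs under a D-minute -MET pulse train; the
    returned record holds the time-averaged R and mean volume over the
    final ``steady_window`` minutes.
    """
    out = {"T_u": [], "R_bar": [], "mean_volume": [], "mean_radius": [],
           "results": []}
    for T_u in T_u_values:
        res = run_closed_loop(params, open_loop_input(T_u, D, duration),
                              duration, dt=dt, N0=N0, capacity=capacity,
                              seed=seed)
        m = res.metrics
        t = m.times
        w = t >= duration - steady_window - 1e-9
        r_bar = time_avg_R(m.R[w], t[w])
        vols = [res.trajectory.volumes_at(i) for i in np.nonzero(w)[0]]
        out["T_u"].append(float(T_u))
        out["R_bar"].append(r_bar)
        out["mean_volume"].append(float(np.mean([v.mean() for v in vols])))
        out["mean_radius"].append(float(np.mean(
            [radius_from_volume(v).mean() for v in vols])))
        out["results"].append(res)
    return out
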