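"""Agent-based budding-yeast cell-cycle model.

Each cell is a phase oscillator on the unit circle with an associated
volume.  The phase ``theta`` is frozen while the volume is below a critical
value ``V_c``; above it the phase advances with a strain-specific angular
velocity plus, while the cell is in G1 and the medium is methionine-free
(``u = 1``), an input-added angular velocity (the phase response).  Volume
grows exponentially during G1 only.  When a cell's phase crosses ``2*pi``
it wraps to zero and a daughter agent is spawned with a fixed fraction of
the mother's volume.

Two strain variants are modelled:

* *non-cycling* — the phase drift is zero in G1, so the cell arrests there
  unless methionine is removed (``u = 1``); beyond the G1/S point it free
  runs at ``omega = 2*pi/T`` with ``T = 75`` min.
* *cycling* — the phase drifts at ``omega = 2*pi/T`` everywhere
  (``T = 105`` min); ``-MET`` pulses merely speed G1 up by ``omega_z``.

The vector field is piecewise constant in phase regions and the volume ODE
is linear, so every trajectory segment has a closed form.  The stepper
advances each agent exactly from event to event (volume reaching ``V_c``,
phase reaching the G1/S point, phase reaching ``2*pi``, input switching),
which makes the integration exact and bitwise reproducible; the ``dt``
argument only caps the step length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "StrainParams",
    "CellState",
    "PopulationState",
    "InputSignal",
    "DivisionEvent",
    "Trajectory",
    "Simulation",
    "non_cycling_params",
    "cycling_params",
    "phase_drift",
    "growth_rate",
    "phase_response",
    "step",
    "simulate",
]


# --------------------------------------------------------------------------
# parameters and state containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainParams:
    """All model constants for one strain variant.

    Parameters
    ----------
    mode:
        ``"non_cycling"`` or ``"cycling"``.
    V_c:
        Critical volume separating daughters (frozen phase) from mothers,
        in relative units.
    beta:
        Exponential volume growth rate during G1, 1/min.
    T:
        Nominal cell-cycle period, min.  ``omega = 2*pi/T`` is derived.
    omega_z:
        Input-added angular velocity in G1 under ``-MET``, rad/min.
    theta_G1S:
        Phase at the G1 -> S (START) transition, rad.
    daughter_fraction:
        Daughter/mother volume ratio at division.
    """

    mode: str
    V_c: float
    beta: float
    T: float
    omega_z: float
    theta_G1S: float
    daughter_fraction: float = 0.61

    def __post_init__(self) -> None:
        if self.mode not in ("non_cycling", "cycling"):
            raise ValueError(f"unknown strain mode {self.mode!r}")
        if self.V_c <= 0 or self.beta <= 0 or self.T <= 0:
            raise ValueError("V_c, beta and T must be positive")
        if not 0.0 < self.theta_G1S < TWO_PI:
            raise ValueError("theta_G1S must lie in (0, 2*pi)")
        if not 0.0 < self.daughter_fraction < 1.0:
            raise ValueError("daughter_fraction must lie in (0, 1)")
        if self.omega_z < 0:
            raise ValueError("omega_z must be non-negative")

    @property
    def omega(self) -> float:
        """Free-running angular velocity 2*pi/T, rad/min."""
        return TWO_PI / self.T


def non_cycling_params(**overrides) -> StrainParams:
    """Defaults for the methionine-arrestable (cln1-3) strain: T = 75 min,
    omega_z = 2*pi/T, theta_G1S = pi/2."""
    p = dict(mode="non_cycling", V_c=1.0, beta=0.0083, T=75.0,
             omega_z=TWO_PI / 75.0, theta_G1S=math.pi / 2.0)
    p.update(overrides)
    if "T" in overrides and "omega_z" not in overrides:
        p["omega_z"] = TWO_PI / p["T"]
    return StrainParams(**p)


def cycling_params(**overrides) -> StrainParams:
    """Defaults for the autonomously cycling (cln3) strain: T = 105 min,
    omega_z = pi/T, theta_G1S = 4*pi/5."""
    p = dict(mode="cycling", V_c=1.0, beta=0.0083, T=105.0,
             omega_z=math.pi / 105.0, theta_G1S=4.0 * math.pi / 5.0)
    p.update(overrides)
    if "T" in overrides and "omega_z" not in overrides:
        p["omega_z"] = math.pi / p["T"]
    return StrainParams(**p)


@dataclass
class CellState:
    """One agent: identity, lineage, phase and volume."""

    cell_id: int
    parent_id: int | None
    birth_time: float
    theta: float
    V: float


@dataclass
class PopulationState:
    """The population at one instant."""

    time: float
    cells: list[CellState]

    @property
    def n(self) -> int:
        return len(self.cells)

    def phases(self) -> np.ndarray:
        return np.array([c.theta for c in self.cells])

    def volumes(self) -> np.ndarray:
        return np.array([c.V for c in self.cells])


@dataclass(frozen=True)
class DivisionEvent:
    """A 2*pi crossing.  ``retained`` is False when the daughter was not
    kept as an agent because the population was at capacity."""

    time: float
    mother_id: int
    daughter_id: int | None
    mother_volume: float
    daughter_volume: float
    retained: bool = True


class InputSignal:
    """Piecewise-constant binary medium signal under zero-order hold.

    ``u = 0`` is methionine-rich (+MET), ``u = 1`` methionine-depleted
    (-MET).  The signal is defined on ``[t0, horizon)`` by breakpoints and
    per-interval values.
    """

    def __init__(self, breakpoints: Sequence[float], values: Sequence[int],
                 horizon: float):
        bp = np.asarray(breakpoints, dtype=float)
        va = np.asarray(values)
        if bp.ndim != 1 or bp.size == 0 or bp.size != va.size:
            raise ValueError("breakpoints and values must be equal-length 1-d")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not np.isin(va, (0, 1)).all():
            raise ValueError("input values must be binary")
        if horizon <= bp[-1]:
            raise ValueError("horizon must exceed the last breakpoint")
        self.breakpoints = bp
        self.values = va.astype(int)
        self.horizon = float(horizon)

    @classmethod
    def constant(cls, u: int, horizon: float, t0: float = 0.0) -> "InputSignal":
        return cls([t0], [u], horizon)

    def value_at(self, t: float) -> int:
        """u on the interval containing t (right-open intervals)."""
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        if i < 0:
            raise ValueError(f"t={t} precedes the signal start")
        return int(self.values[i])

    def segments(self, t_start: float, t_end: float):
        """Yield (a, b, u) sub-intervals covering [t_start, t_end)."""
        cuts = self.breakpoints[(self.breakpoints > t_start)
                                & (self.breakpoints < t_end)]
        edges = np.concatenate(([t_start], cuts, [t_end]))
        for a, b in zip(edges[:-1], edges[1:]):
            yield float(a), float(b), self.value_at(a)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_min": self.breakpoints, "u": self.values})


# --------------------------------------------------------------------------
# exact event-split advancement
# --------------------------------------------------------------------------

_EPS_T = 1e-12  # residual-time tolerance, min


class Simulation:
    """Mutable agent population advanced exactly between events.

    Founders start with uniformly spaced (or seeded-random) phases and
    volume ``V_c``.  ``capacity`` bounds the number of retained agents:
    divisions past it are still logged but the daughter agent is dropped,
    mimicking the fixed-size microfluidic trap that sheds excess newborns.
    """

    def __init__(self, params: StrainParams, N0: int = 3, *,
                 initial_phases: str | Sequence[float] = "uniform",
                 seed: int | None = None, capacity: int | None = None,
                 start_time: float = 0.0):
        if N0 < 1:
            raise ValueError("N0 must be at least 1")
        if capacity is not None and capacity < N0:
            raise ValueError("capacity must be >= N0")
        self.params = params
        self.capacity = capacity
        self.t = float(start_time)
        if isinstance(initial_phases, str):
            if initial_phases == "uniform":
                theta0 = TWO_PI * np.arange(N0) / N0
            elif initial_phases == "random":
                rng = np.random.default_rng(seed)
                theta0 = rng.uniform(0.0, TWO_PI, N0)
            else:
                raise ValueError(f"unknown initial_phases {initial_phases!r}")
        else:
            theta0 = np.asarray(initial_phases, dtype=float)
            if theta0.size != N0:
                raise ValueError("initial_phases length must equal N0")
        self.theta = theta0.astype(float).copy()
        self.V = np.full(N0, params.V_c, dtype=float)
        self.birth_times = np.full(N0, self.t)
        self.parent_ids = np.full(N0, -1, dtype=int)
        self._next_id = N0
        self.divisions: list[DivisionEvent] = []
        self.seed = seed

    @property
    def n(self) -> int:
        return self.theta.size

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n)

    def budded(self) -> np.ndarray:
        return self.theta >= self.params.theta_G1S

    def advance(self, u: int, h: float) -> None:
        """Advance every agent exactly by ``h`` minutes under constant u."""
        if h <= 0:
            raise ValueError("time step must be positive")
        if u not in (0, 1):
            raise ValueError("u must be 0 or 1")
        p = self.params
        g1_rate = (0.0 if p.mode == "non_cycling" else p.omega) + p.omega_z * u
        rem = np.full(self.n, float(h))
        theta, V = self.theta, self.V
        while True:
            act = rem > _EPS_T
            if not act.any():
                break
            idx = np.nonzero(act)[0]
            th = theta[idx]
            vv = V[idx]
            r = rem[idx]
            in_g1 = th < p.theta_G1S
            frozen = vv < p.V_c
            rate = np.where(frozen, 0.0, np.where(in_g1, g1_rate, p.omega))
            growing = in_g1  # dV/dt = beta*V only in G1, frozen or not
            # event horizons
            t_unfreeze = np.full(idx.size, np.inf)
            m = frozen & growing
            if m.any():
                t_unfreeze[m] = np.log(p.V_c / vv[m]) / p.beta
            boundary = np.where(in_g1, p.theta_G1S, TWO_PI)
            t_bound = np.full(idx.size, np.inf)
            m = rate > 0
            t_bound[m] = (boundary[m] - th[m]) / rate[m]
            t_event = np.minimum(t_unfreeze, t_bound)
            dt_i = np.minimum(r, t_event)
            # exact advancement over the event-free piece
            th = th + rate * dt_i
            vv = np.where(growing, vv * np.exp(p.beta * dt_i), vv)
            r = r - dt_i
            hit = t_event <= dt_i  # event reached within this piece
            # pin states exactly at their events to avoid float drift
            uf = hit & (t_unfreeze <= t_bound)
            vv[uf] = p.V_c
            bd = hit & (t_bound < t_unfreeze)
            th[bd] = boundary[bd]
            theta[idx] = th
            V[idx] = vv
            rem[idx] = r
            # divisions: cells pinned at 2*pi wrap and spawn a daughter
            div = np.nonzero(bd & (boundary >= TWO_PI))[0]
            if div.size:
                new_theta, new_V, new_birth, new_parent, new_rem = [], [], [], [], []
                for j in div:
                    i = idx[j]
                    t_div = self.t + h - rem[i]
                    theta[i] = 0.0
                    vd = p.daughter_fraction * V[i]
                    retain = self.capacity is None or (
                        self.n + len(new_theta) < self.capacity)
                    did = self._next_id if retain else None
                    self.divisions.append(DivisionEvent(
                        time=t_div, mother_id=int(i), daughter_id=did,
                        mother_volume=float(V[i]), daughter_volume=float(vd),
                        retained=retain))
                    if retain:
                        self._next_id += 1
                        new_theta.append(0.0)
                        new_V.append(vd)
                        new_birth.append(t_div)
                        new_parent.append(int(i))
                        new_rem.append(rem[i])
                if new_theta:
                    theta = np.concatenate((theta, new_theta))
                    V = np.concatenate((V, new_V))
                    rem = np.concatenate((rem, new_rem))
                    self.birth_times = np.concatenate(
                        (self.birth_times, new_birth))
                    self.parent_ids = np.concatenate(
                        (self.parent_ids, new_parent))
                    self.theta, self.V = theta, V
        self.theta, self.V = theta, V
        self.t += h

    def advance_interval(self, u: int, h: float, dt: float) -> None:
        """Advance by ``h`` in pieces no longer than ``dt``."""
        n_sub = max(1, int(math.ceil(h / dt - 1e-9)))
        sub = h / n_sub
        for _ in range(n_sub):
            self.advance(u, sub)

    def population_state(self) -> PopulationState:
        cells = [CellState(cell_id=i, parent_id=(None if self.parent_ids[i] < 0
                                                 else int(self.parent_ids[i])),
                           birth_time=float(self.birth_times[i]),
                           theta=float(self.theta[i]), V=float(self.V[i]))
                 for i in range(self.n)]
        return PopulationState(time=self.t, cells=cells)


# --------------------------------------------------------------------------
# spec-level operations
# --------------------------------------------------------------------------


def _check_theta(theta: float) -> None:
    if not 0.0 <= theta < TWO_PI:
        raise ValueError(f"theta={theta} outside [0, 2*pi)")


def phase_drift(theta: float, params: StrainParams) -> float:
    """Strain drift f(theta), rad/min: zero in G1 for the non-cycling
    strain, omega elsewhere; omega everywhere for the cycling strain."""
    _check_theta(theta)
    if params.mode == "cycling":
        return params.omega
    return 0.0 if theta < params.theta_G1S else params.omega


def growth_rate(theta: float, V: float, params: StrainParams) -> float:
    """Volume growth g(theta) = beta*V during G1, zero in S-G2-M."""
    _check_theta(theta)
    if V < 0:
        raise ValueError("V must be non-negative")
    return params.beta * V if theta < params.theta_G1S else 0.0


def phase_response(theta: float, params: StrainParams) -> float:
    """Phase response z(theta): omega_z in G1, zero in S-G2-M."""
    _check_theta(theta)
    return params.omega_z if theta < params.theta_G1S else 0.0


def step(pop: PopulationState, u: int, dt: float, params: StrainParams,
         capacity: int | None = None) -> PopulationState:
    """Advance a population by one step of length ``dt`` under constant u.

    Daughters spawned by 2*pi crossings are appended with fresh ids and
    integrated for the remainder of the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sim = Simulation.__new__(Simulation)
    sim.params = params
    sim.capacity = capacity
    sim.t = pop.time
    sim.theta = pop.phases().astype(float)
    sim.V = pop.volumes().astype(float)
    sim.birth_times = np.array([c.birth_time for c in pop.cells], dtype=float)
    sim.parent_ids = np.array(
        [-1 if c.parent_id is None else c.parent_id for c in pop.cells],
        dtype=int)
    sim._next_id = (max(c.cell_id for c in pop.cells) + 1) if pop.cells else 0
    sim.divisions = []
    sim.seed = None
    old_ids = [c.cell_id for c in pop.cells]
    sim.advance(u, dt)
    cells = []
    for i in range(sim.n):
        cid = old_ids[i] if i < len(old_ids) else None
        cells.append(CellState(
            cell_id=cid if cid is not None else -1,
            parent_id=(None if sim.parent_ids[i] < 0
                       else old_ids[sim.parent_ids[i]]),
            birth_time=float(sim.birth_times[i]),
            theta=float(sim.theta[i]), V=float(sim.V[i])))
    # daughters got provisional ids; renumber continuing from the max
    nxt = (max(old_ids) + 1) if old_ids else 0
    for c in cells:
        if c.cell_id == -1:
            c.cell_id = nxt
            nxt += 1
    return PopulationState(time=pop.time + dt, cells=cells)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Sampled population history on a uniform time grid.

    ``theta`` and ``volume`` are (n_samples, n_cells) arrays, NaN before a
    cell's birth.  Cells are indexed by id: founders ``0..N0-1`` then
    daughters in birth order.
    """

    times: np.ndarray
    theta: np.ndarray
    volume: np.ndarray
    birth_times: np.ndarray
    parent_ids: np.ndarray
    input: InputSignal
    divisions: list[DivisionEvent]
    params: StrainParams
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.theta.shape[1]

    def alive(self, i: int) -> np.ndarray:
        """Boolean mask of cells already born at sample index i."""
        return self.birth_times <= self.times[i] + _EPS_T

    def phases_at(self, i: int) -> np.ndarray:
        th = self.theta[i]
        return th[~np.isnan(th)]

    def volumes_at(self, i: int) -> np.ndarray:
        v = self.volume[i]
        return v[~np.isnan(v)]

    def counts(self) -> np.ndarray:
        return (~np.isnan(self.theta)).sum(axis=1)

    def budded_fraction(self) -> np.ndarray:
        """Per-sample fraction of alive cells with theta >= theta_G1S."""
        b = (self.theta >= self.params.theta_G1S)
        alive = ~np.isnan(self.theta)
        return b.sum(axis=1) / np.maximum(alive.sum(axis=1), 1)

    def to_frame(self):
        """Tidy long-format view: one row per cell per sample."""
        import pandas as pd
        S, N = self.theta.shape
        rows = ~np.isnan(self.theta)
        t_idx, c_idx = np.nonzero(rows)
        return pd.DataFrame({
            "time_min": self.times[t_idx],
            "cell_id": c_idx,
            "parent_id": self.parent_ids[c_idx],
            "theta_rad": self.theta[t_idx, c_idx],
            "volume": self.volume[t_idx, c_idx],
            "budded_flag": (self.theta[t_idx, c_idx]
                            >= self.params.theta_G1S).astype(int),
        })


def simulate(params: StrainParams,
             input: InputSignal | Callable[[float, np.ndarray], int],
             duration: float, *, dt: float = 0.1, sample_interval: float = 2.0,
             N0: int = 3, seed: int | None = None,
             initial_phases: str | Sequence[float] = "uniform",
             capacity: int | None = None) -> Trajectory:
    """Simulate a growing population under a fixed input signal.

    ``input`` may be an :class:`InputSignal` or a callback
    ``f(t, phases) -> u`` evaluated at every sampling time (zero-order
    hold between samples).  The result is sampled every
    ``sample_interval`` minutes (default 2 min, the image-acquisition
    cadence).  ``seed`` only matters for ``initial_phases="random"``; the
    dynamics themselves are deterministic.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > sample_interval:
        raise ValueError("dt must not exceed sample_interval")
    sim = Simulation(params, N0=N0, initial_phases=initial_phases, seed=seed,
                     capacity=capacity)
    n_samp = int(round(duration / sample_interval)) + 1
    times = np.arange(n_samp) * sample_interval
    snaps_theta: list[np.ndarray] = [sim.theta.copy()]
    snaps_V: list[np.ndarray] = [sim.V.copy()]
    callback = not isinstance(input, InputSignal)
    applied_bp: list[float] = []
    applied_u: list[int] = []
    for k in range(n_samp - 1):
        a, b = float(times[k]), float(times[k + 1])
        if callback:
            try:
                u = int(input(a, sim.theta.copy()))
            except Exception as exc:  # abort with context
                raise RuntimeError(
                    f"controller callback failed at t={a} min "
                    f"with {sim.n} cells") from exc
            sim.advance_interval(u, b - a, dt)
            if not applied_u or applied_u[-1] != u:
                applied_bp.append(a)
                applied_u.append(u)
        else:
            for s0, s1, u in input.segments(a, b):
                sim.advance_interval(u, s1 - s0, dt)
        snaps_theta.append(sim.theta.copy())
        snaps_V.append(sim.V.copy())
    n_final = sim.n
    theta = np.full((n_samp, n_final), np.nan)
    volume = np.full((n_samp, n_final), np.nan)
    for i, (th, vv) in enumerate(zip(snaps_theta, snaps_V)):
        theta[i, :th.size] = th
        volume[i, :vv.size] = vv
    if callback:
        signal = InputSignal(applied_bp or [0.0], applied_u or [0],
                             duration + sample_interval)
    else:
        signal = input
    return Trajectory(times=times, theta=theta, volume=volume,
                      birth_times=sim.birth_times.copy(),
                      parent_ids=sim.parent_ids.copy(), input=signal,
                      divisions=list(sim.divisions), params=params,
                      meta={"seed": seed, "dt": dt, "N0": N0,
                            "capacity": capacity,
                            "sample_interval": sample_interval})
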