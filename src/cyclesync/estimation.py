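"""Single-cell cell-cycle phase estimation from fluorescence traces.

Two estimators, one per strain readout:

* **Cross-correlation estimator** (non-cycling strain, CLN2 reporter).
  The trailing ``T_flat`` minutes of a cell's trace are Pearson-correlated
  against every same-length sub-window of a periodic reference signal —
  flat for ``T_flat`` minutes, then one raised-cosine cycle of period
  ``T0`` — and the best-matching window position is mapped linearly to a
  phase: ``theta_hat = (2*pi/T0) * (tau* - T_flat) + pi/2`` (mod 2*pi).
  Pearson correlation makes the estimate invariant to affine rescaling of
  the fluorescence signal.

* **Binarization estimator** (cycling strain, CDC10 reporter).  Traces are
  smoothed (5-sample then 3-sample moving averages), thresholded at the
  intersection of a two-component Gaussian mixture fitted to the pooled
  raw values of the trailing 100 min, and scanned for on/off transitions
  with a 14-min refractory constraint.  The phase is the angular distance
  travelled at the nominal rate since the last accepted transition:
  ``omega0 * elapsed`` after entering the unbudded phase (on -> off), plus
  ``theta_G1S`` after entering the budded phase (off -> on), clamped just
  below the segment's end boundary.

The same transition machinery recovers the strain's nominal timing from
an uncontrolled +MET experiment: the median unbudded and budded interval
durations, their sum ``T0``, and ``theta_G1S = 2*pi * T_G1 / T0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import TWO_PI
from .reporters import TraceSet

__all__ = [
    "ReferenceSignalParams", "ThresholdModel", "Transition", "BinaryTraceSet",
    "PhaseEstimateSet", "build_reference", "estimate_phase_noncycling",
    "smooth", "fit_threshold", "binarize", "detect_transitions",
    "estimate_phase_cycling", "estimate_nominal_periods", "budding_index",
    "estimate_phases_noncycling", "estimate_phases_cycling", "NominalPeriods",
]

_FLAT_TOL = 1e-9       # relative variance tolerance for arrested windows
_CLAMP = 1e-9          # phase clamp margin below segment boundaries


# --------------------------------------------------------------------------
# reference-signal cross-correlation estimator (non-cycling strain)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSignalParams:
    """Periodic reference: flat for T_flat, then one cosine cycle of T0.

    Defaults: T0 = 75 min (nominal non-cycling period), T_flat = 30 min
    (the length of the compared trailing fluorescence window), dt = 2 min.
    """

    T0: float = 75.0
    T_flat: float = 30.0
    dt: float = 2.0

    def __post_init__(self) -> None:
        if self.T0 <= 0 or self.T_flat <= 0 or self.dt <= 0:
            raise ValueError("T0, T_flat and dt must be positive")

    @property
    def T(self) -> float:
        return self.T_flat + self.T0

    @property
    def window_len(self) -> int:
        """Samples in a T_flat-long window (inclusive of both ends)."""
        return int(round(self.T_flat / self.dt)) + 1


def build_reference(p: ReferenceSignalParams, n_periods: int = 1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the T-periodic reference signal over ``n_periods`` periods.

    Zero on each ``[kT, kT + T_flat)``; ``1/2 - 1/2*cos(2*pi/T0 *
    (t - kT - T_flat))`` on the rest, so the signal is continuous at the
    flat/cosine junction.  Returns (times, values) on the dt grid.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be at least 1")
    t = np.arange(0.0, n_periods * p.T + p.dt / 2, p.dt)
    tau = np.mod(t, p.T)
    vals = np.where(tau < p.T_flat, 0.0,
                    0.5 - 0.5 * np.cos(TWO_PI / p.T0 * (tau - p.T_flat)))
    return t, vals


def _reference_windows(p: ReferenceSignalParams) -> tuple[np.ndarray, np.ndarray]:
    """All reference sub-windows [tau - T_flat, tau], tau on the dt grid
    over [T_flat, T].  Returns (taus, matrix of shape (n_tau, window_len))."""
    _, ref = build_reference(p, n_periods=2)
    n_win = p.window_len
    n_tau = int(math.floor((p.T - p.T_flat) / p.dt)) + 1
    taus = p.T_flat + p.dt * np.arange(n_tau)
    starts = np.round((taus - p.T_flat) / p.dt).astype(int)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    return taus, ref[idx]


def estimate_phase_noncycling(window: np.ndarray, p: ReferenceSignalParams
                              ) -> tuple[float | None, float]:
    """Phase from the trailing T_flat-long fluorescence window.

    Returns ``(theta_hat, r_max)``; ``theta_hat`` is None when the window
    is flat to within tolerance (a G1-arrested cell — Pearson correlation
    is undefined), in which case the caller decides the fallback.
    Argmax ties break toward the smallest tau (earliest phase).
    """
    w = np.asarray(window, dtype=float)
    if w.size != p.window_len:
        raise ValueError(
            f"window must hold {p.window_len} samples (T_flat/dt + 1), "
            f"got {w.size}")
    wc = w - w.mean()
    scale = max(abs(w).max(), 1.0)
    if float(wc @ wc) <= _FLAT_TOL * scale * scale * w.size:
        return None, float("nan")
    taus, refs = _reference_windows(p)
    rc = refs - refs.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc * rc).sum(axis=1) * float(wc @ wc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ wc) / denom
    r = np.where(np.isfinite(r), r, -np.inf)  # flat reference windows
    best = int(np.argmax(r))  # argmax returns the first (smallest tau)
    theta = (TWO_PI / p.T0) * (taus[best] - p.T_flat) + math.pi / 2.0
    return float(np.mod(theta, TWO_PI)), float(r[best])


# --------------------------------------------------------------------------
# smoothing, mixture threshold, binarization (cycling strain)
# --------------------------------------------------------------------------


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the ends:
    at distance d < half-width from an edge the window shrinks to 2d+1."""
    half = width // 2
    out = np.empty_like(x, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return out


def smooth(trace: np.ndarray) -> np.ndarray:
    """Coarse 5-sample then fine 3-sample centered moving averages."""
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("trace must hold at least one sample")
    return _moving_average(_moving_average(x, 5), 3)


@dataclass(frozen=True)
class ThresholdModel:
    """Two-component normal mixture and the binarization threshold ``l``
    (the equal-weighted-density intersection between the two means)."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    l: float


def _density_intersection(m1, s1, w1, m2, s2, w2) -> float | None:
    """Root of w1*N(x; m1,s1) = w2*N(x; m2,s2) between m1 and m2 (m1 < m2).

    Equating log-densities yields a quadratic in x; returns the root in
    (m1, m2), or None when no such root exists.
    """
    a = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
    b = m1 / (s1 * s1) - m2 / (s2 * s2)
    c = (m2 * m2 / (2 * s2 * s2) - m1 * m1 / (2 * s1 * s1)
         + math.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-300:  # equal variances: linear equation
        if abs(b) < 1e-300:
            return None
        x = -c / b
        return x if m1 < x < m2 else None
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (1.0, -1.0)]
    inside = [x for x in roots if m1 < x < m2]
    return inside[0] if inside else None


def fit_threshold(values: np.ndarray, seed: int = 0) -> ThresholdModel:
    """Fit a two-component normal mixture to pooled raw fluorescence
    values and place the threshold at the density intersection.

    EM via scikit-learn with quantile-based initialisation (25th/75th
    percentiles) for determinism; falls back to the midpoint of the means
    when the densities do not cross between them.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct values to fit a "
                         "bimodal threshold")
    init = np.array([[np.quantile(x, 0.25)], [np.quantile(x, 0.75)]])
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         means_init=init, random_state=seed, reg_covar=1e-6)
    gm.fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    l = _density_intersection(m1, s1, w1, m2, s2, w2)
    if l is None:
        l = 0.5 * (m1 + m2)
    return ThresholdModel(means=(float(m1), float(m2)),
                          sds=(float(s1), float(s2)),
                          weights=(float(w1), float(w2)), l=float(l))


def binarize(trace: np.ndarray, l: float) -> np.ndarray:
    """Pointwise threshold: 1 where x >= l (budded/on), else 0."""
    if not np.isfinite(l):
        raise ValueError("threshold must be finite")
    return (np.asarray(trace, dtype=float) >= l).astype(int)


# --------------------------------------------------------------------------
# transitions and the cycling-strain phase estimator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Transition:
    time: float
    kind: str  # "on_to_off" | "off_to_on"


@dataclass
class BinaryTraceSet:
    """Binary traces plus each cell's accepted transitions."""

    times: np.ndarray
    values: np.ndarray  # (n_samples, n_cells), -1 where undefined
    transitions: list[list[Transition]]
    threshold: ThresholdModel | None = None


def detect_transitions(times: np.ndarray, binary: np.ndarray,
                       min_gap: float = 14.0) -> list[Transition]:
    """Edges of a binary trace, deglitched with a refractory constraint.

    Edges are scanned in time order; an edge closer than ``min_gap``
    minutes to the previously accepted one removes *both* (the glitch and
    its partner), so the accepted kinds always alternate.
    """
    b = np.asarray(binary)
    valid = b >= 0
    t = np.asarray(times, dtype=float)[valid]
    b = b[valid]
    if not np.isin(b, (0, 1)).all():
        raise ValueError("trace must be binary")
    if b.size < 2:
        return []
    change = np.nonzero(np.diff(b) != 0)[0] + 1
    stack: list[Transition] = []
    for i in change:
        tr = Transition(time=float(t[i]),
                        kind="off_to_on" if b[i] == 1 else "on_to_off")
        if stack and tr.time - stack[-1].time < min_gap:
            stack.pop()
        else:
            stack.append(tr)
    return stack


def estimate_phase_cycling(transitions: list[Transition], t: float,
                           T0: float, theta_G1S: float) -> float | None:
    """Phase at time t from the last accepted binary transition.

    ``omega0 * elapsed`` since an on->off transition (start of the
    unbudded phase), plus ``theta_G1S`` since an off->on transition
    (start of the budded phase); clamped just below the segment's end
    boundary when the elapsed time overruns the nominal segment duration.
    Returns None when no transition precedes t.
    """
    prior = [tr for tr in transitions if tr.time <= t]
    if not prior:
        return None
    last = prior[-1]
    elapsed = t - last.time
    omega0 = TWO_PI / T0
    if last.kind == "on_to_off":
        return min(omega0 * elapsed, theta_G1S - _CLAMP)
    return min(theta_G1S + omega0 * elapsed, TWO_PI - _CLAMP)


@dataclass(frozen=True)
class NominalPeriods:
    T_G1: float
    T_SG2M: float
    T0: float
    theta_G1S: float


def estimate_nominal_periods(bts: BinaryTraceSet) -> NominalPeriods:
    """Median unbudded/budded interval durations across all binary traces
    and the derived nominal period and G1/S phase.

    ``T_G1`` is the median gap from an on->off transition to the next
    off->on; ``T_SG2M`` the median of the converse gaps;
    ``T0 = T_G1 + T_SG2M`` and ``theta_G1S = 2*pi * T_G1 / T0``.
    """
    unbudded, budded = [], []
    for trs in bts.transitions:
        for a, b in zip(trs[:-1], trs[1:]):
            gap = b.time - a.time
            if a.kind == "on_to_off":
                unbudded.append(gap)
            else:
                budded.append(gap)
    if not unbudded or not budded:
        raise ValueError("no complete unbudded and budded intervals found")
    t_g1 = float(np.median(unbudded))
    t_sgm = float(np.median(budded))
    t0 = t_g1 + t_sgm
    return NominalPeriods(T_G1=t_g1, T_SG2M=t_sgm, T0=t0,
                          theta_G1S=TWO_PI * t_g1 / t0)


def budding_index(budded_or_phases: np.ndarray,
                  theta_G1S: float | None = None) -> float:
    """Percentage of budded cells: N_budded / N * 100.

    Accepts either boolean budded flags or phases (then a cell is budded
    when theta >= theta_G1S).
    """
    x = np.asarray(budded_or_phases)
    if x.size == 0:
        raise ValueError("budding index undefined for an empty population")
    if x.dtype == bool:
        budded = x
    else:
        if theta_G1S is None:
            raise ValueError("theta_G1S required when passing phases")
        budded = x >= theta_G1S
    return float(budded.mean() * 100.0)


# --------------------------------------------------------------------------
# trace-set pipelines
# --------------------------------------------------------------------------


@dataclass
class PhaseEstimateSet:
    """Per-cell per-sample phase estimates with validity flags.

    ``theta_hat`` is (n_samples, n_cells), NaN where invalid; ``meta``
    holds per-cell estimator diagnostics (Pearson r, elapsed T_t, ...).
    """

    times: np.ndarray
    theta_hat: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def phases_at(self, i: int) -> np.ndarray:
        """Valid phase estimates at sample index i."""
        return self.theta_hat[i][self.valid[i]]

    def to_frame(self):
        import pandas as pd
        S, N = self.theta_hat.shape
        t_idx, c_idx = np.meshgrid(np.arange(S), np.arange(N), indexing="ij")
        return pd.DataFrame({
            "cell_id": c_idx.ravel(),
            "time_min": self.times[t_idx.ravel()],
            "theta_hat_rad": self.theta_hat.ravel(),
            "valid": self.valid.ravel().astype(int),
        })


def estimate_phases_noncycling(traces: TraceSet,
                               p: ReferenceSignalParams | None = None
                               ) -> PhaseEstimateSet:
    """Run the cross-correlation estimator on every cell and sample time
    with at least T_flat minutes of history.

    Flat (arrested) windows inherit the cell's last valid estimate, or
    phase 0 when none exists yet (the cell is taken as G1-arrested).
    """
    if p is None:
        p = ReferenceSignalParams(dt=traces.sample_interval)
    n_win = p.window_len
    S, N = traces.values.shape
    theta_hat = np.full((S, N), np.nan)
    valid = np.zeros((S, N), dtype=bool)
    r_best = np.full((S, N), np.nan)
    taus, refs = _reference_windows(p)
    rc = refs - refs.mean(axis=1, keepdims=True)
    rnorm = np.sqrt((rc * rc).sum(axis=1))
    for c in range(N):
        v = traces.values[:, c]
        born = ~np.isnan(v)
        last = 0.0
        has_last = False
        for i in range(S):
            if not born[i] or i + 1 < n_win:
                continue
            w = v[i + 1 - n_win:i + 1]
            if np.isnan(w).any():
                continue
            wc = w - w.mean()
            scale = max(np.abs(w).max(), 1.0)
            if float(wc @ wc) <= _FLAT_TOL * scale * scale * w.size:
                theta_hat[i, c] = last if has_last else 0.0
                valid[i, c] = True
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (rc @ wc) / (rnorm * math.sqrt(float(wc @ wc)))
            r = np.where(np.isfinite(r), r, -np.inf)
            best = int(np.argmax(r))
            th = np.mod((TWO_PI / p.T0) * (taus[best] - p.T_flat)
                        + math.pi / 2.0, TWO_PI)
            theta_hat[i, c] = th
            valid[i, c] = True
            r_best[i, c] = r[best]
            last, has_last = th, True
    return PhaseEstimateSet(times=traces.times.copy(), theta_hat=theta_hat,
                            valid=valid, meta={"r": r_best, "params": p})


def binarize_traces(traces: TraceSet, *, threshold: ThresholdModel | None = None,
                    threshold_window: float = 100.0, min_gap: float = 14.0,
                    seed: int = 0) -> BinaryTraceSet:
    """Smooth, threshold and deglitch every trace.

    Unless a threshold is supplied, it is fitted on the pooled *raw*
    values of the trailing ``threshold_window`` minutes of all traces.
    """
    S, N = traces.values.shape
    if threshold is None:
        t_lo = traces.times[-1] - threshold_window
        pool = traces.values[traces.times >= t_lo - 1e-9]
        threshold = fit_threshold(pool[np.isfinite(pool)], seed=seed)
    binary = np.full((S, N), -1, dtype=int)
    transitions: list[list[Transition]] = []
    for c in range(N):
        v = traces.values[:, c]
        born = ~np.isnan(v)
        if born.any():
            sm = smooth(v[born])
            binary[born, c] = binarize(sm, threshold.l)
        transitions.append(detect_transitions(traces.times, binary[:, c],
                                              min_gap=min_gap))
    return BinaryTraceSet(times=traces.times.copy(), values=binary,
                          transitions=transitions, threshold=threshold)


def estimate_phases_cycling(traces: TraceSet, *,
                            T0: float | None = None,
                            theta_G1S: float | None = None,
                            threshold: ThresholdModel | None = None,
                            min_gap: float = 14.0, seed: int = 0
                            ) -> tuple[PhaseEstimateSet, BinaryTraceSet,
                                       NominalPeriods | None]:
    """Full cycling-strain pipeline: binarize, then phase per Eq.-10-style
    elapsed-time mapping.

    When ``T0``/``theta_G1S`` are omitted they are first recovered from
    the binary traces via the median-interval procedure.
    """
    bts = binarize_traces(traces, threshold=threshold, min_gap=min_gap,
                          seed=seed)
    periods = None
    if T0 is None or theta_G1S is None:
        periods = estimate_nominal_periods(bts)
        T0 = periods.T0 if T0 is None else T0
        theta_G1S = periods.theta_G1S if theta_G1S is None else theta_G1S
    S, N = traces.values.shape
    theta_hat = np.full((S, N), np.nan)
    valid = np.zeros((S, N), dtype=bool)
    for c in range(N):
        trs = bts.transitions[c]
        if not trs:
            continue
        tr_times = np.array([tr.time for tr in trs])
        tr_on_off = np.array([tr.kind == "on_to_off" for tr in trs])
        idx = np.searchsorted(tr_times, traces.times, side="right") - 1
        born = ~np.isnan(traces.values[:, c])
        omega0 = TWO_PI / T0
        for i in np.nonzero(born & (idx >= 0))[0]:
            j = idx[i]
            elapsed = traces.times[i] - tr_times[j]
            if tr_on_off[j]:
                th = min(omega0 * elapsed, theta_G1S - _CLAMP)
            else:
                th = min(theta_G1S + omega0 * elapsed, TWO_PI - _CLAMP)
            theta_hat[i, c] = th
            valid[i, c] = True
    est = PhaseEstimateSet(times=traces.times.copy(), theta_hat=theta_hat,
                           valid=valid,
                           meta={"T0": T0, "theta_G1S": theta_G1S,
                                 "threshold": bts.threshold})
    return est, bts, periods
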