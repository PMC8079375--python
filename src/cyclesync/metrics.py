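"""Synchronisation metrics.

The headline statistic is the Kuramoto order parameter

    R(t) e^{j psi(t)} = (1/N) sum_m e^{j theta_m(t)},

whose modulus R (mean phase coherence) is 1 for a perfectly synchronised
population and 0 for a uniformly spread one, and whose argument psi is the
population mean phase.  Complementary measures: the power (dB) and period
of the leading peak of an autoregressive power-spectral-density estimate
of the population-average fluorescence signal (peaks implying periods
longer than the record are reported as not determined, N.D.), and the
Spearman rank correlation between a reference-oscillator phase and the
mean phase, ranked as wrapped angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .model import TWO_PI

__all__ = ["SyncMetrics", "kuramoto", "kuramoto_series", "time_avg_R",
           "psd_leading_peak", "tracking_rho", "radius_from_volume",
           "desync_budding_baseline", "ar_modified_covariance"]


@dataclass
class SyncMetrics:
    """Bundle of population synchronisation summaries.

    ``power_db``/``period_min`` are None when the PSD peak is N.D.;
    ``rho`` is None when no reference oscillator was involved.
    """

    R: np.ndarray
    psi: np.ndarray
    times: np.ndarray
    R_bar: float
    power_db: float | None = None
    period_min: float | None = None
    rho: float | None = None
    mean_radius_bar: float | None = None
    mean_volume_bar: float | None = None

    def to_dict(self) -> dict:
        return {"R_bar": self.R_bar, "power_db": self.power_db,
                "period_min": self.period_min, "rho": self.rho,
                "mean_radius_bar": self.mean_radius_bar,
                "mean_volume_bar": self.mean_volume_bar}


def kuramoto(phases: np.ndarray) -> tuple[float, float]:
    """Mean phase coherence R and mean phase psi (in [0, 2*pi)) of a set
    of phases."""
    th = np.asarray(phases, dtype=float)
    if th.size == 0:
        raise ValueError("kuramoto order parameter undefined for an empty "
                         "population")
    if not np.isfinite(th).all():
        raise ValueError("phases must be finite")
    z = np.exp(1j * th).mean()
    return float(abs(z)), float(np.mod(np.angle(z), TWO_PI))


def kuramoto_series(phase_lists) -> tuple[np.ndarray, np.ndarray]:
    """R(t) and psi(t) for a sequence of per-sample phase collections."""
    R = np.empty(len(phase_lists))
    psi = np.empty(len(phase_lists))
    for i, ph in enumerate(phase_lists):
        R[i], psi[i] = kuramoto(ph)
    return R, psi


def time_avg_R(R: np.ndarray, times: np.ndarray,
               window: tuple[float, float] | None = None) -> float:
    """Arithmetic mean of the coherence series over a time window
    (inclusive endpoints; default: the whole series)."""
    R = np.asarray(R, dtype=float)
    t = np.asarray(times, dtype=float)
    if window is not None:
        m = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    else:
        m = np.ones_like(t, dtype=bool)
    if not m.any():
        raise ValueError("empty averaging window")
    return float(R[m].mean())


def ar_modified_covariance(x: np.ndarray, order: int
                           ) -> tuple[np.ndarray, float]:
    """AR(p) coefficients by the modified covariance (forward-backward
    least squares) method.

    Minimises the summed forward and backward prediction error powers;
    returns (a, sigma2) with the AR polynomial A(z) = 1 + sum a_k z^-k.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    p = int(order)
    if n <= 2 * p:
        raise ValueError("series too short for the requested AR order")
    # forward rows: x[t] ~ -sum a_k x[t-k],  t = p..n-1
    idx = np.arange(p)[None, :]
    tf = np.arange(p, n)[:, None]
    Ff = x[tf - 1 - idx]
    yf = x[p:]
    # backward rows: x[t] ~ -sum a_k x[t+k], t = 0..n-1-p
    tb = np.arange(0, n - p)[:, None]
    Fb = x[tb + 1 + idx]
    yb = x[:n - p]
    F = np.vstack((Ff, Fb))
    y = np.concatenate((yf, yb))
    a, *_ = np.linalg.lstsq(F, -y, rcond=None)
    resid = y + F @ a
    sigma2 = float(resid @ resid) / y.size
    return a, sigma2


def psd_leading_peak(signal: np.ndarray, dt: float, ar_order: int = 20,
                     n_freq: int = 4096) -> tuple[float, float] | None:
    """Power (dB) and period (min) of the leading peak of a parametric
    PSD of the mean-subtracted signal.

    The PSD is evaluated from a modified-covariance AR fit on a dense
    one-sided frequency grid; the peak is the global maximum over
    positive frequencies.  Returns None (N.D.) for a degenerate signal or
    when the peak period exceeds the record duration.  The dB reference
    is 1 a.u.^2 per unit frequency.
    """
    x = np.asarray(signal, dtype=float)
    x = x[np.isfinite(x)]
    if x.size <= max(2 * ar_order, 3):
        return None
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return None
    a, sigma2 = ar_modified_covariance(x, ar_order)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    f = np.linspace(0.0, 0.5 / dt, n_freq + 1)[1:]  # exclude DC
    k = np.arange(1, a.size + 1)
    A = 1.0 + np.exp(-2j * math.pi * np.outer(f * dt, k)) @ a
    psd = sigma2 * dt / np.abs(A) ** 2
    peak = int(np.argmax(psd))
    period = 1.0 / f[peak]
    duration = (x.size - 1) * dt
    if period > duration:
        return None
    return float(10.0 * np.log10(psd[peak])), float(period)


def tracking_rho(theta_r: np.ndarray, psi: np.ndarray) -> float:
    """Spearman rank correlation between reference and mean phase.

    Both series are ranked as wrapped angles in [0, 2*pi): two phase
    series that track each other produce aligned sawtooths and rho near
    1, while any two *unwrapped* increasing phase series would correlate
    near 1 trivially, making the statistic uninformative.  Raises on
    constant series.
    """
    a = np.mod(np.asarray(theta_r, dtype=float), TWO_PI)
    b = np.mod(np.asarray(psi, dtype=float), TWO_PI)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length paired series of >= 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("tracking correlation undefined for a constant "
                         "series")
    rho = spearmanr(a, b).statistic
    return float(rho)


def radius_from_volume(V: np.ndarray | float) -> np.ndarray | float:
    """Sphere-equivalent radius (3V / 4*pi)^(1/3)."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volume must be positive")
    out = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def desync_budding_baseline(theta_G1S: float) -> float:
    """Expected budding index (%) of a totally desynchronised population:
    the fraction of the circle beyond the G1/S phase."""
    if not 0.0 < theta_G1S < TWO_PI:
        raise ValueError("theta_G1S must lie in (0, 2*pi)")
    return float((1.0 - theta_G1S / TWO_PI) * 100.0)
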