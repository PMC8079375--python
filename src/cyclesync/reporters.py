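"""Synthetic fluorescence reporters.

Turns simulated phase trajectories into per-cell fluorescence time series
so the estimation pipeline can be exercised and round-trip-tested without
microscopy data.  Two reporter kinds mirror the strains' readouts:

* ``cln2`` — a raised-cosine waveform of the phase, chosen to be exactly
  self-consistent with the cross-correlation estimator's periodic
  reference signal (a cell cycling at the nominal rate reproduces the
  reference's cosine segment).
* ``cdc10`` — a two-level on/off signal: the septin reporter is detected
  only while the cell is budded (theta >= theta_G1S), matching the
  binarization model of the cycling-strain estimator.

Noise is additive white Gaussian, one independent draw per sample; no
photobleaching or autofluorescence drift is modelled.  Samples before a
cell's birth are absent (NaN), mirroring cells entering the field of view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import TWO_PI, Trajectory

__all__ = ["ReporterConfig", "TraceSet", "cln2_waveform", "cdc10_waveform",
           "make_traces"]


@dataclass(frozen=True)
class ReporterConfig:
    """Forward reporter model parameters (arbitrary fluorescence units).

    For ``cdc10`` the trace is ``on_level``/``off_level`` plus noise; the
    default noise sd (0.4) is 10% of the default level separation.  For
    ``cln2`` the trace is ``baseline + amplitude * waveform`` plus noise.
    """

    kind: str = "cdc10"
    baseline: float = 1.0
    amplitude: float = 10.0
    on_level: float = 5.0
    off_level: float = 1.0
    noise_sd: float = 0.4
    seed: int | None = None
    theta_G1S: float = 4.0 * math.pi / 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("cln2", "cdc10"):
            raise ValueError(f"unknown reporter kind {self.kind!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.on_level <= self.off_level:
            raise ValueError("on_level must exceed off_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TraceSet:
    """Per-cell fluorescence traces on a shared uniform time grid.

    ``values`` is (n_samples, n_cells), NaN before each cell's birth.
    """

    times: np.ndarray
    values: np.ndarray
    sample_interval: float

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def trace(self, cell: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to where the cell exists."""
        v = self.values[:, cell]
        m = ~np.isnan(v)
        return self.times[m], v[m]

    def mean_signal(self) -> np.ndarray:
        """Population-average fluorescence, ignoring unborn cells."""
        return np.nanmean(self.values, axis=1)

    def to_frame(self):
        import pandas as pd
        t_idx, c_idx = np.nonzero(~np.isnan(self.values))
        return pd.DataFrame({"cell_id": c_idx,
                             "time_min": self.times[t_idx],
                             "yfp_au": self.values[t_idx, c_idx]})

    @classmethod
    def from_frame(cls, df, sample_interval: float | None = None) -> "TraceSet":
        """Build from a tidy table with cell_id, time_min, yfp_au columns."""
        times = np.unique(df["time_min"].to_numpy(dtype=float))
        cells = np.unique(df["cell_id"].to_numpy())
        values = np.full((times.size, cells.size), np.nan)
        ti = np.searchsorted(times, df["time_min"].to_numpy(dtype=float))
        ci = np.searchsorted(cells, df["cell_id"].to_numpy())
        values[ti, ci] = df["yfp_au"].to_numpy(dtype=float)
        if sample_interval is None:
            sample_interval = float(np.median(np.diff(times))) if times.size > 1 else 1.0
        return cls(times=times, values=values, sample_interval=sample_interval)


def cln2_waveform(theta) -> np.ndarray | float:
    """Unit-interval CLN2 waveform 1/2 - 1/2*cos(theta - pi/2).

    A cell cycling at omega0 = 2*pi/T0 traces out exactly the cosine
    segment of the estimator's periodic reference signal; a frozen cell
    emits the constant waveform value at its frozen phase.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta >= TWO_PI)):
        raise ValueError("theta outside [0, 2*pi)")
    out = 0.5 - 0.5 * np.cos(theta - math.pi / 2.0)
    return float(out) if out.ndim == 0 else out


def cdc10_waveform(theta, cfg: ReporterConfig) -> np.ndarray | float:
    """Two-level CDC10 signal: on_level while budded, off_level in G1.

    The budded interval is closed on the left: theta == theta_G1S maps to
    on_level.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.where(theta >= cfg.theta_G1S, cfg.on_level, cfg.off_level)
    return float(out) if out.ndim == 0 else out


def make_traces(traj: Trajectory, cfg: ReporterConfig) -> TraceSet:
    """Synthesize a TraceSet from a sampled trajectory.

    Reproducible under a fixed ``cfg.seed``; noise draws are independent
    per cell and sample.
    """
    theta = traj.theta
    born = ~np.isnan(theta)
    cfg = ReporterConfig(**{**cfg.__dict__, "theta_G1S": traj.params.theta_G1S})
    values = np.full(theta.shape, np.nan)
    th = np.where(born, theta, 0.0)
    if cfg.kind == "cln2":
        clean = cfg.baseline + cfg.amplitude * (0.5 - 0.5 * np.cos(th - math.pi / 2.0))
    else:
        clean = np.where(th >= cfg.theta_G1S, cfg.on_level, cfg.off_level)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        clean = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape)
    values[born] = clean[born]
    return TraceSet(times=traj.times.copy(), values=values,
                    sample_interval=float(traj.meta.get("sample_interval", 2.0)))
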