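"""Experiment configuration and reproducible run orchestration.

A YAML config file with ``strain``, ``controller``, ``simulation``,
``reporter`` and ``output`` sections resolves to a fully specified
:class:`ExperimentConfig`; unknown keys are rejected by name.
:func:`run_experiment` executes the run and writes a tidy artifact
bundle: trajectory / trace / phase-estimate / input CSVs, a metrics JSON,
the resolved config (tagged with its own hash) and a run log.  Identical
configs produce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import StrainParams, cycling_params, non_cycling_params
from .reporters import ReporterConfig
from .control import (RefOscConfig, StopAndGoConfig, open_loop_input,
                      open_loop_sweep, run_closed_loop)

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "PRESETS",
           "preset_config", "ConfigError"]


class ConfigError(ValueError):
    """A config key is unknown, ill-typed or violates a constraint."""


_STRAIN_KEYS = {"mode", "V_c", "beta", "T", "omega_z", "theta_G1S",
                "daughter_fraction"}
_CONTROLLER_KEYS = {"strategy", "T_u", "D_minus_met", "threshold_pct",
                    "pulse_duration", "omega_r", "gamma", "theta_r0",
                    "gated_coupling", "calibration_duration",
                    "sampling_interval", "control_end"}
_SIM_KEYS = {"duration", "dt", "sample_interval", "N0", "seed", "mode",
             "initial_phases", "capacity", "T_u_values", "steady_window"}
_REPORTER_KEYS = {"kind", "baseline", "amplitude", "on_level", "off_level",
                  "noise_sd", "seed"}


@dataclass
class ExperimentConfig:
    """Resolved description of one run (or sweep)."""

    strain: dict = field(default_factory=dict)
    controller: dict = field(default_factory=lambda: {"strategy": "none"})
    simulation: dict = field(default_factory=dict)
    reporter: dict = field(default_factory=dict)
    output_dir: str = "cyclesync_out"

    def resolved(self) -> dict:
        strain = {"mode": "non_cycling"}
        strain.update(self.strain)
        sim = {"duration": 600.0, "dt": 0.1, "sample_interval": 2.0,
               "N0": 3, "seed": 0, "mode": "oracle",
               "initial_phases": "uniform", "capacity": None}
        sim.update(self.simulation)
        ctrl = {"strategy": "none"}
        ctrl.update(self.controller)
        rep = dict(self.reporter)
        return {"strain": strain, "controller": ctrl, "simulation": sim,
                "reporter": rep, "output_dir": self.output_dir}

    def strain_params(self) -> StrainParams:
        s = dict(self.strain)
        mode = s.pop("mode", "non_cycling")
        factory = non_cycling_params if mode == "non_cycling" else cycling_params
        try:
            return factory(**s)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid strain section: {exc}") from exc

    def hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config.

    An empty file resolves to all defaults (non-cycling strain, N0 = 3,
    dt = 0.1, 2-min sampling, no controller).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {"strain", "controller", "simulation", "reporter",
                   "output_dir"}
    _check_keys("top-level", raw, top_allowed)
    for sec, allowed in (("strain", _STRAIN_KEYS),
                         ("controller", _CONTROLLER_KEYS),
                         ("simulation", _SIM_KEYS),
                         ("reporter", _REPORTER_KEYS)):
        _check_keys(sec, raw.get(sec) or {}, allowed)
    cfg = ExperimentConfig(strain=raw.get("strain") or {},
                           controller=raw.get("controller")
                           or {"strategy": "none"},
                           simulation=raw.get("simulation") or {},
                           reporter=raw.get("reporter") or {},
                           output_dir=raw.get("output_dir", "cyclesync_out"))
    _validate(cfg)
    return cfg


def _validate(cfg: ExperimentConfig) -> None:
    cfg.strain_params()  # raises ConfigError on bad strain values
    ctrl = cfg.controller
    strategy = ctrl.get("strategy", "none")
    if strategy not in ("none", "open_loop", "stop_and_go", "refosc"):
        raise ConfigError(f"controller.strategy: unknown value {strategy!r}")
    for key in ("pulse_duration", "T_u", "D_minus_met", "gamma", "omega_r"):
        if key in ctrl and ctrl[key] is not None and ctrl[key] <= 0:
            raise ConfigError(f"controller.{key} must be positive")
    sim = cfg.simulation
    for key in ("duration", "dt", "sample_interval"):
        if key in sim and sim[key] <= 0:
            raise ConfigError(f"simulation.{key} must be positive")
    if strategy in ("stop_and_go", "refosc"):
        calib = ctrl.get("calibration_duration",
                         30.0 if strategy == "stop_and_go" else 100.0)
        duration = sim.get("duration", 600.0)
        if duration <= calib:
            raise ConfigError("simulation.duration must exceed "
                              "controller.calibration_duration")


# --- presets matching the in-silico experiments -------------------------


PRESETS = {
    # idealised stop&go simulation (trigger threshold 100%)
    "fig3-sim": {
        "strain": {"mode": "non_cycling"},
        "controller": {"strategy": "stop_and_go", "threshold_pct": 100.0,
                       "pulse_duration": 30.0, "calibration_duration": 30.0},
        "simulation": {"duration": 530.0, "capacity": 300, "mode": "oracle"},
    },
    # reference-oscillator simulation on the cycling strain
    "fig4-sim": {
        "strain": {"mode": "cycling"},
        "controller": {"strategy": "refosc", "calibration_duration": 100.0},
        "simulation": {"duration": 600.0, "capacity": 300, "mode": "oracle"},
    },
    # open-loop forcing-period sweep on the non-cycling strain
    "period-sweep": {
        "strain": {"mode": "non_cycling"},
        "controller": {"strategy": "open_loop", "D_minus_met": 30.0},
        "simulation": {"duration": 1500.0, "capacity": 300,
                       "T_u_values": [60.0, 65.0, 70.0, 75.0, 80.0, 90.0],
                       "steady_window": 500.0},
    },
}


def preset_config(name: str) -> ExperimentConfig:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; "
                          f"available: {', '.join(sorted(PRESETS))}")
    spec = PRESETS[name]
    return ExperimentConfig(strain=dict(spec.get("strain", {})),
                            controller=dict(spec.get("controller", {})),
                            simulation=dict(spec.get("simulation", {})),
                            reporter=dict(spec.get("reporter", {})))


# --- execution ----------------------------------------------------------


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None
    return x


def run_experiment(cfg: ExperimentConfig, output_dir: str | Path | None = None
                   ) -> dict:
    """Execute a configured run and write the artifact bundle.

    Returns the metrics record; writes under ``output_dir`` (default from
    the config): trajectory.csv, traces.csv, input.csv, estimates.csv
    (estimated mode), metrics.json, resolved_config.yaml, run.log.
    """
    out = Path(output_dir or cfg.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"output path not writable: {out}") from exc

    params = cfg.strain_params()
    sim = cfg.resolved()["simulation"]
    ctrl = cfg.resolved()["controller"]
    rep = cfg.reporter
    rep_cfg = ReporterConfig(**rep) if rep else None
    strategy = ctrl["strategy"]
    common = dict(mode=sim["mode"], seed=sim["seed"], dt=sim["dt"],
                  N0=sim["N0"], initial_phases=sim["initial_phases"],
                  capacity=sim["capacity"], reporter_cfg=rep_cfg)
    tag = cfg.hash()

    if strategy == "open_loop" and "T_u_values" in cfg.simulation:
        sweep = open_loop_sweep(params, sim["T_u_values"],
                                ctrl.get("D_minus_met", 30.0),
                                sim["duration"],
                                steady_window=sim.get("steady_window", 500.0),
                                dt=sim["dt"], N0=sim["N0"],
                                capacity=sim["capacity"], seed=sim["seed"])
        records = [{"T_u": tu, "R_bar": rb, "mean_volume": mv,
                    "mean_radius": mr}
                   for tu, rb, mv, mr in zip(sweep["T_u"], sweep["R_bar"],
                                             sweep["mean_volume"],
                                             sweep["mean_radius"])]
        metrics = {"config_hash": tag, "sweep": records}
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=2, default=_jsonable))
        _write_resolved(cfg, out, tag)
        return metrics

    if strategy == "none":
        controller = open_loop_input(
            sim["duration"], 0.0, sim["duration"])  # u == 0 throughout
    elif strategy == "open_loop":
        controller = open_loop_input(ctrl.get("T_u", 75.0),
                                     ctrl.get("D_minus_met", 30.0),
                                     sim["duration"])
    elif strategy == "stop_and_go":
        common["stop_go"] = StopAndGoConfig(
            threshold_pct=ctrl.get("threshold_pct", 50.0),
            pulse_duration=ctrl.get("pulse_duration", 30.0),
            sampling_interval=ctrl.get("sampling_interval", 2.0),
            calibration_duration=ctrl.get("calibration_duration", 30.0))
        controller = "stop_and_go"
    else:
        common["ref_osc"] = RefOscConfig(
            omega_r=ctrl.get("omega_r", 2 * math.pi / 105.0),
            gamma=ctrl.get("gamma", 1.0),
            theta_r0=ctrl.get("theta_r0", 0.0),
            sampling_interval=ctrl.get("sampling_interval", 2.0),
            calibration_duration=ctrl.get("calibration_duration", 100.0),
            gated_coupling=ctrl.get("gated_coupling", False))
        controller = "refosc"
    if ctrl.get("control_end") is not None:
        common["control_end"] = ctrl["control_end"]

    res = run_closed_loop(params, controller, sim["duration"], **common)
    res.trajectory.to_frame().to_csv(out / "trajectory.csv", index=False)
    res.input.to_frame().to_csv(out / "input.csv", index=False)
    if res.traces is not None:
        res.traces.to_frame().to_csv(out / "traces.csv", index=False)
    metrics = {"config_hash": tag, **res.metrics.to_dict(),
               "n_cells_final": int(res.trajectory.n_cells),
               "estimates_valid_frac": res.estimates_valid_frac}
    (out / "metrics.json").write_text(
        json.dumps(metrics, indent=2, default=_jsonable))
    _write_resolved(cfg, out, tag)
    return metrics


def _write_resolved(cfg: ExperimentConfig, out: Path, tag: str) -> None:
    resolved = cfg.resolved()
    resolved["config_hash"] = tag
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True))
    (out / "run.log").write_text(
        f"cyclesync run\nconfig_hash: {tag}\n"
        f"seed: {resolved['simulation']['seed']}\n")
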