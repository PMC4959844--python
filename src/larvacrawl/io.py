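"""Configuration files, experiment runners and result writers.

Config schema (YAML, all sections optional; unknown keys are a hard error):

.. code-block:: yaml

    # flat model-parameter overrides, keys named as Params fields
    w_Ep: 0.0
    w_Ip: 0.0
    protocol:
      pulse: {unit: 10, height: 0.61, start: 0.0, duration: 10.0}
      clamps:
        - {population: E, unit: 8, t0: 65.0, t1: 95.0, value: 0.0}
      overrides: {w_En: 0.6}
      duration: 500.0
      dt_sample: 0.1
    integrator: {method: LSODA, rtol: 1.0e-6, atol: 1.0e-9}

Unspecified keys take the documented defaults (default parameter set and
the baseline protocol).  ``run_experiment`` executes a named preset and
writes the trajectory table, metrics JSON/CSV, a kymograph table and a JSON
run manifest that fully reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import Params, default_params
from .simulation import (FRICTION_GRID, PRESETS, WEN_GRID, Clamp,
                         IntegratorConfig, Protocol, Pulse, SweepPoint,
                         Trajectory, preset_protocol, simulate, sweep)
from .metrics import compute_metrics

log = logging.getLogger("larvacrawl")

_PARAM_KEYS = {f.name for f in dataclasses.fields(Params)}
_PROTOCOL_KEYS = {"pulse", "clamps", "overrides", "duration", "dt_sample"}
_PULSE_KEYS = {"unit", "height", "start", "duration"}
_CLAMP_KEYS = {"population", "unit", "t0", "t1", "value"}
_INTEGRATOR_KEYS = {"method", "rtol", "atol"}


class ConfigError(ValueError):
    """Malformed or unknown configuration content, with the key named."""


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in {context}; allowed: {sorted(allowed)}")


def _parse_protocol(spec: dict) -> Protocol:
    _check_keys(spec, _PROTOCOL_KEYS, "protocol section")
    kwargs = {}
    if "pulse" in spec:
        _check_keys(spec["pulse"], _PULSE_KEYS, "protocol.pulse")
        kwargs["pulse"] = Pulse(**spec["pulse"])
    if "clamps" in spec:
        clamps = []
        for n, cl in enumerate(spec["clamps"]):
            _check_keys(cl, _CLAMP_KEYS, f"protocol.clamps[{n}]")
            clamps.append(Clamp(**cl))
        kwargs["clamps"] = tuple(clamps)
    if "overrides" in spec:
        _check_keys(spec["overrides"], _PARAM_KEYS, "protocol.overrides")
        kwargs["overrides"] = dict(spec["overrides"])
    for key in ("duration", "dt_sample"):
        if key in spec:
            kwargs[key] = float(spec[key])
    return Protocol(**kwargs)


def load_config(path) -> tuple[Params, Protocol, IntegratorConfig]:
    """Read a YAML config; missing keys take defaults, unknown keys error."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a key-value mapping")

    _check_keys(raw, _PARAM_KEYS | {"protocol", "integrator"}, "config")
    param_over = {k: v for k, v in raw.items()
                  if k not in ("protocol", "integrator")}
    try:
        params = default_params().with_overrides(**param_over)
    except (ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc

    protocol = (_parse_protocol(raw["protocol"]) if "protocol" in raw
                else preset_protocol("fig2_baseline"))
    if "integrator" in raw:
        _check_keys(raw["integrator"], _INTEGRATOR_KEYS, "integrator section")
        integrator = IntegratorConfig(**raw["integrator"])
    else:
        integrator = IntegratorConfig()
    return params, protocol, integrator


def save_config(path, params: Params, protocol: Protocol,
                integrator: IntegratorConfig | None = None) -> None:
    """Write a config that round-trips through :func:`load_config`."""
    doc: dict = dict(params.to_dict())
    doc["protocol"] = protocol.to_dict()
    doc["integrator"] = (integrator or IntegratorConfig()).to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# writers

def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def write_trajectory_hdf5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        for name in ("t", "E", "I", "f", "x", "v"):
            h5.create_dataset(name, data=getattr(traj, name))
        h5.attrs["dt_sample"] = traj.protocol.dt_sample


def read_trajectory_csv(path, params: Params | None = None,
                        protocol: Protocol | None = None) -> Trajectory:
    """Rebuild a Trajectory from the 53-column table (or any same-schema table)."""
    from .simulation import DEFAULT_V_MOVE

    df = pd.read_csv(path)
    params = params or default_params()
    protocol = protocol or Protocol(duration=float(df["t"].iloc[-1]),
                                    dt_sample=float(df["t"].iloc[1] - df["t"].iloc[0]))
    E = df[[f"E{i}" for i in range(1, 11)]].to_numpy()
    I = df[[f"I{i}" for i in range(1, 11)]].to_numpy()
    f = df[[f"f{i}" for i in range(1, 11)]].to_numpy()
    x = df[[f"x{j}" for j in range(11)]].to_numpy()
    v = df[[f"v{j}" for j in range(11)]].to_numpy()
    return Trajectory(t=df["t"].to_numpy(), E=E, I=I, f=f, x=x, v=v,
                      off_ground=f > params.f_hat,
                      moving=np.abs(v) > DEFAULT_V_MOVE,
                      params=params, protocol=protocol)


def export_kymograph(traj: Trajectory, path) -> pd.DataFrame:
    """Tidy (time, mass, position) table for kymograph plotting.

    Positions are in units of L and times in tau_E, directly comparable to
    published kymographs of body-segment motion.
    """
    if traj.n_samples == 0:
        raise ValueError("cannot export a kymograph of an empty trajectory")
    n_m = traj.x.shape[1]
    df = pd.DataFrame({
        "time": np.repeat(traj.t, n_m),
        "mass": np.tile(np.arange(n_m), traj.n_samples),
        "position": traj.x.reshape(-1),
    })
    df.to_csv(path, index=False)
    return df


def metrics_to_csv(metrics, path) -> None:
    """One-row CSV of the scalar gait metrics."""
    d = metrics.to_dict()
    d.pop("wave_times", None)
    d.pop("phases", None)
    pd.DataFrame([d]).to_csv(path, index=False)


def sweep_to_long_csv(results: dict[str, list[SweepPoint]],
                      parameter_name: str, path) -> pd.DataFrame:
    """Long-format table: one row per (parameter value, variant, metric)."""
    rows = []
    for variant, points in results.items():
        for pt in points:
            if pt.error is not None:
                rows.append({"parameter": parameter_name, "value": pt.value,
                             "variant": variant, "metric": "error",
                             "metric_value": np.nan, "note": pt.error})
                continue
            md = pt.metrics.to_dict()
            md.pop("wave_times", None)
            md.pop("phases", None)
            for name, val in md.items():
                rows.append({"parameter": parameter_name, "value": pt.value,
                             "variant": variant, "metric": name,
                             "metric_value": val, "note": ""})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# experiment driver

@dataclass
class RunManifest:
    """Everything needed to reproduce one run bitwise."""

    preset: str
    params: dict
    protocol: dict
    integrator: dict
    code_version: str
    started_utc: str
    outputs: list = field(default_factory=list)
    complete: bool = False

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)


def run_experiment(preset_name: str, out_dir,
                   params: Params | None = None,
                   integrator: IntegratorConfig | None = None) -> RunManifest:
    """Execute a preset end to end and write all result files.

    Single-run presets produce ``trajectory.csv`` (53 columns),
    ``metrics.json``/``metrics.csv`` and ``kymograph.csv``; the sweep
    presets produce a long-format ``sweep.csv``.  A ``manifest.json`` is
    written in both cases; partially written outputs leave
    ``complete: false`` in the manifest.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; valid presets: {PRESETS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or default_params()
    integrator = integrator or IntegratorConfig()
    protocol = preset_protocol(preset_name)
    manifest = RunManifest(
        preset=preset_name,
        params=params.to_dict(),
        protocol=protocol.to_dict(),
        integrator=integrator.to_dict(),
        code_version=__version__,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    log.info("preset %s -> %s", preset_name, out)

    def metric_fn(traj, p):
        return compute_metrics(traj, p)

    if preset_name == "fig5_wEn_sweep":
        results = {
            "full": sweep(params, protocol, "w_En", WEN_GRID,
                          integrator=integrator, metric_fn=metric_fn,
                          keep_trajectories=False),
            "no_proprio": sweep(params.with_overrides(w_Ep=0.0, w_Ip=0.0),
                                protocol, "w_En", WEN_GRID,
                                integrator=integrator, metric_fn=metric_fn,
                                keep_trajectories=False),
        }
        sweep_to_long_csv(results, "w_En", out / "sweep.csv")
        manifest.outputs = ["sweep.csv"]
    elif preset_name == "fig6_friction_sweep":
        results = {"full": sweep(params, protocol, "F_max", FRICTION_GRID,
                                 integrator=integrator, metric_fn=metric_fn,
                                 keep_trajectories=False)}
        sweep_to_long_csv(results, "F_max", out / "sweep.csv")
        manifest.outputs = ["sweep.csv"]
    else:
        traj = simulate(params, protocol, integrator=integrator)
        metrics = compute_metrics(traj)
        write_trajectory_csv(traj, out / "trajectory.csv")
        metrics.to_json(out / "metrics.json")
        metrics_to_csv(metrics, out / "metrics.csv")
        export_kymograph(traj, out / "kymograph.csv")
        manifest.outputs = ["trajectory.csv", "metrics.json", "metrics.csv",
                            "kymograph.csv"]
        log.info("waves=%d freq=%.4f speed=%.4f", len(metrics.wave_times),
                 metrics.wave_freq, metrics.speed)

    manifest.complete = all((out / name).exists() for name in manifest.outputs)
    manifest.write(manifest_path)
    return manifest
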