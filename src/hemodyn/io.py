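"""Plain-text I/O: waveform CSV + JSON sidecar, beat tables, tidy spectra.

All artifacts are text (CSV/JSON) so that analyses are reproducible from
versionable files.  Waveforms are two-column CSV (time, pressure, flow) with a
JSON sidecar holding the sampling rate and units; beat tables carry a header
comment with column units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    BolusEventSpec,
    PhaseEpoch,
    PhaseSchedule,
    SimulationConfig,
    VarProcessSpec,
)
from .waveform import WaveformRecord

__all__ = [
    "write_waveform",
    "read_waveform",
    "write_beat_table",
    "read_beat_table",
    "write_json",
    "config_to_dict",
    "config_from_dict",
    "write_config",
    "read_config",
]

_BEAT_UNITS = (
    "# t_onset [s], duration [s], hr [beats/min], ap_mean [mmHg], "
    "systolic [mmHg], diastolic [mmHg], dpdt_max [mmHg/s], "
    "sbf_mean [mL/min], sv [mL], svr [mmHg.min/mL]\n"
)


def write_waveform(record: WaveformRecord, csv_path: str | Path) -> Path:
    """Write a waveform as CSV with a ``.json`` sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {"time": record.times, "pressure": record.pressure, "flow": record.flow}
    )
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "sampling_rate_hz": record.fs,
                "t0_s": record.t0,
                "units": {"pressure": "mmHg", "flow": "mL/min", "time": "s"},
            },
            indent=2,
        )
    )
    return csv_path


def read_waveform(csv_path: str | Path) -> WaveformRecord:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(csv_path)
    return WaveformRecord(
        fs=float(meta["sampling_rate_hz"]),
        pressure=frame["pressure"].to_numpy(),
        flow=frame["flow"].to_numpy(),
        t0=float(meta.get("t0_s", 0.0)),
    )


def write_beat_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_BEAT_UNITS)
        table.to_csv(fh, index=False, float_format="%.8g")
    return path


def read_beat_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(payload: dict, path: str | Path) -> Path:
    """Write a JSON results/provenance block (numpy types converted)."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable dictionary of a simulation configuration."""
    out = {
        "seed": config.seed,
        "fs": config.fs,
        "duration": config.duration,
        "hr": config.hr,
        "map0": config.map0,
        "sbf0": config.sbf0,
        "pulse_pressure": config.pulse_pressure,
        "noise_sd_pressure": config.noise_sd_pressure,
        "noise_sd_flow": config.noise_sd_flow,
        "systole_frac": config.systole_frac,
        "rise_frac": config.rise_frac,
        "coupling_boost": list(config.coupling_boost)
        if config.coupling_boost
        else None,
        "var_spec": None,
        "schedule": None,
        "boluses": [
            {
                "time": b.time,
                "peak_mult": b.peak_mult,
                "time_to_peak": b.time_to_peak,
                "k": b.k,
                "plateau_frac": b.plateau_frac,
                "dose": b.dose,
            }
            for b in config.boluses
        ],
    }
    if config.var_spec is not None:
        out["var_spec"] = {
            "coeffs": config.var_spec.coeffs.tolist(),
            "noise_cov": config.var_spec.noise_cov.tolist(),
            "dt": config.var_spec.dt,
        }
    if config.schedule is not None:
        out["schedule"] = [
            {
                "start": e.start,
                "end": e.end,
                "sbf_mult": e.sbf_mult,
                "svr_mult": e.svr_mult,
                "ramp": e.ramp,
            }
            for e in config.schedule.epochs
        ]
    return out


def config_from_dict(payload: dict) -> SimulationConfig:
    payload = dict(payload)
    var_spec = payload.pop("var_spec", None)
    schedule = payload.pop("schedule", None)
    boluses = payload.pop("boluses", [])
    boost = payload.pop("coupling_boost", None)
    return SimulationConfig(
        var_spec=VarProcessSpec(
            coeffs=np.asarray(var_spec["coeffs"]),
            noise_cov=np.asarray(var_spec["noise_cov"]),
            dt=float(var_spec["dt"]),
        )
        if var_spec
        else None,
        schedule=PhaseSchedule(tuple(PhaseEpoch(**e) for e in schedule))
        if schedule
        else None,
        boluses=tuple(BolusEventSpec(**b) for b in boluses),
        coupling_boost=tuple(boost) if boost else None,
        **payload,
    )


def write_config(config: SimulationConfig, path: str | Path) -> Path:
    return write_json(config_to_dict(config), path)


def read_config(path: str | Path) -> SimulationConfig:
    return config_from_dict(json.loads(Path(path).read_text()))
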