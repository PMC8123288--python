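"""Readers and writers for the package's table and config dialects.

All machine-readable files use UTF-8, decimal points, mandatory header
rows, times in days as floats and Greek symbols transliterated (xi1,
omega1, theta1, ...).  CSV outputs written by the command-line tools carry
a provenance comment header (``# key: value`` lines with package version,
seed and a config hash); readers skip ``#`` comment lines, so round trips
are lossless to full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import PatientDataset
from .model import DoseSchedule, ModelParameters

__all__ = [
    "read_params",
    "write_params",
    "read_dose_csv",
    "write_dose_csv",
    "read_patient_csv",
    "write_patient_csv",
    "write_table",
    "provenance",
]

_FLOAT_FMT = "%.17g"


def provenance(seed=None, config=None) -> dict:
    """Provenance record stamped into every output."""
    blob = json.dumps(config, sort_keys=True, default=str) if config is not None else ""
    return {
        "generator": f"hccdyn {__version__}",
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest()[:16],
    }


def _header_lines(seed, config) -> str:
    rec = provenance(seed, config)
    return "".join(f"# {k}: {v}\n" for k, v in rec.items())


def write_table(df: pd.DataFrame, path, *, seed=None, config=None,
                index: bool = False, index_label=None) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed, config))
        df.to_csv(fh, index=index, index_label=index_label,
                  float_format=_FLOAT_FMT, lineterminator="\n")


def read_params(path) -> ModelParameters:
    """Read a flat JSON parameter config (keys = transliterated symbols)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a flat JSON object of parameters")
    return ModelParameters.from_dict(doc)


def write_params(p: ModelParameters, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(p.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_dose_csv(path) -> DoseSchedule:
    """Dose history table: columns start_day, end_day, dose_mg_day.

    An empty table (header only or zero rows) means no drug at any time.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"start_day", "end_day", "dose_mg_day"}
    if len(df.columns) and not required <= set(df.columns):
        raise ValueError(
            f"{path}: dose table needs columns {sorted(required)}, "
            f"got {list(df.columns)}")
    if not len(df):
        return DoseSchedule()
    segs = df[["start_day", "end_day", "dose_mg_day"]].to_numpy(float)
    return DoseSchedule(segs)


def write_dose_csv(schedule: DoseSchedule, path, *, seed=None, config=None) -> None:
    df = pd.DataFrame(list(schedule.segments),
                      columns=["start_day", "end_day", "dose_mg_day"])
    write_table(df, path, seed=seed, config=config)


def read_patient_csv(obs_path, dose_path, c0: float, **kwargs) -> PatientDataset:
    """Observation table (time_days, afp_ng_ml, pivka_mau_ml, tvi_hu,
    ttv_cm3; blank = missing) plus a dose table."""
    obs = pd.read_csv(obs_path, comment="#", float_precision="round_trip")
    if "time_days" not in obs.columns:
        raise ValueError(f"{obs_path}: missing required column 'time_days'")
    schedule = read_dose_csv(dose_path)
    return PatientDataset.from_frame(obs, schedule, c0, **kwargs)


def write_patient_csv(dataset: PatientDataset, obs_path, dose_path=None, *,
                      seed=None, config=None) -> None:
    write_table(dataset.to_frame(), obs_path, seed=seed, config=config)
    if dose_path is not None:
        write_dose_csv(dataset.schedule, dose_path, seed=seed, config=config)
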