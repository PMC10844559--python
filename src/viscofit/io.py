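"""CSV / JSON interchange formats.

CSV columns use SI units with mandatory headers: ``time`` (s), ``stretch``
(-), ``shear`` (-), ``P`` (Pa), ``tau`` (Pa), and optionally ``f_z`` (N)
and ``torque`` (N m).  Configuration and result files are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .constitutive import MaterialParameters
from .experiment import ProtocolConfig, RheometerRecord, SampleGeometry, stress_to_force_torque
from .forward_model import LoadingProtocol, StressResponse

__all__ = [
    "SchemaError",
    "write_record_csv",
    "read_record_csv",
    "write_response_csv",
    "read_protocol_csv",
    "load_params_json",
    "load_protocol_config_json",
]

RECORD_COLUMNS = ("time", "stretch", "shear", "P", "tau")


class SchemaError(ValueError):
    """Raised when a file does not match its documented schema."""


def write_record_csv(path, record: RheometerRecord) -> None:
    df = pd.DataFrame(
        {
            "time": record.time,
            "stretch": record.stretch,
            "shear": record.shear,
            "P": record.P,
            "tau": record.tau,
            "f_z": record.f_z,
            "torque": record.torque,
        }
    )
    df.to_csv(path, index=False)


def read_record_csv(path, geometry: SampleGeometry | None = None) -> RheometerRecord:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in RECORD_COLUMNS:
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}: non-numeric/missing value in '{col}' near line {line}")
    geom = geometry or SampleGeometry()
    if "f_z" in df.columns and "torque" in df.columns:
        f_z = df["f_z"].to_numpy()
        torque = df["torque"].to_numpy()
    else:
        f_z, torque = stress_to_force_torque(df["P"].to_numpy(), df["tau"].to_numpy(), geom)
    return RheometerRecord(
        time=df["time"].to_numpy(),
        stretch=df["stretch"].to_numpy(),
        shear=df["shear"].to_numpy(),
        f_z=f_z,
        torque=torque,
        P=df["P"].to_numpy(),
        tau=df["tau"].to_numpy(),
        geometry=geom,
    )


def write_response_csv(path, protocol: LoadingProtocol, response: StressResponse) -> None:
    pd.DataFrame(
        {
            "time": protocol.time,
            "stretch": protocol.stretch,
            "shear": protocol.shear,
            "P": response.P,
            "tau": response.tau,
        }
    ).to_csv(path, index=False)


def read_protocol_csv(path) -> LoadingProtocol:
    df = pd.read_csv(path)
    for col in ("time", "stretch", "shear"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return LoadingProtocol(
        time=df["time"].to_numpy(),
        stretch=df["stretch"].to_numpy(),
        shear=df["shear"].to_numpy(),
    )


def load_params_json(path) -> MaterialParameters:
    d = json.loads(Path(path).read_text())
    try:
        return MaterialParameters(**d)
    except TypeError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def load_protocol_config_json(path) -> ProtocolConfig:
    d = json.loads(Path(path).read_text())
    try:
        return ProtocolConfig(**d)
    except TypeError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def dump_params_json(path, params: MaterialParameters) -> None:
    Path(path).write_text(json.dumps(asdict(params), indent=1))
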