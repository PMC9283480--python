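"""Delimited-text and JSON readers/writers plus run configuration.

Data files are plain CSV with a commented ``# key: value`` metadata header
so a single file round-trips both the numbers and the calibration/provenance
needed to interpret them.  Fit results are JSON records embedding the
package version, seed, estimator settings and an input digest.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .inference import CoumarinAssayData, DoseResponseSeries
from .kinetics import SwitchParameters
from .radiolysis import (
    SCAVENGER_PRESETS,
    SOURCE_PRESETS,
    RadiationSource,
    Scavenger,
    SolutionConditions,
)
from .synthetic import AssayNoiseModel
from .units import RadiochemicalYield


def _write_with_header(path: Path, df: pd.DataFrame, meta: Mapping[str, Any]) -> None:
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {json.dumps(value)}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_with_header(path: Path) -> tuple[pd.DataFrame, dict[str, Any]]:
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, Any] = {}
    lines = text.splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, raw = body.partition(":")
            try:
                meta[key.strip()] = json.loads(raw.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = raw.strip()
    df = pd.read_csv(_io.StringIO("\n".join(lines[n_header:])))
    return df, meta


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")


# --------------------------------------------------------------------------
# Dose-response series
# --------------------------------------------------------------------------

def write_dose_response(series: DoseResponseSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "dose_Gy": series.doses_Gy,
            "time_h": series.timestamps_h,
            "irradiated": series.irradiated_values,
        }
    )
    if series.control_values is not None:
        df["control"] = series.control_values
    meta = {
        "schema": "dose_response",
        "readout": series.readout,
        "a0": series.a0,
        "a_inf": series.a_inf,
        "trans0": series.trans0,
        **{f"meta.{k}": v for k, v in series.metadata.items()},
    }
    _write_with_header(Path(path), df, meta)


def read_dose_response(path: str | Path) -> DoseResponseSeries:
    path = Path(path)
    df, meta = _read_with_header(path)
    _require_columns(df, ["dose_Gy", "time_h", "irradiated"], path)
    return DoseResponseSeries(
        doses_Gy=df["dose_Gy"].to_numpy(),
        irradiated_values=df["irradiated"].to_numpy(),
        control_values=df["control"].to_numpy() if "control" in df.columns else None,
        timestamps_h=df["time_h"].to_numpy(),
        readout=meta.get("readout", "trans_fraction"),
        a0=meta.get("a0"),
        a_inf=meta.get("a_inf"),
        trans0=float(meta.get("trans0", 0.10)),
        metadata={k[5:]: v for k, v in meta.items() if k.startswith("meta.")},
    )


# --------------------------------------------------------------------------
# Relaxation time courses / generic two-column tables
# --------------------------------------------------------------------------

def write_timecourse(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None) -> None:
    _write_with_header(Path(path), df, {"schema": "relaxation", **(meta or {})})


def read_timecourse(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df, _ = _read_with_header(path)
    _require_columns(df, ["time_h", "trans_fraction"], path)
    return df


# --------------------------------------------------------------------------
# Coumarin assay
# --------------------------------------------------------------------------

def write_coumarin_assay(assay: CoumarinAssayData, path: str | Path) -> None:
    df = pd.DataFrame(
        {"dose_Gy": assay.doses_Gy, "fluorescence_au": assay.fluorescence_au}
    )
    meta = {
        "schema": "coumarin",
        "standard_curve_slope_au_per_uM": assay.standard_curve[0],
        "standard_curve_intercept_au": assay.standard_curve[1],
        "conversion_yield": assay.conversion_yield,
        "gd_concentration_uM": assay.gd_concentration_uM,
        **{f"meta.{k}": v for k, v in assay.metadata.items()},
    }
    _write_with_header(Path(path), df, meta)


def read_coumarin_assay(path: str | Path) -> CoumarinAssayData:
    path = Path(path)
    df, meta = _read_with_header(path)
    _require_columns(df, ["dose_Gy", "fluorescence_au"], path)
    try:
        curve = (
            float(meta["standard_curve_slope_au_per_uM"]),
            float(meta["standard_curve_intercept_au"]),
        )
    except KeyError as exc:
        raise DataError(f"{path}: missing standard-curve metadata ({exc})")
    return CoumarinAssayData(
        doses_Gy=df["dose_Gy"].to_numpy(),
        fluorescence_au=df["fluorescence_au"].to_numpy(),
        standard_curve=curve,
        conversion_yield=float(meta.get("conversion_yield", 0.031)),
        gd_concentration_uM=float(meta.get("gd_concentration_uM", 0.0)),
        metadata={k[5:]: v for k, v in meta.items() if k.startswith("meta.")},
    )


# --------------------------------------------------------------------------
# Gd-enhancement tables
# --------------------------------------------------------------------------

def write_gd_table(
    table: Mapping[float, RadiochemicalYield], path: str | Path, meta: Mapping | None = None
) -> None:
    df = pd.DataFrame(
        {
            "gd_uM": list(table.keys()),
            "g_ho_umol_per_J": [v.value_umol_per_J for v in table.values()],
        }
    )
    _write_with_header(Path(path), df, {"schema": "gd_table", **(meta or {})})


def read_gd_table(path: str | Path) -> dict[float, RadiochemicalYield]:
    path = Path(path)
    df, _ = _read_with_header(path)
    _require_columns(df, ["gd_uM", "g_ho_umol_per_J"], path)
    return {
        float(row.gd_uM): RadiochemicalYield(float(row.g_ho_umol_per_J), "HO•")
        for row in df.itertuples()
    }


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serialisable description of one simulate run."""

    source: str = "GR"
    gas: str = "none"
    gd_concentration_uM: float = 0.0
    scavengers: dict[str, float] = field(default_factory=dict)  # name -> mol/L
    switch: dict[str, float] = field(default_factory=dict)
    doses_Gy: list[float] = field(default_factory=lambda: [0.0, 2.0, 3.0, 5.0, 10.0])
    lag_h: float = 0.5
    interval_h: float = 0.25
    replicates: int = 3
    total_uM: float = 50.0
    noise: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    def radiation_source(self) -> RadiationSource:
        try:
            return SOURCE_PRESETS[self.source]
        except KeyError:
            raise ConfigurationError(
                f"unknown source preset {self.source!r}; expected one of "
                f"{sorted(SOURCE_PRESETS)}"
            )

    def conditions(self) -> SolutionConditions:
        scavengers: list[Scavenger] = []
        for name, conc in self.scavengers.items():
            if name not in SCAVENGER_PRESETS:
                raise ConfigurationError(f"unknown scavenger preset {name!r}")
            scavengers.append(SCAVENGER_PRESETS[name].with_concentration(float(conc)))
        return SolutionConditions(
            gas=self.gas,
            gd_concentration_uM=self.gd_concentration_uM,
            scavengers=tuple(scavengers),
        )

    def switch_parameters(self) -> SwitchParameters:
        return SwitchParameters(**self.switch)

    def noise_model(self) -> AssayNoiseModel:
        return AssayNoiseModel(seed=self.seed, **self.noise)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text(encoding="utf-8"))

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:16]


# --------------------------------------------------------------------------
# Result records
# --------------------------------------------------------------------------

def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_result_json(
    path: str | Path,
    estimator: str,
    result: Mapping[str, Any],
    settings: Mapping[str, Any] | None = None,
    input_path: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Write a reproducible fit-result record; returns the payload."""
    payload: dict[str, Any] = {
        "package": "radioswitch",
        "version": __version__,
        "estimator": estimator,
        "result": _jsonable(result),
        "settings": _jsonable(settings or {}),
    }
    if seed is not None:
        payload["seed"] = int(seed)
    if input_path is not None:
        payload["input"] = str(input_path)
        payload["input_digest"] = file_digest(input_path)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), "utf-8")
    return payload


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, RadiochemicalYield):
        return {
            "umol_per_J": obj.value_umol_per_J,
            "per_100eV": obj.value_per_100eV,
            "species": obj.species,
        }
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
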