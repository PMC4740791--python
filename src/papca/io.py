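"""Readers, writers and run configuration.

Containers: HDF5 for RF signal sets and spectrograms (array-friendly),
CSV for feature tables (spreadsheet-friendly), YAML for configuration
(human-editable), JSON for reports (machine-readable).  Every artifact
embeds the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .calibrate import AttenuationModel, CalibrationConfig, SystemResponse
from .classify import SVMConfig
from .pcs import PCSMatrix
from .synth import AcquisitionSettings, RFFrame


class SchemaError(ValueError):
    """An artifact is missing a required field or attribute."""


class ConfigError(ValueError):
    """A configuration document fails validation."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def default_config() -> dict:
    """The shipped default configuration document."""
    with resources.files("papca").joinpath("data/default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


_REQUIRED = {
    "acquisition": {"fs_MHz", "n_samples", "n_averages", "v_s_mm_per_us", "noise_sigma"},
    "calibration": {"alpha0", "y", "path_cm", "floor_frac", "mode"},
    "analysis": {"band_MHz", "wavelengths_nm", "proxy_scale", "wavelength_tol_nm"},
    "svm": {"C", "gamma", "degree", "normalization"},
}


def validate_config(cfg: Mapping) -> dict:
    """Check a configuration document; raises :class:`ConfigError` naming
    the first missing or invalid field."""
    if not isinstance(cfg, Mapping):
        raise ConfigError("configuration must be a mapping")
    out = {
        section: dict(block) if isinstance(block, Mapping) else block
        for section, block in cfg.items()
    }
    for section, keys in _REQUIRED.items():
        if section not in out:
            raise ConfigError(f"missing configuration section '{section}'")
        for key in sorted(keys):
            if key not in out[section]:
                raise ConfigError(f"missing field '{section}.{key}'")
    acq = out["acquisition"]
    if acq["fs_MHz"] <= 2 * max(out["analysis"]["band_MHz"]):
        raise ConfigError(
            "acquisition.fs_MHz must exceed twice the analysis band upper edge"
        )
    if acq["n_averages"] < 1:
        raise ConfigError("acquisition.n_averages must be at least 1")
    if out["calibration"]["mode"] not in ("ex_vivo", "in_situ"):
        raise ConfigError("calibration.mode must be 'ex_vivo' or 'in_situ'")
    if out["svm"]["C"] <= 0 or out["svm"]["gamma"] <= 0:
        raise ConfigError("svm.C and svm.gamma must be positive")
    out["seed"] = int(cfg.get("seed", 0))
    return out


def load_config(path=None) -> dict:
    """Load and validate a YAML config, falling back to shipped defaults."""
    if path is None:
        return validate_config(default_config())
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    base = default_config()
    for section, block in user.items():
        if isinstance(block, Mapping) and section in base:
            base[section].update(block)
        else:
            base[section] = block
    return validate_config(base)


def config_hash(cfg: Mapping) -> str:
    """Short stable digest of a configuration document."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def acquisition_from_config(cfg: Mapping) -> AcquisitionSettings:
    acq = cfg["acquisition"]
    kwargs = dict(
        fs_MHz=float(acq["fs_MHz"]),
        n_samples=int(acq["n_samples"]),
        n_averages=int(acq["n_averages"]),
        v_s_mm_per_us=float(acq["v_s_mm_per_us"]),
        noise_sigma=float(acq["noise_sigma"]),
    )
    if "wavelengths_nm" in acq and acq["wavelengths_nm"] is not None:
        kwargs["wavelengths_nm"] = tuple(float(w) for w in acq["wavelengths_nm"])
    if "sensor_position_mm" in acq:
        kwargs["sensor_position_mm"] = tuple(float(v) for v in acq["sensor_position_mm"])
    return AcquisitionSettings(**kwargs)


def calibration_from_config(cfg: Mapping, response: SystemResponse | None = None) -> CalibrationConfig:
    cal = cfg["calibration"]
    return CalibrationConfig(
        attenuation=AttenuationModel(
            alpha0=float(cal["alpha0"]), y=float(cal["y"]), path_cm=float(cal["path_cm"])
        ),
        response=response,
        floor_frac=float(cal["floor_frac"]),
        mode=str(cal["mode"]),
    )


def svm_from_config(cfg: Mapping) -> SVMConfig:
    svm = cfg["svm"]
    return SVMConfig(
        C=float(svm["C"]),
        gamma=float(svm["gamma"]),
        degree=int(svm["degree"]),
        normalization=str(svm["normalization"]),
    )


# --------------------------------------------------------------------------
# RF containers
# --------------------------------------------------------------------------

_FRAME_ATTRS = ("fs_MHz", "pulse_energy_mJ", "t0_us")


def write_rf(path, frames: Sequence[RFFrame], meta: Mapping | None = None) -> None:
    """Write RF frames to HDF5: ``/frames/<λ>`` groups plus ``/meta``."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("frames")
        for frame in frames:
            g = grp.create_group(_frame_key(frame.wavelength_nm))
            g.create_dataset("samples", data=frame.samples)
            g.attrs["fs_MHz"] = frame.fs_MHz
            g.attrs["pulse_energy_mJ"] = frame.pulse_energy
            g.attrs["t0_us"] = frame.t0_us
        m = fh.create_group("meta")
        for key, value in (meta or {}).items():
            m.attrs[key] = value


def read_rf(path) -> tuple[list[RFFrame], dict]:
    """Read an RF container; raises :class:`SchemaError` naming any missing
    dataset or attribute."""
    frames = []
    with h5py.File(path, "r") as fh:
        if "frames" not in fh:
            raise SchemaError("RF container missing group 'frames'")
        for key in sorted(fh["frames"], key=float):
            g = fh["frames"][key]
            if "samples" not in g:
                raise SchemaError(f"frame '{key}' missing dataset 'samples'")
            for attr in _FRAME_ATTRS:
                if attr not in g.attrs:
                    raise SchemaError(f"frame '{key}' missing attribute '{attr}'")
            frames.append(
                RFFrame(
                    wavelength_nm=float(key),
                    pulse_energy=float(g.attrs["pulse_energy_mJ"]),
                    samples=g["samples"][...],
                    fs_MHz=float(g.attrs["fs_MHz"]),
                    t0_us=float(g.attrs["t0_us"]),
                )
            )
        meta = dict(fh["meta"].attrs) if "meta" in fh else {}
    return frames, meta


def _frame_key(wavelength_nm: float) -> str:
    key = f"{wavelength_nm:g}"
    return key


# --------------------------------------------------------------------------
# PCS containers
# --------------------------------------------------------------------------

def write_pcs(path, pcs: PCSMatrix, meta: Mapping | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("wavelength_nm", data=pcs.wavelengths_nm)
        fh.create_dataset("f_MHz", data=pcs.f_MHz)
        fh.create_dataset("power_dB", data=pcs.power_dB)
        fh.attrs["reference_dB"] = pcs.reference_dB
        fh.attrs["calibration_record"] = json.dumps(dict(pcs.calibration_record))
        for key, value in (meta or {}).items():
            fh.attrs[key] = value


def read_pcs(path) -> tuple[PCSMatrix, dict]:
    with h5py.File(path, "r") as fh:
        for name in ("wavelength_nm", "f_MHz", "power_dB"):
            if name not in fh:
                raise SchemaError(f"PCS container missing dataset '{name}'")
        record = json.loads(fh.attrs.get("calibration_record", "{}"))
        pcs = PCSMatrix(
            wavelengths_nm=fh["wavelength_nm"][...],
            f_MHz=fh["f_MHz"][...],
            power_dB=fh["power_dB"][...],
            reference_dB=float(fh.attrs.get("reference_dB", 0.0)),
            calibration_record=record,
        )
        meta = {
            k: v for k, v in fh.attrs.items() if k not in ("reference_dB", "calibration_record")
        }
    return pcs, meta


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

FEATURE_SCHEMA = (
    "specimen_id", "condition",
    "slope700", "slope1220", "slope1370", "mid700", "mid1220", "mid1370",
)


def write_features(path, table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_SCHEMA if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing column '{missing[0]}'")
    table.loc[:, list(FEATURE_SCHEMA)].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_SCHEMA if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing column '{missing[0]}'")
    return table


def worked_example_predictions() -> pd.DataFrame:
    """The bundled worked-example cross-validation prediction table.

    One row per test specimen (4 per condition, conditions coded 1 = normal,
    2 = steatosis, 3 = fibrosis) and one column per (cycle, feature-set)
    combination holding the predicted condition code.
    """
    with resources.files("papca").joinpath("data/cv_worked_example.csv").open() as fh:
        return pd.read_csv(fh)


def worked_example_cycles(table: pd.DataFrame | None = None):
    """Reshape the worked-example table for :func:`papca.classify.accuracy_table`.

    Returns ``(per_cycle_predictions, truths)``.
    """
    table = worked_example_predictions() if table is None else table
    truths = table["truth"].to_numpy()
    preds = {
        name: [
            table[f"cycle{k}_{name}"].to_numpy() for k in (1, 2, 3)
        ]
        for name in ("slope", "mid", "both")
    }
    return preds, truths
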