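"""File formats: JSON geometry/results, HDF5 time series, YAML configs.

Conventions: SI units with unit suffixes in key names (``position_m``,
``sample_rate_hz``, ``noise_density_fT_sqrtHz``); every format carries a
``schema_version`` and readers reject newer major versions; round-trips are
lossless to float64 precision.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np
import yaml

from .arrays import SensorArray, SensorSlot, TrueChannel
from .calibration import ArrayCalibrationResults
from .errors import ParseError
from .phantom import PhantomModel, PhantomQAReport, RigidTransform
from .timeseries import TimeSeries

SCHEMA_VERSION = 1


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ParseError(f"missing required field: {path}.{key}" if path else
                         f"missing required field: {key}")
    return mapping[key]


def _check_version(doc: dict, path: str = ""):
    version = _require(doc, "schema_version", path)
    if int(version) > SCHEMA_VERSION:
        raise ParseError(
            f"schema_version {version} is newer than supported ({SCHEMA_VERSION})"
        )


# ---------------------------------------------------------------------------
# sensor arrays

def write_array(array: SensorArray, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "frame": array.frame_label,
        "slots": [
            {
                "id": s.slot_id,
                "position_m": s.cell_position.tolist(),
                "casing_axes": s.casing_axes.tolist(),
            }
            for s in array.slots
        ],
        "channels": [
            {
                "sensor_id": c.sensor_id,
                "axis": c.axis_label,
                "orientation": c.true_orientation.tolist(),
                "gain": c.true_gain,
                "noise_density_fT_sqrtHz": c.noise_density,
            }
            for c in array.channels
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_array(path) -> SensorArray:
    with open(path) as fh:
        doc = json.load(fh)
    _check_version(doc)
    frame = _require(doc, "frame", "")
    slots = []
    for i, s in enumerate(_require(doc, "slots", "")):
        slots.append(
            SensorSlot(
                slot_id=int(_require(s, "id", f"slots[{i}]")),
                cell_position=np.array(_require(s, "position_m", f"slots[{i}]"), dtype=float),
                casing_axes=np.array(_require(s, "casing_axes", f"slots[{i}]"), dtype=float),
            )
        )
    channels = []
    for i, c in enumerate(_require(doc, "channels", "")):
        channels.append(
            TrueChannel(
                sensor_id=int(_require(c, "sensor_id", f"channels[{i}]")),
                axis_label=_require(c, "axis", f"channels[{i}]"),
                true_orientation=np.array(_require(c, "orientation", f"channels[{i}]"), dtype=float),
                true_gain=float(_require(c, "gain", f"channels[{i}]")),
                noise_density=float(_require(c, "noise_density_fT_sqrtHz", f"channels[{i}]")),
            )
        )
    return SensorArray(slots=slots, channels=channels, frame_label=frame)


# ---------------------------------------------------------------------------
# time series (HDF5)

def write_timeseries(ts: TimeSeries, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.create_dataset("data", data=ts.data)
        fh.create_dataset("sample_rate_hz", data=float(ts.sample_rate))
        if ts.channel_ids is not None:
            fh.create_dataset("channel_ids",
                              data=np.array(ts.channel_ids, dtype="S32"))
        names = np.array([e[0] for e in ts.events], dtype="S64")
        samples = np.array([e[1] for e in ts.events], dtype=np.int64)
        fh.create_dataset("events/names", data=names)
        fh.create_dataset("events/samples", data=samples)


def read_timeseries(path) -> TimeSeries:
    with h5py.File(path, "r") as fh:
        if int(fh.attrs.get("schema_version", 1)) > SCHEMA_VERSION:
            raise ParseError("time-series schema_version newer than supported")
        for key in ("data", "sample_rate_hz"):
            if key not in fh:
                raise ParseError(f"missing required dataset: /{key}")
        data = fh["data"][()]
        rate = float(fh["sample_rate_hz"][()])
        ids = ([s.decode() for s in fh["channel_ids"][()]]
               if "channel_ids" in fh else None)
        events = []
        if "events/names" in fh:
            names = [s.decode() for s in fh["events/names"][()]]
            samples = fh["events/samples"][()]
            events = [(n, int(s)) for n, s in zip(names, samples)]
    return TimeSeries(data=data, sample_rate=rate, channel_ids=ids, events=events)


# ---------------------------------------------------------------------------
# calibration results

def write_calibration(results: ArrayCalibrationResults, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "window_start_s": results.window[0],
        "window_length_s": results.window[1],
        "channels": [
            {
                "sensor_id": int(results.model.sensor_ids[i]),
                "orientation": results.orientations[i].tolist(),
                "gain": float(results.gains[i]),
                "position_m": results.positions[i].tolist(),
                "residual_T": float(results.residuals[i]),
                "ok": bool(results.ok[i]),
            }
            for i in range(results.n_channels)
        ],
        "sensors": [
            {"sensor_id": sid, "position_m": pos.tolist()}
            for sid, pos in sorted(results.sensor_positions.items())
        ],
        "flagged": {str(k): v for k, v in results.flagged.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_calibration_geometry(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a calibration JSON back as (positions, orientations, gains)."""
    with open(path) as fh:
        doc = json.load(fh)
    _check_version(doc)
    chans = _require(doc, "channels", "")
    pos = np.array([_require(c, "position_m", f"channels[{i}]") for i, c in enumerate(chans)])
    ori = np.array([_require(c, "orientation", f"channels[{i}]") for i, c in enumerate(chans)])
    gains = np.array([_require(c, "gain", f"channels[{i}]") for i, c in enumerate(chans)])
    return pos, ori, gains


# ---------------------------------------------------------------------------
# phantom definitions and QA reports

def write_phantom(phantom: PhantomModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "positions_pcb_m": phantom.positions_pcb.tolist(),
        "moment_per_volt_Am2": phantom.moment_per_volt,
        "series_resistance_ohm": phantom.series_resistance,
        "pose": {
            "rotation": phantom.pose.rotation.tolist(),
            "translation_m": phantom.pose.translation.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_phantom(path) -> PhantomModel:
    with open(path) as fh:
        doc = json.load(fh)
    _check_version(doc)
    pose = _require(doc, "pose", "")
    return PhantomModel(
        positions_pcb=np.array(_require(doc, "positions_pcb_m", ""), dtype=float),
        moment_per_volt=float(_require(doc, "moment_per_volt_Am2", "")),
        series_resistance=float(_require(doc, "series_resistance_ohm", "")),
        pose=RigidTransform(
            rotation=np.array(_require(pose, "rotation", "pose"), dtype=float),
            translation=np.array(_require(pose, "translation_m", "pose"), dtype=float),
        ),
    )


def write_qa_report(report: PhantomQAReport, json_path, tsv_path=None) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "variant": report.variant,
        "n_localisations_per_dipole": int(report.fitted_positions.shape[1]),
        "mean_positions_m": report.mean_positions.tolist(),
        "error_matrix_mm": report.error_matrix.tolist(),
        "pair_errors_mm": report.pair_errors.tolist(),
        "mean_pair_error_mm": report.mean_pair_error_mm,
        "mean_correlation": report.mean_correlation,
        "per_dipole_mean_correlation": report.correlations.mean(axis=1).tolist(),
        "n_failed_fits": report.n_failed,
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if tsv_path is not None:
        np.savetxt(tsv_path, report.error_matrix, delimiter="\t", fmt="%.6f",
                   header="relative distance error matrix (mm)")


# ---------------------------------------------------------------------------
# configs and run manifests

def load_config(path, allowed_keys: set[str]) -> dict:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParseError("config root must be a mapping")
    unknown = set(doc) - set(allowed_keys)
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return doc


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, command: str, seed: int | None, config: dict) -> None:
    from . import __version__

    doc = {
        "schema_version": SCHEMA_VERSION,
        "command": command,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "opmcal_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
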