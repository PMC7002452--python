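"""Readers and writers for all on-disk artifacts.

Formats: HDF5 for movies, calibration sets and ground truth; TSV for
stimulus protocols; CSV or 32-bit-float TIFF for per-pixel maps; YAML for
run configuration.  All writers are deterministic (fixed compression
settings, ``track_times=False``, no embedded wall clock), so the same
object always produces a byte-identical file.  Readers validate container
invariants and raise :class:`~phimage.types.FormatError` instead of
silently repairing.

HDF5 movie layout: ``/frames`` (n_frames, n_rows, n_cols) float32 chunked
by frame and gzip-compressed, ``/timestamps`` float64, geometry and
condition as root attributes, ``/metadata`` a YAML string.
"""

from __future__ import annotations

import os
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    CalibrationSet,
    FormatError,
    GroundTruth,
    InvalidParameterError,
    Kinetics,
    Recording,
    SensorGeometry,
    StimulusProtocol,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_calibration_set",
    "read_calibration_set",
    "write_ground_truth",
    "read_ground_truth",
    "write_calibration_model",
    "read_calibration_model",
    "write_response_maps",
    "read_response_maps",
    "write_protocol",
    "read_protocol",
    "export_map",
    "import_map_csv",
    "import_map_tiff",
    "read_config",
    "write_config",
]

_H5_OPTS = dict(compression="gzip", compression_opts=4, shuffle=True, track_times=False)

_GEOMETRY_ATTRS = ("n_rows", "n_cols", "pixel_pitch_um", "frame_rate_hz")


def _write_geometry(obj, geometry: SensorGeometry) -> None:
    for name in _GEOMETRY_ATTRS:
        obj.attrs[name] = getattr(geometry, name)


def _read_geometry(obj) -> SensorGeometry:
    missing = [a for a in _GEOMETRY_ATTRS if a not in obj.attrs]
    if missing:
        raise FormatError(f"missing geometry attribute: {missing[0]}")
    return SensorGeometry(
        n_rows=int(obj.attrs["n_rows"]),
        n_cols=int(obj.attrs["n_cols"]),
        pixel_pitch_um=float(obj.attrs["pixel_pitch_um"]),
        frame_rate_hz=float(obj.attrs["frame_rate_hz"]),
    )


def write_recording(recording: Recording, path: str | os.PathLike) -> None:
    """Write a movie to the HDF5 layout; round-trips bit-exactly."""
    with h5py.File(path, "w", track_order=False) as f:
        frames = recording.frames
        if recording.units == "mV":
            frames = frames.astype(np.float32)
        chunk = (1,) + recording.geometry.shape
        f.create_dataset("frames", data=frames, chunks=chunk, **_H5_OPTS)
        f.create_dataset("timestamps", data=recording.timestamps, track_times=False)
        _write_geometry(f, recording.geometry)
        f.attrs["condition"] = recording.condition
        f.attrs["units"] = recording.units
        f.create_dataset(
            "metadata",
            data=yaml.safe_dump(recording.metadata, sort_keys=True),
            track_times=False,
        )


def read_recording(path: str | os.PathLike) -> Recording:
    with h5py.File(path, "r") as f:
        for name in ("frames", "timestamps"):
            if name not in f:
                raise FormatError(f"missing dataset: {name}")
        if "condition" not in f.attrs:
            raise FormatError("missing attribute: condition")
        geometry = _read_geometry(f)
        metadata = {}
        if "metadata" in f:
            metadata = yaml.safe_load(f["metadata"][()].decode()) or {}
        return Recording(
            frames=f["frames"][()],
            timestamps=f["timestamps"][()],
            geometry=geometry,
            condition=str(f.attrs["condition"]),
            units=str(f.attrs.get("units", "mV")),
            metadata=metadata,
        )


def write_calibration_set(calset: CalibrationSet, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("buffer_phs", data=calset.buffer_phs, track_times=False)
        f.create_dataset("voltages", data=calset.voltages, **_H5_OPTS)
        _write_geometry(f, calset.geometry)
        f.attrs["n_replicates"] = calset.n_replicates
        f.create_dataset(
            "metadata", data=yaml.safe_dump(calset.metadata, sort_keys=True), track_times=False
        )


def read_calibration_set(path: str | os.PathLike) -> CalibrationSet:
    with h5py.File(path, "r") as f:
        for name in ("buffer_phs", "voltages"):
            if name not in f:
                raise FormatError(f"missing dataset: {name}")
        metadata = {}
        if "metadata" in f:
            metadata = yaml.safe_load(f["metadata"][()].decode()) or {}
        return CalibrationSet(
            buffer_phs=f["buffer_phs"][()],
            voltages=f["voltages"][()],
            geometry=_read_geometry(f),
            n_replicates=int(f.attrs.get("n_replicates", 1)),
            metadata=metadata,
        )


def write_ground_truth(truth: GroundTruth, path: str | os.PathLike) -> None:
    """Sidecar HDF5 with the simulator's generating parameters."""
    with h5py.File(path, "w") as f:
        g = f.create_group("truth")
        for name in (
            "sensitivity_map",
            "offset_map",
            "stuck_voltage_mv",
            "response_field",
            "angles_deg",
        ):
            g.create_dataset(name, data=getattr(truth, name), **_H5_OPTS)
        g.create_dataset("defective_mask", data=truth.defective_mask, **_H5_OPTS)
        _write_geometry(g, truth.geometry)
        g.attrs["noise_sd_ph"] = truth.noise_sd_ph
        g.attrs["inserted_rows"] = truth.inserted_rows
        g.attrs["relax"] = truth.relax
        for tag, kin in (("alkaline", truth.alkaline_kinetics), ("acidic", truth.acidic_kinetics)):
            g.attrs[f"{tag}_tau_fast_s"] = kin.tau_fast_s
            g.attrs[f"{tag}_tau_slow_s"] = kin.tau_slow_s
            g.attrs[f"{tag}_frac_fast"] = kin.frac_fast


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise FormatError("missing group: truth")
        g = f["truth"]
        kins = {}
        for tag in ("alkaline", "acidic"):
            kins[tag] = Kinetics(
                tau_fast_s=float(g.attrs[f"{tag}_tau_fast_s"]),
                tau_slow_s=float(g.attrs[f"{tag}_tau_slow_s"]),
                frac_fast=float(g.attrs[f"{tag}_frac_fast"]),
            )
        return GroundTruth(
            geometry=_read_geometry(g),
            sensitivity_map=g["sensitivity_map"][()],
            offset_map=g["offset_map"][()],
            defective_mask=g["defective_mask"][()].astype(bool),
            stuck_voltage_mv=g["stuck_voltage_mv"][()],
            response_field=g["response_field"][()],
            angles_deg=g["angles_deg"][()],
            alkaline_kinetics=kins["alkaline"],
            acidic_kinetics=kins["acidic"],
            noise_sd_ph=float(g.attrs["noise_sd_ph"]),
            inserted_rows=int(g.attrs["inserted_rows"]),
            relax=bool(g.attrs["relax"]),
        )


def write_calibration_model(model, path: str | os.PathLike) -> None:
    from .calibration import CalibrationModel  # local import to avoid a cycle

    assert isinstance(model, CalibrationModel)
    with h5py.File(path, "w") as f:
        for name in ("slope_map", "intercept_map", "fit_residuals"):
            f.create_dataset(name, data=getattr(model, name), **_H5_OPTS)
        f.create_dataset("defective_mask", data=model.defective_mask, **_H5_OPTS)
        f.create_dataset("buffer_phs", data=model.buffer_phs, track_times=False)
        _write_geometry(f, model.geometry)
        f.attrs["central_sensitivity"] = model.central_sensitivity


def read_calibration_model(path: str | os.PathLike):
    from .calibration import CalibrationModel

    with h5py.File(path, "r") as f:
        for name in ("slope_map", "intercept_map", "defective_mask", "buffer_phs"):
            if name not in f:
                raise FormatError(f"missing dataset: {name}")
        return CalibrationModel(
            slope_map=f["slope_map"][()],
            intercept_map=f["intercept_map"][()],
            defective_mask=f["defective_mask"][()].astype(bool),
            central_sensitivity=float(f.attrs["central_sensitivity"]),
            fit_residuals=f["fit_residuals"][()],
            buffer_phs=f["buffer_phs"][()],
            geometry=_read_geometry(f),
        )


def write_response_maps(maps, path: str | os.PathLike) -> None:
    from .response import ResponseMaps

    assert isinstance(maps, ResponseMaps)
    with h5py.File(path, "w") as f:
        for name in (
            "ph_interval_theta",
            "ph_interval",
            "delta_ph_trial",
            "delta_ph_theta",
            "delta_ph",
            "delta_delta_ph",
        ):
            f.create_dataset(name, data=getattr(maps, name), **_H5_OPTS)
        if maps.delta_delta_ph_trial is not None:
            f.create_dataset("delta_delta_ph_trial", data=maps.delta_delta_ph_trial, **_H5_OPTS)
        f.create_dataset("angles_deg", data=maps.angles_deg, track_times=False)
        f.create_dataset("trial_angles", data=maps.trial_angles, track_times=False)


def read_response_maps(path: str | os.PathLike):
    from .response import ResponseMaps

    with h5py.File(path, "r") as f:
        required = (
            "ph_interval_theta",
            "ph_interval",
            "delta_ph_trial",
            "delta_ph_theta",
            "delta_ph",
            "delta_delta_ph",
            "angles_deg",
            "trial_angles",
        )
        for name in required:
            if name not in f:
                raise FormatError(f"missing dataset: {name}")
        kwargs = {name: f[name][()] for name in required}
        ddt = f["delta_delta_ph_trial"][()] if "delta_delta_ph_trial" in f else None
        return ResponseMaps(delta_delta_ph_trial=ddt, **kwargs)


_PROTOCOL_COLUMNS = ["trial_index", "onset_s", "angle_deg"]


def write_protocol(protocol: StimulusProtocol, path: str | os.PathLike) -> None:
    """TSV event log with phase durations in ``#``-comment header lines."""
    header = [
        f"# pre_phase_s: {protocol.pre_phase_s!r}",
        f"# stim_s: {protocol.stim_s!r}",
        f"# interval_s: {protocol.interval_s!r}",
        f"# n_trials_per_angle: {protocol.n_trials_per_angle}",
        f"# angles_deg: {list(protocol.angles_deg)}",
        f"# seed: {protocol.seed if protocol.seed is not None else 'null'}",
    ]
    df = pd.DataFrame(
        {
            "trial_index": np.arange(len(protocol.events)),
            "onset_s": [e[0] for e in protocol.events],
            "angle_deg": [e[1] for e in protocol.events],
        }
    )
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_protocol(path: str | os.PathLike) -> StimulusProtocol:
    """Parse and revalidate a TSV event log (events sorted by onset)."""
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and ":" in line:
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = yaml.safe_load(value)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in _PROTOCOL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"protocol TSV missing column: {missing[0]}")
    for key in ("pre_phase_s", "stim_s", "interval_s", "n_trials_per_angle", "angles_deg"):
        if key not in meta:
            raise FormatError(f"protocol TSV missing header field: {key}")
    if df["trial_index"].duplicated().any():
        raise FormatError("protocol TSV: duplicate trial_index")
    if not df["onset_s"].is_monotonic_increasing:
        raise FormatError("protocol TSV: onsets must be sorted increasing")
    angles = tuple(float(a) for a in meta["angles_deg"])
    unknown = set(df["angle_deg"].astype(float)) - set(angles)
    if unknown:
        raise FormatError(f"protocol TSV: unknown angle {sorted(unknown)[0]}")
    df = df.sort_values("onset_s")
    events = tuple(zip(df["onset_s"].astype(float), df["angle_deg"].astype(float)))
    seed = meta.get("seed")
    return StimulusProtocol(
        pre_phase_s=float(meta["pre_phase_s"]),
        stim_s=float(meta["stim_s"]),
        interval_s=float(meta["interval_s"]),
        n_trials_per_angle=int(meta["n_trials_per_angle"]),
        angles_deg=angles,
        events=events,
        seed=None if seed is None else int(seed),
    )


_MAP_HEADER = "# per-pixel map; rows: 0-based sensor rows, row 0 = tip; cols: 0-based"


def export_map(map2d: np.ndarray, path: str | os.PathLike, format: str = "csv") -> None:
    """Write a per-pixel 2-D map as CSV (row/col headers) or float32 TIFF."""
    map2d = np.asarray(map2d)
    if map2d.ndim != 2:
        raise InvalidParameterError("export_map expects a 2-D map")
    if format == "csv":
        df = pd.DataFrame(
            map2d,
            index=[f"row_{i}" for i in range(map2d.shape[0])],
            columns=[f"col_{j}" for j in range(map2d.shape[1])],
        )
        with open(path, "w") as fh:
            fh.write(_MAP_HEADER + "\n")
            df.to_csv(fh, float_format="%.17g")
    elif format == "tiff":
        tifffile.imwrite(path, map2d.astype(np.float32))
    else:
        raise InvalidParameterError(f"format must be 'csv' or 'tiff', got {format!r}")


def import_map_csv(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path, comment="#", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float)


def import_map_tiff(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config YAML must be a mapping")
    return cfg


def write_config(config: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
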