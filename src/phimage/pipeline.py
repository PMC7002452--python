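"""Stage orchestration: run the whole synthetic experiment end to end.

Stages (``simulate``, ``calibrate``, ``convert``, ``boundary``,
``respond``, ``classify``, ``psth``, ``fit``) read their inputs from the
previous stage's directory under ``output_dir``, write their outputs plus
a ``manifest.json`` recording the parameters, the SHA-256 of every input
file and the package version.  All writers are deterministic, so
re-running an unchanged stage reproduces byte-identical outputs.

``run_paper_replica`` mirrors the full study design — nine brain-condition
runs and three buffered-saline null runs under the same drifting-gratings
protocol — at a reduced default scale, and emits the summary tables: the
pooled per-angle response histograms, the threshold-exceedance proportion
table, the significant-pixel count comparison (two-way ANOVA + pooled
t-test) and the four fitted time constants.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import calibration as cal
from . import classify as cls
from . import dynamics as dyn
from . import io as pio
from . import response as resp
from . import synth
from .boundary import compute_difference_map, detect_boundary
from .types import InvalidParameterError, SensorGeometry

__all__ = ["RunConfig", "DEFAULT_CONFIG", "run_stage", "run_paper_replica", "STAGES"]

log = logging.getLogger("phimage")

DEFAULT_CONFIG: dict = {
    "output_dir": "phimage_out",
    "seed": 0,
    "geometry": {"n_rows": 32, "n_cols": 16, "pixel_pitch_um": 23.55, "frame_rate_hz": 25.0},
    "protocol": {
        "pre_phase_s": 20.0,
        "stim_s": 2.0,
        "interval_s": 8.0,
        "n_trials_per_angle": 10,
        "angles_deg": [0, 45, 90, 135, 180, 225, 270, 315],
    },
    "simulate": {
        "condition": "brain",
        "amplitude_ph": 0.01,
        "noise_sd_ph": 0.005,
        "interpixel_sd_ph": [0.0171, 0.0037, 0.0061],
        "defect_rate": 0.0,
        "inserted_rows": 24,
        "photovoltage_mv": 20.0,
        "illumination_noise_sd_mv": 2.0,
    },
    "calibrate": {"mad_threshold": 5.0},
    "boundary": {"pre_window_s": 10.0, "exposure_window_s": 10.0, "method": "half_max"},
    "classify": {"alpha": 0.05},
    "psth": {"pre_s": 2.0, "stim_s": 2.0, "post_s": 4.0},
    "fit": {"fit_window_s": 6.0},
    "replica": {"n_brain": 9, "n_hepes": 3},
}


def _check_keys(config: dict, schema: dict, prefix: str = "") -> None:
    for key, value in config.items():
        if key not in schema:
            raise InvalidParameterError(f"unknown config key: {prefix}{key}")
        if isinstance(schema[key], dict):
            if not isinstance(value, dict):
                raise InvalidParameterError(f"config key {prefix}{key} must be a mapping")
            _check_keys(value, schema[key], prefix=f"{prefix}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    data: dict

    @classmethod
    def from_dict(cls, config: dict | None = None) -> "RunConfig":
        config = config or {}
        _check_keys(config, DEFAULT_CONFIG)
        data = _merge(DEFAULT_CONFIG, config)
        seed = data["seed"]
        if not isinstance(seed, int) or seed < 0:
            raise InvalidParameterError("seed must be a non-negative integer")
        alpha = data["classify"]["alpha"]
        if not 0.0 < alpha < 1.0:
            raise InvalidParameterError("classify.alpha must lie in (0, 1)")
        if data["simulate"]["condition"] not in ("brain", "hepes"):
            raise InvalidParameterError("simulate.condition must be 'brain' or 'hepes'")
        return cls(data=data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        return cls.from_dict(pio.read_config(path))

    @property
    def output_dir(self) -> Path:
        return Path(self.data["output_dir"])

    def geometry(self) -> SensorGeometry:
        return SensorGeometry(**self.data["geometry"])

    def stage_dir(self, stage: str) -> Path:
        d = self.output_dir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "outputs": sorted(outputs),
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(cfg: RunConfig, stage: str, name: str) -> Path:
    path = cfg.output_dir / stage / name
    if not path.exists():
        raise InvalidParameterError(
            f"missing upstream artifact {name!r}: run the {stage!r} stage first"
        )
    return path


def _stage_simulate(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("simulate")
    geom = cfg.geometry()
    p = cfg.data["protocol"]
    s = cfg.data["simulate"]
    seed = cfg.data["seed"]
    protocol = synth.generate_protocol(
        pre_phase_s=p["pre_phase_s"],
        stim_s=p["stim_s"],
        interval_s=p["interval_s"],
        n_trials_per_angle=p["n_trials_per_angle"],
        angles_deg=p["angles_deg"],
        seed=seed,
    )
    pio.write_protocol(protocol, d / "protocol.tsv")
    calset, truth = synth.generate_calibration_set(
        geometry=geom,
        interpixel_sd_ph=s["interpixel_sd_ph"],
        defect_rate=s["defect_rate"],
        seed=seed + 1,
    )
    pio.write_calibration_set(calset, d / "calibration.h5")
    field = (
        synth.generate_response_field(
            geom, angles_deg=p["angles_deg"], amplitude_ph=s["amplitude_ph"], seed=seed + 2
        )
        if s["condition"] == "brain"
        else None
    )
    truth.response_field = (
        field if field is not None else np.zeros(geom.shape + (len(p["angles_deg"]),))
    )
    truth.noise_sd_ph = s["noise_sd_ph"]
    truth.inserted_rows = s["inserted_rows"]
    pio.write_ground_truth(truth, d / "truth.h5")
    movie = synth.generate_recording(geom, protocol, truth, s["condition"], seed=seed + 3)
    pio.write_recording(movie, d / "movie.h5")
    illum = synth.generate_illumination_segment(
        geom,
        inserted_rows=s["inserted_rows"],
        photovoltage_mv=s["photovoltage_mv"],
        noise_sd_mv=s["illumination_noise_sd_mv"],
        seed=seed + 4,
    )
    pio.write_recording(illum, d / "illumination.h5")
    log.info("simulate: %d trials, %d frames, condition=%s", protocol.n_trials, movie.n_frames, s["condition"])
    _write_manifest(d, "simulate", {**p, **s, "seed": seed}, [], ["protocol.tsv", "calibration.h5", "truth.h5", "movie.h5", "illumination.h5"])
    return {"protocol": protocol, "movie": movie, "calset": calset, "truth": truth}


def _stage_calibrate(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("calibrate")
    src = _require(cfg, "simulate", "calibration.h5")
    calset = pio.read_calibration_set(src)
    model = cal.fit_standard_curves(calset)
    mask = cal.detect_defective_pixels(model, mad_threshold=cfg.data["calibrate"]["mad_threshold"])
    pio.write_calibration_model(model, d / "calibration_model.h5")
    report = pd.DataFrame(
        {
            "quantity": ["central_sensitivity_mv_per_ph", "mean_abs_slope_mv_per_ph", "n_defective", "defective_fraction"],
            "value": [
                model.central_sensitivity,
                float(np.abs(model.slope_map[~mask]).mean()),
                int(mask.sum()),
                float(mask.mean()),
            ],
        }
    )
    report.to_csv(d / "sensitivity_report.csv", index=False)
    log.info("calibrate: sensitivity %.2f mV/pH, %d defective pixels", model.central_sensitivity, int(mask.sum()))
    _write_manifest(d, "calibrate", cfg.data["calibrate"], [src], ["calibration_model.h5", "sensitivity_report.csv"])
    return {"model": model}


def _stage_convert(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("convert")
    movie_path = _require(cfg, "simulate", "movie.h5")
    model_path = _require(cfg, "calibrate", "calibration_model.h5")
    movie = pio.read_recording(movie_path)
    model = pio.read_calibration_model(model_path)
    ph = cal.convert_voltage_to_ph(movie, model)
    pio.write_recording(ph, d / "movie_ph.h5")
    log.info("convert: %d frames to pH units", ph.n_frames)
    _write_manifest(d, "convert", {}, [movie_path, model_path], ["movie_ph.h5"])
    return {"ph_movie": ph}


def _stage_boundary(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("boundary")
    src = _require(cfg, "simulate", "illumination.h5")
    b = cfg.data["boundary"]
    rec = pio.read_recording(src)
    diff = compute_difference_map(rec, b["pre_window_s"], b["exposure_window_s"])
    result = detect_boundary(diff, rec.geometry, method=b["method"])
    pd.DataFrame(
        [
            {
                "boundary_row": result.boundary_row,
                "insertion_depth_um": result.insertion_depth_um,
                "threshold_mv": result.threshold_mv,
                "method": result.method,
                "fully_inserted": result.fully_inserted,
            }
        ]
    ).to_csv(d / "boundary.csv", index=False)
    pio.export_map(diff, d / "difference_map.tiff", format="tiff")
    log.info("boundary: row %d (%.0f um)", result.boundary_row, result.insertion_depth_um)
    _write_manifest(d, "boundary", b, [src], ["boundary.csv", "difference_map.tiff"])
    return {"boundary": result}


def _read_boundary(cfg: RunConfig):
    src = _require(cfg, "simulate", "illumination.h5")
    b = cfg.data["boundary"]
    rec = pio.read_recording(src)
    diff = compute_difference_map(rec, b["pre_window_s"], b["exposure_window_s"])
    return detect_boundary(diff, rec.geometry, method=b["method"])


def _stage_respond(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("respond")
    ph_path = _require(cfg, "convert", "movie_ph.h5")
    proto_path = _require(cfg, "simulate", "protocol.tsv")
    ph = pio.read_recording(ph_path)
    protocol = pio.read_protocol(proto_path)
    boundary = _read_boundary(cfg)
    tm = resp.segment_trials(ph, protocol, boundary)
    maps = resp.compute_response_maps(tm)
    resp.compute_trial_responses(tm, maps)
    pio.write_response_maps(maps, d / "response_maps.h5")
    outputs = ["response_maps.h5"]
    for k, angle in enumerate(maps.angles_deg):
        name = f"delta_delta_ph_{int(angle)}deg.csv"
        pio.export_map(maps.delta_delta_ph[:, :, k], d / name, format="csv")
        outputs.append(name)
    log.info("respond: %d trials segmented, %d angles", tm.n_trials, maps.angles_deg.size)
    _write_manifest(d, "respond", {}, [ph_path, proto_path], outputs)
    return {"maps": maps, "boundary": boundary}


def _stage_classify(cfg: RunConfig) -> dict:
    d = cfg.stage_dir("classify")
    maps_path = _require(cfg, "respond", "response_maps.h5")
    maps = pio.read_response_maps(maps_path)
    boundary = _read_boundary(cfg)
    alpha = cfg.data["classify"]["alpha"]
    cmap = cls.classify_by_ttest(maps, alpha=alpha, region_mask=boundary.inside_mask)
    counts = cmap.per_angle_counts()
    counts.to_csv(d / "ttest_counts.csv", index=False)
    outputs = ["ttest_counts.csv"]
    for k, angle in enumerate(cmap.angles_deg):
        name = f"labels_{int(angle)}deg.csv"
        pio.export_map(cmap.labels[:, :, k].astype(float), d / name, format="csv")
        outputs.append(name)
    log.info("classify: %d labeled pixel-angles (alpha=%.3f)", int((cmap.labels != 0).sum()), alpha)
    _write_manifest(d, "classify", {"alpha": alpha}, [maps_path], outputs)
    return {"classification": cmap}


def _psth_inputs(cfg: RunConfig):
    ph = pio.read_recording(_require(cfg, "convert", "movie_ph.h5"))
    protocol = pio.read_protocol(_require(cfg, "simulate", "protocol.tsv"))
    boundary = _read_boundary(cfg)
    w = cfg.data["psth"]
    windows = (w["pre_s"], w["stim_s"], w["post_s"])
    return ph, protocol, boundary, windows


def _stage_psth(cfg: RunConfig) -> dict:
    import h5py

    d = cfg.stage_dir("psth")
    ph, protocol, boundary, windows = _psth_inputs(cfg)
    psth = dyn.build_psth(ph, protocol, boundary, windows_s=windows)
    pre, stim, angles = dyn.trial_window_means(ph, protocol, boundary, windows_s=windows)
    cats = dyn.categorize_responses(pre, stim, alpha=cfg.data["classify"]["alpha"])
    order = dyn.sort_pixels(psth, cats)
    with h5py.File(d / "psth.h5", "w") as f:
        f.create_dataset("traces", data=psth.traces, compression="gzip", compression_opts=4, shuffle=True, track_times=False)
        f.create_dataset("time_axis", data=psth.time_axis, track_times=False)
        f.create_dataset("categories", data=cats, track_times=False)
        f.create_dataset("sort_order", data=order, track_times=False)
        f.attrs["windows_s"] = windows
    n_alk = int((cats == dyn.CATEGORY_ALKALINE).sum())
    n_acid = int((cats == dyn.CATEGORY_ACIDIC).sum())
    log.info("psth: %d alkaline, %d acidic pixel-angles", n_alk, n_acid)
    _write_manifest(
        d,
        "psth",
        cfg.data["psth"],
        [cfg.output_dir / "convert" / "movie_ph.h5", cfg.output_dir / "simulate" / "protocol.tsv"],
        ["psth.h5"],
    )
    return {"psth": psth, "categories": cats, "order": order}


def _stage_fit(cfg: RunConfig) -> dict:
    import h5py

    d = cfg.stage_dir("fit")
    src = _require(cfg, "psth", "psth.h5")
    w = cfg.data["psth"]
    with h5py.File(src, "r") as f:
        psth = dyn.PSTHSet(
            traces=f["traces"][()],
            time_axis=f["time_axis"][()],
            windows_s=(w["pre_s"], w["stim_s"], w["post_s"]),
            n_trials=cfg.data["protocol"]["n_trials_per_angle"],
        )
        cats = f["categories"][()]
    summary = dyn.summarize_categories([psth], [cats], fit_window_s=cfg.data["fit"]["fit_window_s"])
    report = {}
    for name, entry in summary.items():
        fit = entry["fit"]
        report[name] = {
            "n_members": entry["n_members"],
            "tau_fast_s": None if fit is None or not fit.converged else fit.tau_fast_s,
            "tau_slow_s": None if fit is None or not fit.converged else fit.tau_slow_s,
            "a_fast": None if fit is None or not fit.converged else fit.a_fast,
            "a_slow": None if fit is None or not fit.converged else fit.a_slow,
            "converged": None if fit is None else fit.converged,
        }
    (d / "fit_report.yaml").write_text(yaml.safe_dump(report, sort_keys=True))
    log.info("fit: %s", {k: v["tau_fast_s"] for k, v in report.items()})
    _write_manifest(d, "fit", cfg.data["fit"], [src], ["fit_report.yaml"])
    return {"report": report}


STAGES = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "convert": _stage_convert,
    "boundary": _stage_boundary,
    "respond": _stage_respond,
    "classify": _stage_classify,
    "psth": _stage_psth,
    "fit": _stage_fit,
}


def run_stage(stage_name: str, config: RunConfig | dict | None = None) -> dict:
    """Validate the config and execute one pipeline stage."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    if stage_name not in STAGES:
        raise InvalidParameterError(
            f"unknown stage {stage_name!r}; choose from {sorted(STAGES)}"
        )
    return STAGES[stage_name](config)


def _replica_single_run(cfg: RunConfig, condition: str, run_seed: int):
    """One full run (movie -> pH -> response maps) without touching disk."""
    geom = cfg.geometry()
    p = cfg.data["protocol"]
    s = cfg.data["simulate"]
    protocol = synth.generate_protocol(
        pre_phase_s=p["pre_phase_s"],
        stim_s=p["stim_s"],
        interval_s=p["interval_s"],
        n_trials_per_angle=p["n_trials_per_angle"],
        angles_deg=p["angles_deg"],
        seed=run_seed,
    )
    truth = synth.make_ground_truth(
        geom,
        angles_deg=p["angles_deg"],
        noise_sd_ph=s["noise_sd_ph"],
        inserted_rows=s["inserted_rows"],
    )
    if condition == "brain":
        truth.response_field = synth.generate_response_field(
            geom, angles_deg=p["angles_deg"], amplitude_ph=s["amplitude_ph"], seed=run_seed + 1
        )
    movie = synth.generate_recording(geom, protocol, truth, condition, seed=run_seed + 2)
    calset, _ = synth.generate_calibration_set(
        geometry=geom, interpixel_sd_ph=s["interpixel_sd_ph"], seed=run_seed + 3
    )
    model = cal.fit_standard_curves(calset)
    ph = cal.convert_voltage_to_ph(movie, model)
    illum = synth.generate_illumination_segment(
        geom,
        inserted_rows=s["inserted_rows"],
        photovoltage_mv=s["photovoltage_mv"],
        noise_sd_mv=s["illumination_noise_sd_mv"],
        seed=run_seed + 4,
    )
    boundary = detect_boundary(compute_difference_map(illum), geom)
    # the same insertion geometry applies in both conditions so that
    # per-angle pixel counts are comparable across conditions
    tm = resp.segment_trials(ph, protocol, boundary)
    maps = resp.compute_response_maps(tm)
    resp.compute_trial_responses(tm, maps)
    return protocol, ph, boundary, maps


def run_paper_replica(config: RunConfig | dict | None = None) -> dict:
    """Simulate the full 9-brain + 3-null design and emit the report tables."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    d = cfg.stage_dir("replica")
    seed = cfg.data["seed"]
    n_brain = cfg.data["replica"]["n_brain"]
    n_hepes = cfg.data["replica"]["n_hepes"]
    alpha = cfg.data["classify"]["alpha"]
    w = cfg.data["psth"]
    windows = (w["pre_s"], w["stim_s"], w["post_s"])

    runs = {}
    for i in range(n_brain):
        runs[f"brain_{i}"] = ("brain", *_replica_single_run(cfg, "brain", seed + 100 * (i + 1)))
    for i in range(n_hepes):
        runs[f"hepes_{i}"] = ("hepes", *_replica_single_run(cfg, "hepes", seed + 100 * (n_brain + i + 1)))

    hepes_maps = [v[4] for v in runs.values() if v[0] == "hepes"]
    thresholds = cls.compute_null_thresholds(hepes_maps, sources=[k for k, v in runs.items() if v[0] == "hepes"])

    # pooled per-angle response histograms (the distribution view)
    hist_rows = []
    edges = np.linspace(-0.02, 0.02, 81)
    for name, (condition, _, _, _, maps) in runs.items():
        for k, angle in enumerate(maps.angles_deg):
            vals = maps.delta_delta_ph[:, :, k]
            vals = vals[np.isfinite(vals)]
            counts, _ = np.histogram(vals, bins=edges)
            for lo, c in zip(edges[:-1], counts):
                hist_rows.append(
                    {"run": name, "condition": condition, "angle_deg": float(angle), "bin_left": float(lo), "count": int(c)}
                )
    pd.DataFrame(hist_rows).to_csv(d / "response_histograms.csv", index=False)

    # threshold-exceedance proportions and t-test counts per run/angle
    prop_rows, count_tables = [], []
    for name, (condition, protocol, ph, boundary, maps) in runs.items():
        region = boundary.inside_mask
        ci_map = cls.classify_by_threshold(maps, thresholds, region_mask=region)
        for _, row in ci_map.per_angle_counts().iterrows():
            prop_rows.append({"run": name, "condition": condition, **row.to_dict()})
        t_map = cls.classify_by_ttest(maps, alpha=alpha, region_mask=region)
        count_tables.append(cls.count_table(t_map, run=name, condition=condition))
    pd.DataFrame(prop_rows).to_csv(d / "threshold_proportions.csv", index=False)
    comparison = cls.compare_brain_vs_null(count_tables)
    pd.concat(count_tables, ignore_index=True).to_csv(d / "ttest_counts.csv", index=False)

    # peri-stimulus dynamics pooled over the brain runs
    psth_sets, cats_list = [], []
    for name, (condition, protocol, ph, boundary, maps) in runs.items():
        if condition != "brain":
            continue
        psth = dyn.build_psth(ph, protocol, boundary, windows_s=windows)
        pre, stim, _ = dyn.trial_window_means(ph, protocol, boundary, windows_s=windows)
        psth_sets.append(psth)
        cats_list.append(dyn.categorize_responses(pre, stim, alpha=alpha))
    summary = dyn.summarize_categories(psth_sets, cats_list, fit_window_s=cfg.data["fit"]["fit_window_s"])

    interaction_f, interaction_p = comparison.effect("interaction")
    condition_f, condition_p = comparison.effect("condition")
    taus = {}
    for name in ("alkaline", "acidic"):
        fit = summary[name]["fit"]
        taus[name] = {
            "tau_fast_s": None if fit is None or not fit.converged else fit.tau_fast_s,
            "tau_slow_s": None if fit is None or not fit.converged else fit.tau_slow_s,
            "n_members": summary[name]["n_members"],
        }
    stats_report = {
        "thresholds_ph": {"lower": thresholds.lower, "upper": thresholds.upper, "n_pooled": thresholds.n_values},
        "two_way_anova": {
            "condition_F": condition_f,
            "condition_p": condition_p,
            "interaction_F": interaction_f,
            "interaction_p": interaction_p,
        },
        "pooled_t_test": {"t": comparison.t_stat, "p": comparison.t_p},
        "time_constants": taus,
        "n_runs": {"brain": n_brain, "hepes": n_hepes},
    }
    (d / "replica_report.yaml").write_text(yaml.safe_dump(stats_report, sort_keys=True))
    comparison.anova.to_csv(d / "anova_table.csv")
    log.info("replica: ANOVA condition p=%.3g, pooled t p=%.3g", condition_p, comparison.t_p)
    _write_manifest(
        d,
        "replica",
        {"n_brain": n_brain, "n_hepes": n_hepes, "alpha": alpha, "seed": seed},
        [],
        ["response_histograms.csv", "threshold_proportions.csv", "ttest_counts.csv", "anova_table.csv", "replica_report.yaml"],
    )
    return stats_report
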