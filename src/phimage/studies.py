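"""Parameter-recovery and calibration studies on synthetic data.

Each study generates data with known ground truth using the device and
kinetic constants the sensor was characterized with (central-pixel
sensitivity 51.6 mV per pH, per-buffer inter-pixel spreads, 2.89%
defective-pixel probability, alkaline/acidic two-component time
constants), runs the corresponding pipeline stage, and returns the
recovered quantity.  The studies double as the package's self-checks:
tests and the acceptance script call exactly these functions.

Problem sizes are chosen so every study runs on a laptop in seconds to a
couple of minutes; where the in-vivo design is larger (e.g. the 128x32
grid over a 42-minute session) the study keeps the axes that matter for
the statistic being recovered and trims the rest.
"""

from __future__ import annotations

import numpy as np

from . import calibration as cal
from . import classify as cls
from . import dynamics as dyn
from . import response as resp
from . import synth
from .boundary import compute_difference_map, detect_boundary
from .types import (
    ACIDIC_KINETICS,
    ALKALINE_KINETICS,
    DEFAULT_BUFFER_PHS,
    DEFAULT_DEFECT_RATE,
    DEFAULT_INTERPIXEL_SD_PH,
    DEFAULT_SENSITIVITY_MV_PER_PH,
    Kinetics,
    SensorGeometry,
)

__all__ = [
    "sensitivity_recovery",
    "tau_recovery",
    "defect_rate_recovery",
    "interpixel_sd_recovery",
    "null_calibration_study",
    "boundary_recovery",
]


def sensitivity_recovery(
    seed: int = 0,
    geometry: SensorGeometry = SensorGeometry(),
    sensitivity: float = DEFAULT_SENSITIVITY_MV_PER_PH,
) -> dict:
    """Fit standard curves on a noiseless three-buffer set; recover |slope|."""
    calset, truth = synth.generate_calibration_set(
        geometry=geometry,
        mean_sensitivity_mv_per_ph=sensitivity,
        interpixel_sd_ph=0.0,
        defect_rate=0.0,
        buffer_phs=DEFAULT_BUFFER_PHS,
        seed=seed,
    )
    model = cal.fit_standard_curves(calset)
    return {
        "mean_abs_slope_mv_per_ph": float(np.abs(model.slope_map).mean()),
        "central_sensitivity_mv_per_ph": model.central_sensitivity,
        "true_sensitivity_mv_per_ph": sensitivity,
        "n_pixels": geometry.n_pixels,
    }


def tau_recovery(
    polarity: str,
    kinetics: Kinetics | None = None,
    amplitude_ph: float = 0.01,
    n_pixels: int = 60,
    n_trials: int = 30,
    frame_rate_hz: float = 50.0,
    snr: float = 5.0,
    seed: int = 0,
) -> dyn.BiexpFit:
    """Recover the fast/slow time constants of one response category.

    Simulates ``n_pixels`` responding pixels whose evoked time course
    follows the rising two-component exponential of the given category,
    30 noisy trials each at 50 Hz; builds baseline-referenced PSTHs,
    categorizes each pixel from its per-trial pre/stim means, pools the
    expected category's traces, and fits the two-component model.
    """
    if polarity == "alkaline":
        kin = kinetics or ALKALINE_KINETICS
        amp = abs(amplitude_ph)
        code = dyn.CATEGORY_ALKALINE
    elif polarity == "acidic":
        kin = kinetics or ACIDIC_KINETICS
        amp = -abs(amplitude_ph)
        code = dyn.CATEGORY_ACIDIC
    else:
        raise ValueError(f"polarity must be 'alkaline' or 'acidic', got {polarity!r}")
    traces, time_axis = synth.generate_psth_trials(
        kin,
        amplitude_ph=amp,
        n_pixels=n_pixels,
        n_trials=n_trials,
        frame_rate_hz=frame_rate_hz,
        snr=snr,
        seed=seed,
    )
    psth = dyn.psth_from_trial_traces(traces, time_axis)
    pre = time_axis < 0.0
    stim = (time_axis >= 0.0) & (time_axis < psth.windows_s[1])
    pre_means = traces[..., pre].mean(axis=-1)  # (n_pixels, n_trials)
    stim_means = traces[..., stim].mean(axis=-1)
    cats = dyn.categorize_responses(pre_means, stim_means)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="category .* has no members")
        summary = dyn.summarize_categories([psth], [cats])
    fit = summary[polarity]["fit"]
    if fit is None:
        raise RuntimeError(f"no pixels were categorized as {polarity}")
    return fit


def defect_rate_recovery(
    n_seeds: int = 20,
    geometry: SensorGeometry = SensorGeometry(),
    defect_rate: float = DEFAULT_DEFECT_RATE,
    interpixel_sd_ph=DEFAULT_INTERPIXEL_SD_PH,
    mad_threshold: float = 5.0,
    seed: int = 0,
) -> dict:
    """Mean detected defective-pixel fraction over seeded replicate arrays."""
    fractions = []
    for k in range(n_seeds):
        calset, truth = synth.generate_calibration_set(
            geometry=geometry,
            interpixel_sd_ph=interpixel_sd_ph,
            defect_rate=defect_rate,
            seed=seed * 10_000 + k,
        )
        model = cal.fit_standard_curves(calset)
        mask = cal.detect_defective_pixels(model, mad_threshold=mad_threshold)
        fractions.append(mask.mean())
    fractions = np.asarray(fractions)
    return {
        "mean_detected_fraction": float(fractions.mean()),
        "sd_detected_fraction": float(fractions.std(ddof=1)),
        "injected_rate": float(defect_rate),
        "n_seeds": n_seeds,
        "n_pixels": geometry.n_pixels,
    }


def interpixel_sd_recovery(
    n_devices: int = 12,
    geometry: SensorGeometry = SensorGeometry(),
    interpixel_sd_ph=DEFAULT_INTERPIXEL_SD_PH,
    seed: int = 0,
) -> dict:
    """Mean per-device inter-pixel SD of converted pH readouts per buffer."""
    devices = []
    for k in range(n_devices):
        calset, _ = synth.generate_calibration_set(
            geometry=geometry,
            interpixel_sd_ph=interpixel_sd_ph,
            seed=seed * 10_000 + k,
        )
        model = cal.fit_standard_curves(calset)
        devices.append((calset, model))
    mean_sd, sd_sd = cal.interpixel_variation_study(devices)
    return {
        "buffer_phs": list(DEFAULT_BUFFER_PHS),
        "mean_sd_ph": mean_sd.tolist(),
        "sd_sd_ph": sd_sd.tolist(),
        "generating_sd_ph": list(np.broadcast_to(interpixel_sd_ph, (len(DEFAULT_BUFFER_PHS),))),
        "n_devices": n_devices,
    }


def _hepes_response_maps(geometry, protocol, noise_sd_ph, seed):
    truth = synth.make_ground_truth(geometry, noise_sd_ph=noise_sd_ph)
    movie = synth.generate_recording(geometry, protocol, truth, "hepes", seed=seed)
    calset, _ = synth.generate_calibration_set(geometry=geometry, seed=seed + 1)
    model = cal.fit_standard_curves(calset)
    ph = cal.convert_voltage_to_ph(movie, model)
    tm = resp.segment_trials(ph, protocol)
    maps = resp.compute_response_maps(tm)
    resp.compute_trial_responses(tm, maps)
    return maps


def null_calibration_study(
    seed: int = 0,
    geometry: SensorGeometry = SensorGeometry(n_rows=42, n_cols=32),
    n_null_runs: int = 3,
    noise_sd_ph: float = 0.005,
    alpha: float = 0.05,
) -> dict:
    """False-positive fractions of both classifiers on buffered-saline runs.

    Thresholds come from ``n_null_runs`` pooled null runs; a fresh null run
    is then classified by the CI-threshold rule and by the per-pixel
    t-test.  The default grid keeps the device's 32-pixel width and gives
    42 * 32 * 8 = 10752 pixel-angle draws per run.
    """
    protocol = synth.generate_protocol(seed=seed)
    pool = [
        _hepes_response_maps(geometry, protocol, noise_sd_ph, seed=seed * 100 + k)
        for k in range(n_null_runs)
    ]
    thresholds = cls.compute_null_thresholds(pool)
    fresh = _hepes_response_maps(geometry, protocol, noise_sd_ph, seed=seed * 100 + n_null_runs)
    ci_map = cls.classify_by_threshold(fresh, thresholds)
    t_map = cls.classify_by_ttest(fresh, alpha=alpha)
    n_draws = int(ci_map.valid.sum()) * fresh.angles_deg.size
    return {
        "fp_fraction_ci": ci_map.labeled_fraction,
        "fp_fraction_ttest": t_map.labeled_fraction,
        "nominal": alpha,
        "n_draws": n_draws,
        "thresholds": (thresholds.lower, thresholds.upper),
    }


def boundary_recovery(
    n_runs: int = 100,
    geometry: SensorGeometry = SensorGeometry(),
    true_boundary_row: int = 85,
    photovoltage_mv: float = 20.0,
    snr: float = 10.0,
    seed: int = 0,
) -> dict:
    """Detected insertion row vs truth over noisy illumination segments."""
    errors = []
    for k in range(n_runs):
        rec = synth.generate_illumination_segment(
            geometry,
            inserted_rows=true_boundary_row,
            photovoltage_mv=photovoltage_mv,
            noise_sd_mv=photovoltage_mv / snr,
            seed=seed * 10_000 + k,
        )
        diff = compute_difference_map(rec)
        result = detect_boundary(diff, geometry)
        errors.append(result.boundary_row - true_boundary_row)
    errors = np.asarray(errors)
    rec0 = synth.generate_illumination_segment(
        geometry, inserted_rows=true_boundary_row, photovoltage_mv=photovoltage_mv, seed=seed
    )
    exact = detect_boundary(compute_difference_map(rec0), geometry)
    return {
        "fraction_within_1_row": float((np.abs(errors) <= 1).mean()),
        "max_abs_error_rows": int(np.abs(errors).max()),
        "noiseless_boundary_row": exact.boundary_row,
        "noiseless_depth_um": exact.insertion_depth_um,
        "noiseless_depth_mm": exact.insertion_depth_mm,
        "n_runs": n_runs,
    }
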