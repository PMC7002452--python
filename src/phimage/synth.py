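"""Synthetic sensor-data generator with known ground truth.

Emulates the device and the visual-stimulation experiment end to end:
three-buffer calibration readouts with inter-pixel spread and stuck
(defective) pixels, the drifting-gratings protocol (120 s gray pre-phase,
then 2 s grating + 8 s gray, 30 trials for each of 8 directions in
randomized order), direction-dependent spatial response fields with
two-component exponential onset kinetics, a HEPES-buffered-saline null
condition with no evoked response, and a white-light illumination segment
in which only non-inserted pixel rows show the full photoelectric voltage
step.

Every operation takes an integer ``seed`` and draws all randomness from a
single ``numpy.random.default_rng(seed)``; identical parameters and seed
give bit-identical output.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import (
    ACIDIC_KINETICS,
    ALKALINE_KINETICS,
    BASELINE_PH,
    DEFAULT_BUFFER_PHS,
    DEFAULT_SENSITIVITY_MV_PER_PH,
    CalibrationSet,
    GroundTruth,
    InvalidParameterError,
    Kinetics,
    Recording,
    SensorGeometry,
    StimulusProtocol,
)

__all__ = [
    "generate_protocol",
    "generate_response_field",
    "generate_calibration_set",
    "generate_recording",
    "generate_illumination_segment",
    "generate_psth_trials",
    "make_ground_truth",
]

DEFAULT_ANGLES = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

#: Signed mean evoked amplitude per direction (pH units).  Directions 0, 90
#: and 270 deg shift the pixel distribution toward alkalinity, 45, 135 and
#: 180 deg toward acidity, and the remaining two are close to neutral.
DEFAULT_ANGLE_MEANS_PH = {
    0.0: +1.0,
    45.0: -1.0,
    90.0: +1.0,
    135.0: -1.0,
    180.0: -1.0,
    225.0: 0.0,
    270.0: +1.0,
    315.0: 0.0,
}


def generate_protocol(
    pre_phase_s: float = 120.0,
    stim_s: float = 2.0,
    interval_s: float = 8.0,
    n_trials_per_angle: int = 30,
    angles_deg: Sequence[float] = DEFAULT_ANGLES,
    seed: int = 0,
) -> StimulusProtocol:
    """Build a randomized presentation schedule.

    The event order is a seeded uniform permutation of the full trial
    multiset (each angle exactly ``n_trials_per_angle`` times); onsets are
    ``pre_phase_s + i * (stim_s + interval_s)``.
    """
    angles = tuple(float(a) for a in angles_deg)
    if len(set(angles)) != len(angles):
        raise InvalidParameterError("angles must be distinct")
    if stim_s <= 0 or interval_s <= 0 or pre_phase_s < 0:
        raise InvalidParameterError("durations must be positive (pre_phase_s >= 0)")
    if n_trials_per_angle < 1:
        raise InvalidParameterError("n_trials_per_angle must be >= 1")
    rng = np.random.default_rng(seed)
    trial_angles = np.repeat(np.asarray(angles, dtype=float), n_trials_per_angle)
    rng.shuffle(trial_angles)
    period = stim_s + interval_s
    events = tuple(
        (pre_phase_s + i * period, float(a)) for i, a in enumerate(trial_angles)
    )
    return StimulusProtocol(
        pre_phase_s=pre_phase_s,
        stim_s=stim_s,
        interval_s=interval_s,
        n_trials_per_angle=n_trials_per_angle,
        angles_deg=angles,
        events=events,
        seed=seed,
    )


def generate_response_field(
    geometry: SensorGeometry,
    angles_deg: Sequence[float] = DEFAULT_ANGLES,
    amplitude_ph: float = 0.01,
    angle_means: dict[float, float] | None = None,
    spatial_sd_frac: float = 0.5,
    corr_length_px: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-angle signed amplitude maps as smoothed Gaussian random fields.

    Each angle's map is a zero-mean Gaussian random field with spatial
    correlation length ``corr_length_px`` (pixels) and pixel SD
    ``spatial_sd_frac * amplitude_ph``, shifted by that angle's signed mean
    ``angle_means[angle] * amplitude_ph``.  No generative spatial model is
    known for the real cortex; this is the simulator's definition.
    """
    rng = np.random.default_rng(seed)
    angles = [float(a) for a in angles_deg]
    means = DEFAULT_ANGLE_MEANS_PH if angle_means is None else angle_means
    field = np.empty(geometry.shape + (len(angles),), dtype=float)
    for k, angle in enumerate(angles):
        white = rng.standard_normal(geometry.shape)
        smooth = gaussian_filter(white, sigma=corr_length_px, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        field[:, :, k] = (
            means.get(angle, 0.0) * amplitude_ph + spatial_sd_frac * amplitude_ph * smooth
        )
    return field


def make_ground_truth(
    geometry: SensorGeometry,
    response_field: np.ndarray | None = None,
    angles_deg: Sequence[float] = DEFAULT_ANGLES,
    sensitivity_mv_per_ph: float = DEFAULT_SENSITIVITY_MV_PER_PH,
    noise_sd_ph: float = 0.0,
    inserted_rows: int | None = None,
    alkaline_kinetics: Kinetics = ALKALINE_KINETICS,
    acidic_kinetics: Kinetics = ACIDIC_KINETICS,
    relax: bool = True,
) -> GroundTruth:
    """Convenience constructor for a defect-free ground truth."""
    angles = np.asarray([float(a) for a in angles_deg])
    if response_field is None:
        response_field = np.zeros(geometry.shape + (angles.size,))
    if inserted_rows is None:
        inserted_rows = geometry.n_rows
    return GroundTruth(
        geometry=geometry,
        sensitivity_map=np.full(geometry.shape, float(sensitivity_mv_per_ph)),
        offset_map=np.zeros(geometry.shape),
        defective_mask=np.zeros(geometry.shape, dtype=bool),
        stuck_voltage_mv=np.full(geometry.shape, np.nan),
        response_field=np.asarray(response_field, dtype=float),
        angles_deg=angles,
        alkaline_kinetics=alkaline_kinetics,
        acidic_kinetics=acidic_kinetics,
        noise_sd_ph=float(noise_sd_ph),
        inserted_rows=int(inserted_rows),
        relax=relax,
    )


def generate_calibration_set(
    geometry: SensorGeometry = SensorGeometry(),
    mean_sensitivity_mv_per_ph: float = DEFAULT_SENSITIVITY_MV_PER_PH,
    interpixel_sd_ph: float | Sequence[float] = 0.0,
    defect_rate: float = 0.0,
    buffer_phs: Sequence[float] = DEFAULT_BUFFER_PHS,
    seed: int = 0,
) -> tuple[CalibrationSet, GroundTruth]:
    """Simulate three-buffer calibration readouts plus ground truth.

    Non-defective pixels read ``V = offset - S * (pH + eta - 7.0)`` where
    ``eta`` is zero-mean Gaussian inter-pixel noise whose SD (per buffer)
    equals ``interpixel_sd_ph`` in pH-equivalent units.  Defective pixels
    (seeded Bernoulli at ``defect_rate``) emit a constant stuck voltage
    independent of pH.
    """
    buffers = np.asarray(buffer_phs, dtype=float)
    if buffers.size < 2 or len(set(buffers.tolist())) < 2:
        raise InvalidParameterError("at least 2 distinct calibration buffers required")
    if not 0.0 <= defect_rate < 1.0:
        raise InvalidParameterError("defect_rate must lie in [0, 1)")
    sd = np.broadcast_to(np.asarray(interpixel_sd_ph, dtype=float), (buffers.size,))
    if np.any(sd < 0):
        raise InvalidParameterError("interpixel_sd_ph must be >= 0")

    rng = np.random.default_rng(seed)
    truth = make_ground_truth(geometry, sensitivity_mv_per_ph=mean_sensitivity_mv_per_ph)
    defective = rng.random(geometry.shape) < defect_rate
    stuck = np.where(defective, rng.uniform(-150.0, 150.0, size=geometry.shape), np.nan)
    truth.defective_mask = defective
    truth.stuck_voltage_mv = stuck

    eta = rng.standard_normal((buffers.size,) + geometry.shape) * sd[:, None, None]
    ph_seen = buffers[:, None, None] + eta
    voltages = truth.transduce(ph_seen)
    voltages[:, defective] = stuck[defective]
    calset = CalibrationSet(
        buffer_phs=buffers,
        voltages=voltages,
        geometry=geometry,
        metadata={
            "mean_sensitivity_mv_per_ph": float(mean_sensitivity_mv_per_ph),
            "interpixel_sd_ph": [float(x) for x in sd],
            "defect_rate": float(defect_rate),
            "seed": int(seed),
        },
    )
    return calset, truth


def _evoked_ph(
    protocol: StimulusProtocol,
    truth: GroundTruth,
    timestamps: np.ndarray,
) -> np.ndarray:
    """Noise-free pH movie (n_frames, n_rows, n_cols) above baseline 7.4.

    pH(t, p) = 7.4 + sum_trials r[p, angle] * k(t - onset) where k is the
    two-component kinetic of the pixel's polarity; alkaline kinetics apply
    to positive amplitudes, acidic to negative.
    """
    n_frames = timestamps.size
    angles = truth.angles_deg
    n_angles = angles.size
    field = truth.response_field
    pos = np.maximum(field, 0.0)
    neg = np.minimum(field, 0.0)

    # per-angle summed kinetic time courses, one per polarity
    u_pos = np.zeros((n_angles, n_frames))
    u_neg = np.zeros((n_angles, n_frames))
    need_pos = np.any(pos != 0, axis=(0, 1))
    need_neg = np.any(neg != 0, axis=(0, 1))
    angle_index = {a: k for k, a in enumerate(angles.tolist())}
    for onset, angle in protocol.events:
        k = angle_index[float(angle)]
        rel = timestamps - onset
        if need_pos[k]:
            u_pos[k] += truth.alkaline_kinetics.response(
                rel, protocol.stim_s, relax=truth.relax
            )
        if need_neg[k]:
            u_neg[k] += truth.acidic_kinetics.response(
                rel, protocol.stim_s, relax=truth.relax
            )
    evoked = np.einsum("rca,at->trc", pos, u_pos) + np.einsum("rca,at->trc", neg, u_neg)
    return BASELINE_PH + evoked


def generate_recording(
    geometry: SensorGeometry,
    protocol: StimulusProtocol,
    truth: GroundTruth,
    condition: str,
    duration_pad_s: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Simulate a voltage-frame movie for a full stimulation session.

    ``condition='hepes'`` forces the response field to zero (buffered
    saline cannot respond); ``'brain'`` uses ``truth.response_field``.
    Voltage frames are the truth's transduction of the pH movie plus
    per-frame Gaussian noise of SD ``truth.noise_sd_ph`` (pH-equivalent);
    defective pixels emit their stuck voltage.  Frame f is stamped
    ``f / frame_rate``.
    """
    if condition not in ("brain", "hepes"):
        raise InvalidParameterError(f"condition must be 'brain' or 'hepes', got {condition!r}")
    if truth.geometry != geometry:
        raise InvalidParameterError("truth geometry inconsistent with requested geometry")
    rng = np.random.default_rng(seed)
    n_frames = int(round((protocol.total_duration_s + duration_pad_s) * geometry.frame_rate_hz))
    timestamps = np.arange(n_frames) / geometry.frame_rate_hz

    if condition == "hepes" or not np.any(truth.response_field):
        ph = np.full((n_frames,) + geometry.shape, BASELINE_PH)
    else:
        ph = _evoked_ph(protocol, truth, timestamps)
    if truth.noise_sd_ph > 0:
        ph = ph + rng.standard_normal(ph.shape) * truth.noise_sd_ph
    volts = truth.transduce(ph)
    if np.any(truth.defective_mask):
        volts[:, truth.defective_mask] = truth.stuck_voltage_mv[truth.defective_mask]
    return Recording(
        frames=volts.astype(np.float32),
        timestamps=timestamps,
        geometry=geometry,
        condition=condition,
        units="mV",
        metadata={"seed": int(seed), "noise_sd_ph": float(truth.noise_sd_ph)},
    )


def generate_illumination_segment(
    geometry: SensorGeometry,
    inserted_rows: int,
    pre_exposure_s: float = 10.0,
    exposure_s: float = 10.0,
    photovoltage_mv: float = 20.0,
    attenuation: float = 0.05,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Simulate the white-light boundary-check segment.

    Rows outside the brain (row index >= ``inserted_rows``; the tip is row
    0 and goes in first) gain the full photoelectric step
    ``+photovoltage_mv`` during the exposure window; inserted rows gain
    only the attenuated fraction (light scattered into tissue), default 5%.
    """
    if not 0 <= inserted_rows <= geometry.n_rows:
        raise InvalidParameterError("inserted_rows out of range")
    if pre_exposure_s <= 0 or exposure_s <= 0:
        raise InvalidParameterError("exposure windows must be > 0")
    rng = np.random.default_rng(seed)
    n_frames = int(round((pre_exposure_s + exposure_s) * geometry.frame_rate_hz))
    timestamps = np.arange(n_frames) / geometry.frame_rate_hz
    step_map = np.full(geometry.shape, attenuation * photovoltage_mv)
    step_map[inserted_rows:, :] = photovoltage_mv
    exposed = timestamps >= pre_exposure_s
    volts = np.zeros((n_frames,) + geometry.shape)
    volts[exposed] = step_map
    if noise_sd_mv > 0:
        volts += rng.standard_normal(volts.shape) * noise_sd_mv
    return Recording(
        frames=volts.astype(np.float32),
        timestamps=timestamps,
        geometry=geometry,
        condition="illumination",
        units="mV",
        metadata={
            "inserted_rows": int(inserted_rows),
            "pre_exposure_s": float(pre_exposure_s),
            "exposure_s": float(exposure_s),
            "photovoltage_mv": float(photovoltage_mv),
            "seed": int(seed),
        },
    )


def generate_psth_trials(
    kinetics: Kinetics,
    amplitude_ph: float,
    n_pixels: int = 60,
    n_trials: int = 30,
    frame_rate_hz: float = 50.0,
    windows_s: tuple[float, float, float] = (2.0, 2.0, 4.0),
    snr: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial evoked time courses for time-constant recovery studies.

    Each trial trace follows the rising two-component exponential
    ``amplitude_ph * k(t)`` from onset through the whole stim + post
    window (a sustained response, matching the family the fitter assumes)
    with additive per-sample Gaussian noise of SD ``|amplitude_ph| / snr``.

    Returns ``(traces, time_axis)`` with traces shaped
    ``(n_pixels, n_trials, n_bins)`` and time in seconds relative to onset.
    """
    if snr <= 0:
        raise InvalidParameterError("snr must be > 0")
    pre_s, stim_s, post_s = windows_s
    rng = np.random.default_rng(seed)
    n_bins = int(round((pre_s + stim_s + post_s) * frame_rate_hz))
    n_pre = int(round(pre_s * frame_rate_hz))
    time_axis = (np.arange(n_bins) - n_pre) / frame_rate_hz
    signal = amplitude_ph * kinetics.rise(time_axis)
    noise_sd = abs(amplitude_ph) / snr
    traces = signal + rng.standard_normal((n_pixels, n_trials, n_bins)) * noise_sd
    return traces, time_axis
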