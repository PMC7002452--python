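"""Core data containers for proton-image-sensor experiments.

Conventions used throughout the package:

* Pixel indexing is 0-based ``(row, col)``; row 0 is the sensor tip, i.e.
  the deepest inserted row.  The chip enters the tissue tip-first, so rows
  ``< boundary_row`` are inside the brain.
* Voltages are in mV; pH is dimensionless.
* Transduction sign convention: the Si3N4 surface potential rises as pH
  falls (proton adsorption), so ``V = offset - S * (pH - 7.0)`` with the
  sensitivity ``S > 0`` in mV per pH unit.  The convention is configurable
  through the sign of the stored sensitivity/slope maps.
* Voltage frames are stored as float32 (the on-disk layout); everything
  derived from them is computed in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SensorGeometry",
    "Kinetics",
    "GroundTruth",
    "StimulusProtocol",
    "Recording",
    "CalibrationSet",
    "InvalidParameterError",
    "FormatError",
    "BASELINE_PH",
    "DEFAULT_BUFFER_PHS",
    "DEFAULT_SENSITIVITY_MV_PER_PH",
    "DEFAULT_DEFECT_RATE",
    "DEFAULT_INTERPIXEL_SD_PH",
    "ALKALINE_KINETICS",
    "ACIDIC_KINETICS",
]

#: Physiological baseline of the HEPES-buffered saline and resting tissue.
BASELINE_PH = 7.4

#: Standard calibration buffers (pH units).
DEFAULT_BUFFER_PHS = (4.01, 6.86, 9.18)

#: Central-pixel sensitivity of the device, mV per pH unit.
DEFAULT_SENSITIVITY_MV_PER_PH = 51.6

#: Defective-pixel probability of the device.
DEFAULT_DEFECT_RATE = 0.0289

#: Inter-pixel spread of converted pH readouts per buffer, pH units,
#: ordered as DEFAULT_BUFFER_PHS.
DEFAULT_INTERPIXEL_SD_PH = (0.0171, 0.0037, 0.0061)


class InvalidParameterError(ValueError):
    """A caller-supplied parameter violates an operation precondition."""


class FormatError(ValueError):
    """An on-disk artifact is malformed or violates a container invariant."""


@dataclass(frozen=True)
class SensorGeometry:
    """Pixel-grid geometry and frame clock of the sensing area."""

    n_rows: int = 128
    n_cols: int = 32
    pixel_pitch_um: float = 23.55
    frame_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("pixel counts must be >= 1")
        if self.pixel_pitch_um <= 0:
            raise InvalidParameterError("pixel_pitch_um must be > 0")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_hz


@dataclass(frozen=True)
class Kinetics:
    """Two-component exponential kinetics of an evoked pH transient.

    The response develops during stimulation as

        k(t) = f * (1 - exp(-t / tau_fast)) + (1 - f) * (1 - exp(-t / tau_slow))

    and, after stimulus offset at ``t = stim_s``, each component relaxes
    from its attained level with its own time constant.
    """

    tau_fast_s: float
    tau_slow_s: float
    frac_fast: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_fast_s <= 0 or self.tau_slow_s <= 0:
            raise InvalidParameterError("time constants must be > 0")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise InvalidParameterError("frac_fast must lie in [0, 1]")

    def rise(self, t: np.ndarray | float) -> np.ndarray:
        """Normalized rising response, 0 before onset, -> 1 as t -> inf."""
        t = np.asarray(t, dtype=float)
        pos = np.maximum(t, 0.0)
        f = self.frac_fast
        out = f * (1.0 - np.exp(-pos / self.tau_fast_s)) + (1.0 - f) * (
            1.0 - np.exp(-pos / self.tau_slow_s)
        )
        return np.where(t < 0.0, 0.0, out)

    def response(
        self, t: np.ndarray | float, stim_s: float, relax: bool = True
    ) -> np.ndarray:
        """Normalized response with per-component relaxation after offset.

        With ``relax=False`` the response keeps following the rising form
        beyond the stimulus offset (a sustained response); whether evoked
        transients persist through the inter-trial interval in vivo is
        unknown, so persistence is a parameter here, not an assertion.
        """
        t = np.asarray(t, dtype=float)
        rising = self.rise(t)
        if not relax:
            return rising
        f = self.frac_fast
        dt = t - stim_s
        decay = f * (1.0 - np.exp(-stim_s / self.tau_fast_s)) * np.exp(
            -np.maximum(dt, 0.0) / self.tau_fast_s
        ) + (1.0 - f) * (1.0 - np.exp(-stim_s / self.tau_slow_s)) * np.exp(
            -np.maximum(dt, 0.0) / self.tau_slow_s
        )
        return np.where(t < stim_s, rising, decay)


#: Kinetics of the alkaline response category (fast 250.2 ms, slow 14.19 s).
ALKALINE_KINETICS = Kinetics(tau_fast_s=0.2502, tau_slow_s=14.19, frac_fast=0.5)

#: Kinetics of the acidic response category (fast 231.0 ms, slow 6.99 s).
ACIDIC_KINETICS = Kinetics(tau_fast_s=0.2310, tau_slow_s=6.99, frac_fast=0.5)


@dataclass
class GroundTruth:
    """Generating parameters of a simulated sensor + experiment.

    ``response_field`` holds the signed evoked pH amplitude per
    (row, col, angle): alkaline responses positive, acidic negative.  It is
    all-zero for the HEPES null condition.
    """

    geometry: SensorGeometry
    sensitivity_map: np.ndarray  # mV per pH, > 0, shape (n_rows, n_cols)
    offset_map: np.ndarray  # mV at pH 7.0
    defective_mask: np.ndarray  # bool
    stuck_voltage_mv: np.ndarray  # constant output of defective pixels
    response_field: np.ndarray  # pH amplitude, (n_rows, n_cols, n_angles)
    angles_deg: np.ndarray  # angle labels of the response-field axis
    alkaline_kinetics: Kinetics = ALKALINE_KINETICS
    acidic_kinetics: Kinetics = ACIDIC_KINETICS
    noise_sd_ph: float = 0.0
    inserted_rows: int = 0
    relax: bool = True

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        for name in ("sensitivity_map", "offset_map", "defective_mask", "stuck_voltage_mv"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise InvalidParameterError(f"{name} shape {arr.shape} != {shape}")
            setattr(self, name, arr)
        self.response_field = np.asarray(self.response_field, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.response_field.shape != shape + (self.angles_deg.size,):
            raise InvalidParameterError("response_field shape inconsistent with geometry/angles")
        if np.any(self.sensitivity_map <= 0):
            raise InvalidParameterError("sensitivity_map must be positive everywhere")
        if self.noise_sd_ph < 0:
            raise InvalidParameterError("noise_sd_ph must be >= 0")
        if not 0 <= self.inserted_rows <= self.geometry.n_rows:
            raise InvalidParameterError("inserted_rows out of range")

    def transduce(self, ph: np.ndarray) -> np.ndarray:
        """Forward voltage map(s) for pH map(s): V = offset - S * (pH - 7)."""
        return self.offset_map - self.sensitivity_map * (np.asarray(ph) - 7.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-gratings presentation schedule.

    ``events`` is the full presentation order: one ``(onset_s, angle_deg)``
    per trial, onsets spaced by ``stim_s + interval_s`` starting at
    ``pre_phase_s`` (a gray screen precedes the first trial).
    """

    pre_phase_s: float = 120.0
    stim_s: float = 2.0
    interval_s: float = 8.0
    n_trials_per_angle: int = 30
    angles_deg: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
    events: tuple[tuple[float, float], ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.angles_deg)) != len(self.angles_deg):
            raise InvalidParameterError("angles must be distinct")
        if self.stim_s <= 0 or self.interval_s <= 0 or self.pre_phase_s < 0:
            raise InvalidParameterError("durations must be positive (pre_phase_s >= 0)")
        if self.n_trials_per_angle < 1:
            raise InvalidParameterError("n_trials_per_angle must be >= 1")
        if self.events:
            self.validate_events()

    def validate_events(self) -> None:
        """Check the event list against the protocol invariants."""
        n_expected = self.n_trials_per_angle * len(self.angles_deg)
        if len(self.events) != n_expected:
            raise FormatError(
                f"events: expected {n_expected} trials, found {len(self.events)}"
            )
        onsets = np.array([e[0] for e in self.events])
        angles = np.array([e[1] for e in self.events])
        if onsets.size and not np.isclose(onsets[0], self.pre_phase_s):
            raise FormatError("events: first onset must equal pre_phase_s")
        period = self.stim_s + self.interval_s
        if onsets.size > 1 and not np.allclose(np.diff(onsets), period):
            raise FormatError("events: consecutive onsets must differ by stim_s + interval_s")
        for angle in self.angles_deg:
            n = int(np.sum(angles == angle))
            if n != self.n_trials_per_angle:
                raise FormatError(
                    f"events: angle {angle} appears {n} times, expected {self.n_trials_per_angle}"
                )

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_angle * len(self.angles_deg)

    @property
    def total_duration_s(self) -> float:
        return self.pre_phase_s + self.n_trials * (self.stim_s + self.interval_s)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=float)

    @property
    def trial_angles(self) -> np.ndarray:
        return np.array([e[1] for e in self.events], dtype=float)


VALID_CONDITIONS = ("brain", "hepes", "calibration", "illumination")


@dataclass
class Recording:
    """A time-stamped frame movie from the sensor.

    ``frames`` carries voltages in mV (``units='mV'``) or converted pH
    values (``units='pH'``); voltage frames are float32 to match the
    on-disk layout bit for bit.
    """

    frames: np.ndarray  # (n_frames, n_rows, n_cols)
    timestamps: np.ndarray  # seconds, strictly increasing
    geometry: SensorGeometry
    condition: str
    units: str = "mV"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames)
        if self.units == "mV" and self.frames.dtype != np.float32:
            self.frames = self.frames.astype(np.float32)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be 3-D (n_frames, n_rows, n_cols)")
        if self.frames.shape[0] < 1:
            raise FormatError("recording must contain at least one frame")
        if self.frames.shape[1:] != self.geometry.shape:
            raise FormatError(
                f"frame shape {self.frames.shape[1:]} != geometry {self.geometry.shape}"
            )
        if self.timestamps.shape != (self.frames.shape[0],):
            raise FormatError("timestamps length must equal the frame count")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.condition not in VALID_CONDITIONS:
            raise InvalidParameterError(
                f"condition must be one of {VALID_CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def with_frames(self, frames: np.ndarray, units: str) -> "Recording":
        return Recording(
            frames=frames,
            timestamps=self.timestamps,
            geometry=self.geometry,
            condition=self.condition,
            units=units,
            metadata=dict(self.metadata),
        )


@dataclass
class CalibrationSet:
    """Averaged voltage readouts in buffers of known pH."""

    buffer_phs: np.ndarray  # (n_buffers,)
    voltages: np.ndarray  # mV, (n_buffers, n_rows, n_cols)
    geometry: SensorGeometry
    n_replicates: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.buffer_phs = np.asarray(self.buffer_phs, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.buffer_phs.ndim != 1:
            raise FormatError("buffer_phs must be 1-D")
        if len(set(self.buffer_phs.tolist())) != self.buffer_phs.size:
            raise FormatError("buffer_phs must be distinct")
        if self.voltages.shape != (self.buffer_phs.size,) + self.geometry.shape:
            raise FormatError(
                f"voltages shape {self.voltages.shape} inconsistent with buffers/geometry"
            )

    @property
    def n_buffers(self) -> int:
        return self.buffer_phs.size
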