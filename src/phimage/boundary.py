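"""Insertion-boundary detection from the photoelectric light response.

Pixels left above the brain surface respond strongly to white-light
illumination (photoelectric effect) while inserted pixels are shielded by
tissue.  Subtracting the time-averaged pre-exposure voltage from the
time-averaged voltage during illumination gives a per-pixel difference
map with a step along the insertion axis; the first row (scanning from
the tip, row 0) whose column-median difference exceeds a threshold is the
boundary.  The default threshold is the midpoint between the profile's
robust low and high plateaus (parameter-free, gain-independent); a fixed
mV threshold is available as an override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InvalidParameterError, Recording, SensorGeometry

__all__ = ["BoundaryResult", "compute_difference_map", "detect_boundary"]


@dataclass
class BoundaryResult:
    """Detected insertion boundary.

    ``boundary_row`` is the first row index outside the brain; rows
    ``< boundary_row`` are inside.  ``insertion_depth_um`` is
    ``boundary_row * pixel_pitch_um``.
    """

    difference_map: np.ndarray  # mV
    boundary_row: int
    inside_mask: np.ndarray  # bool, True for inserted pixels
    insertion_depth_um: float
    threshold_mv: float
    method: str
    fully_inserted: bool = False
    row_profile: np.ndarray | None = None

    @property
    def insertion_depth_mm(self) -> float:
        return self.insertion_depth_um / 1000.0


def compute_difference_map(
    recording: Recording,
    pre_window_s: float = 10.0,
    exposure_window_s: float = 10.0,
) -> np.ndarray:
    """Exposure-mean minus pre-exposure-mean voltage, per pixel.

    The pre window is ``[0, pre_window_s)`` and the exposure window
    ``[pre_window_s, pre_window_s + exposure_window_s)``.
    """
    if pre_window_s <= 0 or exposure_window_s <= 0:
        raise InvalidParameterError("windows must be > 0")
    t = recording.timestamps
    end = pre_window_s + exposure_window_s
    if t[-1] + 1.0 / recording.geometry.frame_rate_hz < end - 1e-9:
        raise InvalidParameterError(
            f"recording ({t[-1]:.2f} s) does not span the requested windows ({end:.2f} s)"
        )
    pre = t < pre_window_s
    exp = (t >= pre_window_s) & (t < end)
    if not pre.any() or not exp.any():
        raise InvalidParameterError("a window contains no frames")
    frames = recording.frames.astype(np.float64)
    return frames[exp].mean(axis=0) - frames[pre].mean(axis=0)


def detect_boundary(
    difference_map: np.ndarray,
    geometry: SensorGeometry,
    method: str = "half_max",
    threshold_mv: float | None = None,
    min_step_mv: float = 1.0,
) -> BoundaryResult:
    """Locate the insertion boundary on the difference map.

    The row profile is the median across columns (robust to defective
    pixels).  ``method='half_max'`` thresholds at the midpoint between the
    profile's 10th and 90th percentiles; if the profile has no contrast
    (span below ``min_step_mv``) there is nothing above the brain and the
    result is flagged fully inserted.  ``method='fixed'`` uses
    ``threshold_mv`` directly; a profile that never crosses it also yields
    the fully-inserted flag with ``boundary_row = n_rows``.
    """
    diff = np.asarray(difference_map, dtype=float)
    if diff.shape != geometry.shape:
        raise InvalidParameterError("difference map shape does not match geometry")
    profile = np.nanmedian(diff, axis=1)
    if method == "half_max":
        lo = np.nanpercentile(profile, 10)
        hi = np.nanpercentile(profile, 90)
        if hi - lo < min_step_mv:
            return _result(diff, geometry, geometry.n_rows, float(hi), method, profile, True)
        threshold = 0.5 * (lo + hi)
    elif method == "fixed":
        if threshold_mv is None:
            raise InvalidParameterError("method='fixed' requires threshold_mv")
        threshold = float(threshold_mv)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    above = np.where(profile > threshold)[0]
    if above.size == 0:
        return _result(diff, geometry, geometry.n_rows, threshold, method, profile, True)
    return _result(diff, geometry, int(above[0]), threshold, method, profile, False)


def _result(diff, geometry, boundary_row, threshold, method, profile, fully_inserted):
    inside = np.zeros(geometry.shape, dtype=bool)
    inside[:boundary_row, :] = True
    return BoundaryResult(
        difference_map=diff,
        boundary_row=boundary_row,
        inside_mask=inside,
        insertion_depth_um=boundary_row * geometry.pixel_pitch_um,
        threshold_mv=float(threshold),
        method=method,
        fully_inserted=fully_inserted,
        row_profile=profile,
    )
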