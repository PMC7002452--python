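"""Per-pixel voltage–pH standard curves and everything derived from them.

Each pixel gets an ordinary-least-squares line fitted to its voltage
readouts in the calibration buffers (three points per pixel, unweighted —
with so few points robust fitting buys nothing).  The fitted line is
parametrized as ``V = intercept + slope * (pH - 7.0)``, so the intercept
is the voltage at neutral pH and the slope is signed per the transduction
convention (negative when the surface potential rises as pH falls).  The
reported device sensitivity is the mean |slope| over the five central
pixels — the center pixel plus its 4-neighbors.

Inter-pixel variation converts every pixel's buffer voltage to pH through
one array-median curve (not each pixel's own curve, which would nullify
the statistic by construction) so that pixel-to-pixel transduction
differences show up as pH spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CalibrationSet,
    InvalidParameterError,
    Recording,
    SensorGeometry,
)

__all__ = [
    "CalibrationModel",
    "BufferComparison",
    "fit_standard_curves",
    "detect_defective_pixels",
    "interpixel_variation",
    "interpixel_variation_study",
    "compare_buffer_distributions",
    "convert_voltage_to_ph",
]

_MAD_SCALE = 1.4826  # scaled MAD -> SD for a normal distribution


@dataclass
class CalibrationModel:
    """Fitted per-pixel standard curves plus the defective-pixel mask."""

    slope_map: np.ndarray  # mV per pH, signed
    intercept_map: np.ndarray  # mV at pH 7.0
    defective_mask: np.ndarray  # bool
    central_sensitivity: float  # mean |slope| over the five central pixels
    fit_residuals: np.ndarray  # mV, (n_buffers, n_rows, n_cols)
    buffer_phs: np.ndarray
    geometry: SensorGeometry

    def central_pixels(self) -> list[tuple[int, int]]:
        return _central_pixels(self.geometry)


def _central_pixels(geometry: SensorGeometry) -> list[tuple[int, int]]:
    """Center pixel plus 4-neighbors, clipped to the array."""
    r0, c0 = geometry.n_rows // 2, geometry.n_cols // 2
    cand = [(r0, c0), (r0 - 1, c0), (r0 + 1, c0), (r0, c0 - 1), (r0, c0 + 1)]
    return [
        (r, c) for r, c in cand if 0 <= r < geometry.n_rows and 0 <= c < geometry.n_cols
    ]


def _central_sensitivity(
    slope_map: np.ndarray, defective: np.ndarray, geometry: SensorGeometry
) -> float:
    pix = _central_pixels(geometry)
    vals = [abs(slope_map[r, c]) for r, c in pix if not defective[r, c]]
    return float(np.mean(vals)) if vals else float("nan")


def fit_standard_curves(calset: CalibrationSet) -> CalibrationModel:
    """OLS line per pixel over (pH, voltage).

    Closed-form normal equations, vectorized over the pixel grid:
    ``slope = S_xy / S_xx`` with x = pH - 7.0.
    """
    if calset.n_buffers < 2:
        raise InvalidParameterError("need at least 2 buffers to fit a line")
    x = calset.buffer_phs - 7.0
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise InvalidParameterError("all calibration buffers have identical pH (singular fit)")
    y = calset.voltages  # (n_buffers, n_rows, n_cols)
    xc = (x - x.mean())[:, None, None]
    slope = np.sum(xc * (y - y.mean(axis=0)), axis=0) / sxx
    intercept = y.mean(axis=0) - slope * x.mean()
    residuals = y - (intercept[None] + slope[None] * x[:, None, None])
    defective = np.zeros(calset.geometry.shape, dtype=bool)
    return CalibrationModel(
        slope_map=slope,
        intercept_map=intercept,
        defective_mask=defective,
        central_sensitivity=_central_sensitivity(slope, defective, calset.geometry),
        fit_residuals=residuals,
        buffer_phs=calset.buffer_phs.copy(),
        geometry=calset.geometry,
    )


def detect_defective_pixels(
    model: CalibrationModel, mad_threshold: float = 5.0
) -> np.ndarray:
    """Flag pixels with aberrant or non-monotonic calibration responses.

    A pixel is defective if its slope deviates from the array median by
    more than ``mad_threshold`` robust SDs (scaled median absolute
    deviation), or if its buffer response reverses direction against the
    array-wide trend by more than the robust residual scale.  The returned
    mask replaces the model's prior mask, and the central sensitivity is
    recomputed without the flagged pixels.
    """
    if mad_threshold <= 0:
        raise InvalidParameterError("mad_threshold must be > 0")
    slope = model.slope_map
    med = float(np.median(slope))
    dev = np.abs(slope - med)
    robust_sd = _MAD_SCALE * float(np.median(dev))
    # degenerate (noiseless) arrays: any measurable deviation is aberrant
    floor = 1e-9 * max(1.0, abs(med))
    robust_sd = max(robust_sd, floor)
    outlier = dev > mad_threshold * robust_sd

    # non-monotonicity: consecutive buffer readouts (pH-sorted) moving
    # against the median trend by more than the residual noise scale
    order = np.argsort(model.buffer_phs)
    volts = (
        model.intercept_map[None]
        + model.slope_map[None] * (model.buffer_phs[order, None, None] - 7.0)
        + model.fit_residuals[order]
    )
    diffs = np.diff(volts, axis=0)
    resid_sd = _MAD_SCALE * float(np.median(np.abs(model.fit_residuals)))
    tol = 5.0 * max(resid_sd, floor)
    trend = np.sign(med) if med != 0 else 1.0
    non_monotonic = np.any(diffs * trend < -tol, axis=0)

    mask = outlier | non_monotonic
    model.defective_mask = mask
    model.central_sensitivity = _central_sensitivity(slope, mask, model.geometry)
    return mask


def _median_curve(model: CalibrationModel) -> tuple[float, float]:
    good = ~model.defective_mask
    if not np.any(good):
        raise InvalidParameterError("all pixels defective: no data for the median curve")
    return (
        float(np.median(model.slope_map[good])),
        float(np.median(model.intercept_map[good])),
    )


def interpixel_variation(
    calset: CalibrationSet, model: CalibrationModel
) -> np.ndarray:
    """Per-buffer SD (pH units) of pixel readouts across the array.

    Each pixel's buffer voltage is converted to pH through the array-median
    curve; the SD is taken across non-defective pixels.
    """
    good = ~model.defective_mask
    if np.sum(good) < 2:
        raise InvalidParameterError("need at least 2 non-defective pixels")
    b_med, a_med = _median_curve(model)
    ph = 7.0 + (calset.voltages - a_med) / b_med
    return np.array([np.std(ph[b][good], ddof=1) for b in range(calset.n_buffers)])


def interpixel_variation_study(
    devices: Sequence[tuple[CalibrationSet, CalibrationModel]],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over devices of the per-device, per-buffer pixel SD."""
    sds = np.array([interpixel_variation(cs, m) for cs, m in devices])
    return sds.mean(axis=0), sds.std(axis=0, ddof=1)


@dataclass
class BufferComparison:
    """One-way ANOVA + Tukey HSD across buffer groups of converted values."""

    buffer_phs: np.ndarray
    group_means: np.ndarray
    group_sds: np.ndarray
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # columns: ph_a, ph_b, p_adj

    def all_pairs_distinct(self, alpha: float = 0.05) -> bool:
        return bool((self.tukey["p_adj"] < alpha).all())


def compare_buffer_distributions(
    calset: CalibrationSet, model: CalibrationModel
) -> BufferComparison:
    """Are the per-pixel converted values at the buffers statistically distinct?"""
    if calset.n_buffers < 2:
        raise InvalidParameterError("need at least 2 buffers to compare")
    good = ~model.defective_mask
    if np.sum(good) < 2:
        raise InvalidParameterError("need at least 2 non-defective pixels")
    b_med, a_med = _median_curve(model)
    groups = [7.0 + (calset.voltages[b][good] - a_med) / b_med for b in range(calset.n_buffers)]
    f_stat, p_val = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "ph_a": calset.buffer_phs[i],
                    "ph_b": calset.buffer_phs[j],
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    n_total = sum(g.size for g in groups)
    return BufferComparison(
        buffer_phs=calset.buffer_phs.copy(),
        group_means=np.array([g.mean() for g in groups]),
        group_sds=np.array([g.std(ddof=1) for g in groups]),
        anova_f=float(f_stat),
        anova_p=float(p_val),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        tukey=pd.DataFrame(rows),
    )


def convert_voltage_to_ph(
    recording: Recording, model: CalibrationModel, curve: str = "per_pixel"
) -> Recording:
    """Invert the transduction: pH = 7.0 + (V - intercept) / slope.

    ``curve='per_pixel'`` uses each pixel's own standard curve (default);
    ``'median'`` applies the single array-median curve to every pixel.
    Defective pixels become NaN and stay NaN downstream.
    """
    if recording.geometry != model.geometry:
        raise InvalidParameterError("recording geometry does not match calibration model")
    if recording.condition == "calibration":
        raise InvalidParameterError("cannot pH-convert a calibration recording")
    if curve == "per_pixel":
        slope, intercept = model.slope_map, model.intercept_map
    elif curve == "median":
        b_med, a_med = _median_curve(model)
        slope = np.full(model.geometry.shape, b_med)
        intercept = np.full(model.geometry.shape, a_med)
    else:
        raise InvalidParameterError(f"curve must be 'per_pixel' or 'median', got {curve!r}")
    with np.errstate(divide="ignore", invalid="ignore"):  # stuck pixels: slope ~ 0
        ph = 7.0 + (recording.frames.astype(np.float64) - intercept[None]) / slope[None]
    ph[:, model.defective_mask] = np.nan
    out = recording.with_frames(ph, units="pH")
    out.metadata["conversion_curve"] = curve
    return out
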