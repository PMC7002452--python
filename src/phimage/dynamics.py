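"""Peri-stimulus time histograms and pH transient kinetics.

For every (pixel, angle) the movie is cut into onset-aligned snippets
spanning pre-stim (2 s before onset), stim (2 s) and post-stim (4 s by
default).  Each trial snippet is baseline-referenced by subtracting its
own pre-window mean, then trials are averaged bin-wise (bin width = one
frame period) into the PSTH.  For trial 1 the pre window falls in the
tail of the 120 s gray pre-phase, which is exactly what it is for.

Responses are categorized per (pixel, angle) as alkaline / acidic /
neutral by a two-sample t-test between the per-trial pre-stim means and
stim means, and category-mean traces are fitted with a rising
two-component exponential

    y(t) = a_f * (1 - exp(-t / tau_f)) + a_s * (1 - exp(-t / tau_s))

by multi-start nonlinear least squares over the window [0, 6] s (stim +
post).  The slow time constants exceed that window, so they are
extrapolated quantities with correspondingly weaker identifiability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .boundary import BoundaryResult
from .types import FormatError, InvalidParameterError, Recording, StimulusProtocol

__all__ = [
    "PSTHSet",
    "BiexpFit",
    "build_psth",
    "psth_from_trial_traces",
    "trial_window_means",
    "categorize_responses",
    "sort_pixels",
    "biexp_rise",
    "fit_biexponential",
    "summarize_categories",
    "CATEGORY_ACIDIC",
    "CATEGORY_NEUTRAL",
    "CATEGORY_ALKALINE",
]

CATEGORY_ACIDIC, CATEGORY_NEUTRAL, CATEGORY_ALKALINE = -1, 0, 1

DEFAULT_WINDOWS_S = (2.0, 2.0, 4.0)  # pre, stim, post


@dataclass
class PSTHSet:
    """Trial-averaged, baseline-referenced response time courses.

    ``traces`` has the time bins on the last axis; leading axes identify
    the unit (e.g. ``(n_rows, n_cols, n_angles)`` for a movie-derived set,
    or ``(n_pixels,)`` for a direct trial-trace study).
    """

    traces: np.ndarray  # (..., n_bins)
    time_axis: np.ndarray  # seconds relative to onset
    windows_s: tuple[float, float, float]  # (pre, stim, post)
    n_trials: int
    angles_deg: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.time_axis.size

    def stim_slice(self) -> np.ndarray:
        return (self.time_axis >= 0.0) & (self.time_axis < self.windows_s[1])


def _aligned_slices(
    ph_movie: Recording, onsets: np.ndarray, start_rel: float, n_bins: int
) -> list[slice]:
    period = 1.0 / ph_movie.geometry.frame_rate_hz
    mids = ph_movie.timestamps + 0.5 * period
    slices = []
    for onset in onsets:
        i0 = int(np.searchsorted(mids, onset + start_rel))
        if i0 < 0 or i0 + n_bins > ph_movie.n_frames:
            raise FormatError(
                f"movie missing frames for the trial window at onset {onset:.2f} s"
            )
        slices.append(slice(i0, i0 + n_bins))
    return slices


def build_psth(
    ph_movie: Recording,
    protocol: StimulusProtocol,
    boundary: BoundaryResult | None = None,
    windows_s: tuple[float, float, float] = DEFAULT_WINDOWS_S,
) -> PSTHSet:
    """Movie-derived PSTHs per (pixel, angle); outside-brain pixels are NaN."""
    if ph_movie.units != "pH":
        raise InvalidParameterError("build_psth expects a pH-converted movie")
    pre_s, stim_s, post_s = windows_s
    if pre_s <= 0 or stim_s <= 0 or post_s <= 0:
        raise InvalidParameterError("PSTH windows must be > 0")
    rate = ph_movie.geometry.frame_rate_hz
    n_bins = int(round((pre_s + stim_s + post_s) * rate))
    n_pre = int(round(pre_s * rate))
    frames = ph_movie.frames.astype(np.float64, copy=False)
    if boundary is not None:
        frames = frames.copy()
        frames[:, ~boundary.inside_mask] = np.nan

    angles = np.asarray(protocol.angles_deg, dtype=float)
    shape = ph_movie.geometry.shape
    traces = np.empty(shape + (angles.size, n_bins))
    time_axis = (np.arange(n_bins) - n_pre) / rate
    onsets = protocol.onsets_s
    trial_angles = protocol.trial_angles
    n_per_angle = None
    for k, angle in enumerate(angles):
        sel = np.where(trial_angles == angle)[0]
        slices = _aligned_slices(ph_movie, onsets[sel], -pre_s, n_bins)
        acc = np.zeros(shape + (n_bins,))
        for sl in slices:
            snip = np.moveaxis(frames[sl], 0, -1)  # (rows, cols, bins)
            baseline = snip[..., :n_pre].mean(axis=-1, keepdims=True)
            acc += snip - baseline
        traces[:, :, k, :] = acc / sel.size
        n_per_angle = sel.size
    return PSTHSet(
        traces=traces,
        time_axis=time_axis,
        windows_s=windows_s,
        n_trials=int(n_per_angle),
        angles_deg=angles,
    )


def psth_from_trial_traces(
    traces: np.ndarray,
    time_axis: np.ndarray,
    windows_s: tuple[float, float, float] = DEFAULT_WINDOWS_S,
) -> PSTHSet:
    """Average pre-referenced trial traces (..., n_trials, n_bins) into a PSTH."""
    traces = np.asarray(traces, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    if traces.shape[-1] != time_axis.size:
        raise InvalidParameterError("trace length does not match time axis")
    pre = time_axis < 0.0
    if not pre.any():
        raise InvalidParameterError("time axis has no pre-onset bins for baselining")
    referenced = traces - traces[..., pre].mean(axis=-1, keepdims=True)
    return PSTHSet(
        traces=referenced.mean(axis=-2),
        time_axis=time_axis,
        windows_s=windows_s,
        n_trials=traces.shape[-2],
    )


def trial_window_means(
    ph_movie: Recording,
    protocol: StimulusProtocol,
    boundary: BoundaryResult | None = None,
    windows_s: tuple[float, float, float] = DEFAULT_WINDOWS_S,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial pre-stim and stim means, grouped by angle.

    Returns ``(pre_means, stim_means, angles)`` with the mean arrays
    shaped ``(n_rows, n_cols, n_angles, n_trials_per_angle)``.
    """
    pre_s, stim_s, _ = windows_s
    rate = ph_movie.geometry.frame_rate_hz
    period = 1.0 / rate
    mids = ph_movie.timestamps + 0.5 * period
    frames = ph_movie.frames.astype(np.float64, copy=False)
    if boundary is not None:
        frames = frames.copy()
        frames[:, ~boundary.inside_mask] = np.nan
    angles = np.asarray(protocol.angles_deg, dtype=float)
    shape = ph_movie.geometry.shape
    n_per = protocol.n_trials_per_angle
    pre_means = np.empty(shape + (angles.size, n_per))
    stim_means = np.empty(shape + (angles.size, n_per))
    onsets = protocol.onsets_s
    trial_angles = protocol.trial_angles
    for k, angle in enumerate(angles):
        for j, i in enumerate(np.where(trial_angles == angle)[0]):
            onset = onsets[i]
            pre_sel = (mids >= onset - pre_s) & (mids < onset)
            stim_sel = (mids >= onset) & (mids < onset + stim_s)
            if not pre_sel.any() or not stim_sel.any():
                raise FormatError(f"movie missing frames around trial onset {onset:.2f} s")
            pre_means[:, :, k, j] = frames[pre_sel].mean(axis=0)
            stim_means[:, :, k, j] = frames[stim_sel].mean(axis=0)
    return pre_means, stim_means, angles


def categorize_responses(
    pre_means: np.ndarray, stim_means: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Alkaline / acidic / neutral per (pixel, angle).

    Two-sample t-test between the per-trial pre-stim means and stim means
    (trial axis last): alkaline if significantly increased, acidic if
    significantly decreased, else neutral.  Zero variance in both groups
    (or any non-finite p) is neutral.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if pre_means.shape != stim_means.shape:
        raise InvalidParameterError("pre/stim mean arrays must have identical shape")
    if pre_means.shape[-1] < 2:
        raise InvalidParameterError("need at least 2 trials per angle")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t_stat, p_val = stats.ttest_ind(stim_means, pre_means, axis=-1)
    diff = stim_means.mean(axis=-1) - pre_means.mean(axis=-1)
    cats = np.zeros(diff.shape, dtype=np.int8)
    # zero variance in both groups is neutral by definition (relative floor:
    # numerically constant groups count as constant)
    scale = 1e-9 * np.maximum(np.abs(diff), 1e-6)
    some_var = (stim_means.std(axis=-1) > scale) | (pre_means.std(axis=-1) > scale)
    sig = np.isfinite(p_val) & (p_val < alpha) & some_var
    cats[sig & (diff > 0)] = CATEGORY_ALKALINE
    cats[sig & (diff < 0)] = CATEGORY_ACIDIC
    return cats


_CATEGORY_RANK = {CATEGORY_ALKALINE: 0, CATEGORY_NEUTRAL: 1, CATEGORY_ACIDIC: 2}


def sort_pixels(psth: PSTHSet, categories: np.ndarray) -> np.ndarray:
    """Display order of all (pixel, angle) traces.

    Primary key: category (alkaline, neutral, acidic).  Secondary key:
    median trace value within the stim window, descending.  Ties broken
    by (row, col, angle) index.  Returns an ``(n_units, ndim)`` array of
    multi-indices into the trace array, a permutation of all units.
    """
    lead_shape = psth.traces.shape[:-1]
    if categories.shape != lead_shape:
        raise InvalidParameterError("categories shape does not match PSTH units")
    stim = psth.stim_slice()
    medians = np.median(psth.traces[..., stim], axis=-1)
    idx = np.stack([a.ravel() for a in np.indices(lead_shape)], axis=1)
    ranks = np.vectorize(_CATEGORY_RANK.get)(categories.ravel())
    med = medians.ravel()
    med = np.where(np.isfinite(med), med, -np.inf)  # NaN traces sort last in key 2
    order = np.lexsort(tuple(idx[:, d] for d in reversed(range(idx.shape[1]))) + (-med, ranks))
    return idx[order]


def biexp_rise(t: np.ndarray, a_f: float, tau_f: float, a_s: float, tau_s: float) -> np.ndarray:
    """Rising two-component exponential, zero at t = 0."""
    t = np.asarray(t, dtype=float)
    return a_f * (1.0 - np.exp(-t / tau_f)) + a_s * (1.0 - np.exp(-t / tau_s))


@dataclass
class BiexpFit:
    """Result of a two-component exponential fit (tau_fast <= tau_slow)."""

    a_fast: float
    a_slow: float
    tau_fast_s: float
    tau_slow_s: float
    polarity: str | None
    rss: float
    converged: bool
    n_points: int


_TAU_GRID = (0.1, 0.3, 1.0, 3.0, 10.0)


def fit_biexponential(
    time_axis: np.ndarray,
    trace: np.ndarray,
    polarity: str | None = None,
    fit_window_s: float = 6.0,
) -> BiexpFit:
    """Fit the rising two-component exponential to an onset-aligned trace.

    Deterministic multi-start: time-constant pairs from a fixed grid, each
    with amplitudes initialized by linear projection (for a fixed pair of
    time constants the model is linear in the amplitudes), refined by
    bounded nonlinear least squares; the lowest-RSS solution is kept and
    the time constants ordered fast <= slow.  If no start converges the
    result carries ``converged=False`` and NaN parameters.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    trace = np.asarray(trace, dtype=float)
    sel = (time_axis >= 0.0) & (time_axis <= fit_window_s) & np.isfinite(trace)
    t, y = time_axis[sel], trace[sel]
    if t.size < 8:
        raise InvalidParameterError("need at least 8 points inside the fit window")

    def resid(params):
        a_f, tau_f, a_s, tau_s = params
        return biexp_rise(t, a_f, tau_f, a_s, tau_s) - y

    best = None
    bounds = ([-np.inf, 1e-3, -np.inf, 1e-3], [np.inf, 1e4, np.inf, 1e4])
    for i, tau_f0 in enumerate(_TAU_GRID):
        for tau_s0 in _TAU_GRID[i + 1 :]:
            design = np.column_stack(
                [1.0 - np.exp(-t / tau_f0), 1.0 - np.exp(-t / tau_s0)]
            )
            amp0, *_ = np.linalg.lstsq(design, y, rcond=None)
            try:
                sol = least_squares(
                    resid,
                    x0=[amp0[0], tau_f0, amp0[1], tau_s0],
                    bounds=bounds,
                    method="trf",
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        return BiexpFit(
            a_fast=np.nan,
            a_slow=np.nan,
            tau_fast_s=np.nan,
            tau_slow_s=np.nan,
            polarity=polarity,
            rss=np.nan,
            converged=False,
            n_points=t.size,
        )
    rss, (a_f, tau_f, a_s, tau_s) = best
    if tau_f > tau_s:
        a_f, a_s, tau_f, tau_s = a_s, a_f, tau_s, tau_f
    return BiexpFit(
        a_fast=float(a_f),
        a_slow=float(a_s),
        tau_fast_s=float(tau_f),
        tau_slow_s=float(tau_s),
        polarity=polarity,
        rss=rss,
        converged=True,
        n_points=t.size,
    )


CATEGORY_NAMES = {
    CATEGORY_ALKALINE: "alkaline",
    CATEGORY_NEUTRAL: "neutral",
    CATEGORY_ACIDIC: "acidic",
}


def summarize_categories(
    psth_sets: Sequence[PSTHSet],
    categories_list: Sequence[np.ndarray],
    fit_window_s: float = 6.0,
) -> dict[str, dict]:
    """Pool (pixel, angle) traces by category across runs and fit kinetics.

    Concatenates every run's traces per category, averages them into one
    category-mean trace, and fits the two-component exponential to the
    alkaline and acidic means.  Returns, per category name, the pooled
    mean trace, member count and fit (None for neutral or empty).
    """
    if not psth_sets:
        raise InvalidParameterError("no PSTH sets supplied")
    time_axis = psth_sets[0].time_axis
    for ps in psth_sets[1:]:
        if ps.time_axis.shape != time_axis.shape or not np.allclose(
            ps.time_axis, time_axis
        ):
            raise InvalidParameterError("PSTH sets have inconsistent time axes")
    out: dict[str, dict] = {}
    for code, name in CATEGORY_NAMES.items():
        member_traces = []
        for ps, cats in zip(psth_sets, categories_list):
            flat = ps.traces.reshape(-1, ps.n_bins)
            sel = (cats.ravel() == code) & np.all(np.isfinite(flat), axis=1)
            if sel.any():
                member_traces.append(flat[sel])
        if not member_traces:
            warnings.warn(f"category {name!r} has no members; skipped", stacklevel=2)
            out[name] = {"trace": None, "n_members": 0, "fit": None}
            continue
        pooled = np.concatenate(member_traces, axis=0)
        mean_trace = pooled.mean(axis=0)
        fit = None
        if code != CATEGORY_NEUTRAL:
            fit = fit_biexponential(
                time_axis, mean_trace, polarity=name, fit_window_s=fit_window_s
            )
        out[name] = {"trace": mean_trace, "n_members": pooled.shape[0], "fit": fit}
    return out
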