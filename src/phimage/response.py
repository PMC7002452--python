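"""Trial segmentation and the per-pixel visual-response statistic.

For each trial the pH movie is split into a stimulation window
``[onset, onset + stim_s)`` and the following interval window
``[onset + stim_s, onset + stim_s + interval_s)`` (the inter-trial
interval is attributed to the trial it follows; the 120 s gray pre-phase
precedes trial 1 and belongs to no trial).  A frame belongs to a window
iff its timestamp midpoint falls inside — half-open windows plus midpoint
inclusion resolve edge ties deterministically.

From the per-trial window means, per pixel:

    pH_interval_theta = mean over an angle's trials of the interval means
    pH_interval       = mean over angles of pH_interval_theta
    dpH_trial         = pH_stim_trial - pH_interval
    dpH_theta         = mean over an angle's trials of dpH_trial
    dpH               = mean over angles of dpH_theta
    ddpH              = dpH_theta - dpH          (response at each angle)
    ddpH_trial        = dpH_trial - dpH          (response at each trial)

Two identities follow and are enforced by tests: the mean of ddpH over
angles is exactly zero at every finite pixel, and the per-angle trial
mean of ddpH_trial equals that angle's ddpH.  Trial counts (30) and angle
counts (8) generalize to whatever the protocol holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import BoundaryResult
from .types import InvalidParameterError, Recording, StimulusProtocol

__all__ = [
    "TrialMatrix",
    "ResponseMaps",
    "TruncatedTrialError",
    "segment_trials",
    "compute_response_maps",
    "compute_trial_responses",
]


class TruncatedTrialError(ValueError):
    """A trial's windows extend past the end of the movie."""

    def __init__(self, trial_indices):
        self.trial_indices = list(trial_indices)
        super().__init__(
            f"trials extend past the end of the movie: {self.trial_indices}"
        )


@dataclass
class TrialMatrix:
    """Per-trial window means, per pixel; masked pixels are NaN."""

    ph_stim: np.ndarray  # (n_rows, n_cols, n_trials)
    ph_interval_trial: np.ndarray  # (n_rows, n_cols, n_trials)
    trial_angles: np.ndarray  # (n_trials,)
    angles_deg: np.ndarray  # distinct angles in protocol order
    n_frames_used: np.ndarray  # (n_trials, 2): [stim, interval] counts

    @property
    def n_trials(self) -> int:
        return self.trial_angles.size


@dataclass
class ResponseMaps:
    """The seven per-pixel response quantities (pixel axes first)."""

    ph_interval_theta: np.ndarray  # (n_rows, n_cols, n_angles)
    ph_interval: np.ndarray  # (n_rows, n_cols)
    delta_ph_trial: np.ndarray  # (n_rows, n_cols, n_trials)
    delta_ph_theta: np.ndarray  # (n_rows, n_cols, n_angles)
    delta_ph: np.ndarray  # (n_rows, n_cols)
    delta_delta_ph: np.ndarray  # (n_rows, n_cols, n_angles)
    angles_deg: np.ndarray
    trial_angles: np.ndarray
    delta_delta_ph_trial: np.ndarray | None = None  # (n_rows, n_cols, n_trials)


def _window_means(
    frames: np.ndarray, mids: np.ndarray, start: float, stop: float
) -> tuple[np.ndarray, int]:
    sel = (mids >= start) & (mids < stop)
    n = int(sel.sum())
    if n == 0:
        return np.full(frames.shape[1:], np.nan), 0
    return frames[sel].mean(axis=0), n


def segment_trials(
    ph_movie: Recording,
    protocol: StimulusProtocol,
    boundary: BoundaryResult | None = None,
    allow_truncated: bool = False,
) -> TrialMatrix:
    """Per-trial stimulation and interval means for every pixel.

    Pixels outside the brain (per ``boundary``) are NaN; NaN pixels in the
    movie (defective) propagate.  Trials whose windows extend past the end
    of the movie raise :class:`TruncatedTrialError` unless
    ``allow_truncated`` is set, in which case they are dropped.
    """
    if ph_movie.units != "pH":
        raise InvalidParameterError("segment_trials expects a pH-converted movie")
    frames = ph_movie.frames.astype(np.float64, copy=False)
    if boundary is not None:
        frames = frames.copy()
        frames[:, ~boundary.inside_mask] = np.nan
    period = 1.0 / ph_movie.geometry.frame_rate_hz
    mids = ph_movie.timestamps + 0.5 * period
    end_time = ph_movie.timestamps[-1] + period

    truncated = [
        i
        for i, (onset, _) in enumerate(protocol.events)
        if onset + protocol.stim_s + protocol.interval_s > end_time + 1e-9
    ]
    if truncated and not allow_truncated:
        raise TruncatedTrialError(truncated)
    keep = [i for i in range(len(protocol.events)) if i not in set(truncated)]

    shape = ph_movie.geometry.shape
    ph_stim = np.empty(shape + (len(keep),))
    ph_int = np.empty(shape + (len(keep),))
    counts = np.empty((len(keep), 2), dtype=int)
    angles = np.empty(len(keep))
    for j, i in enumerate(keep):
        onset, angle = protocol.events[i]
        stim_mean, n_stim = _window_means(frames, mids, onset, onset + protocol.stim_s)
        int_mean, n_int = _window_means(
            frames,
            mids,
            onset + protocol.stim_s,
            onset + protocol.stim_s + protocol.interval_s,
        )
        if n_stim == 0 or n_int == 0:
            raise TruncatedTrialError([i])
        ph_stim[:, :, j] = stim_mean
        ph_int[:, :, j] = int_mean
        counts[j] = (n_stim, n_int)
        angles[j] = angle
    return TrialMatrix(
        ph_stim=ph_stim,
        ph_interval_trial=ph_int,
        trial_angles=angles,
        angles_deg=np.asarray(protocol.angles_deg, dtype=float),
        n_frames_used=counts,
    )


def compute_response_maps(tm: TrialMatrix) -> ResponseMaps:
    """Reduce the trial matrix to the per-angle and per-pixel response maps."""
    angles = tm.angles_deg
    n_angles = angles.size
    shape = tm.ph_stim.shape[:2]
    ph_int_theta = np.empty(shape + (n_angles,))
    dph_theta = np.empty(shape + (n_angles,))

    groups = [np.where(tm.trial_angles == a)[0] for a in angles]
    for k, idx in enumerate(groups):
        if idx.size == 0:
            raise InvalidParameterError(f"angle {angles[k]} has zero trials")
        ph_int_theta[:, :, k] = tm.ph_interval_trial[:, :, idx].mean(axis=2)
    ph_interval = ph_int_theta.mean(axis=2)

    dph_trial = tm.ph_stim - ph_interval[:, :, None]
    for k, idx in enumerate(groups):
        dph_theta[:, :, k] = dph_trial[:, :, idx].mean(axis=2)
    dph = dph_theta.mean(axis=2)
    ddph = dph_theta - dph[:, :, None]
    return ResponseMaps(
        ph_interval_theta=ph_int_theta,
        ph_interval=ph_interval,
        delta_ph_trial=dph_trial,
        delta_ph_theta=dph_theta,
        delta_ph=dph,
        delta_delta_ph=ddph,
        angles_deg=angles.copy(),
        trial_angles=tm.trial_angles.copy(),
    )


def compute_trial_responses(tm: TrialMatrix, maps: ResponseMaps) -> np.ndarray:
    """Per-trial responses: ddpH_trial = dpH_trial - dpH (stored on the maps)."""
    if maps.delta_ph_trial.shape != tm.ph_stim.shape:
        raise InvalidParameterError("response maps were not computed from this trial matrix")
    ddph_trial = maps.delta_ph_trial - maps.delta_ph[:, :, None]
    maps.delta_delta_ph_trial = ddph_trial
    return ddph_trial
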