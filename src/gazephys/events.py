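"""Gaze-event segmentation and locomotion masking.

Raw eye/head traces are upsampled to a common rate, gaze is the sum of eye
and head position, and samples are classified as gaze shifts or fixations by
thresholding gaze speed at 0.2 deg/ms.  Periods of locomotion (body speed
> 3 cm/s after a 0.2 Hz low-pass, head lower than 18 cm, lasting more than
3 s) are excluded from analysis.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt

from .types import (
    FIXATION,
    SHIFT,
    AnalysisMask,
    ConfigError,
    GazeEvent,
    GazeTrace,
)

__all__ = [
    "resample_trace",
    "compute_gaze",
    "gaze_speed",
    "detect_events",
    "detect_locomotion",
    "apply_mask",
]


def resample_trace(trace: GazeTrace, target_rate: float = 200.0) -> GazeTrace:
    """Linearly resample every channel of ``trace`` to ``target_rate`` Hz.

    Endpoints are preserved; if the trace is already at the target rate it is
    returned unchanged.
    """
    if trace.n_samples < 2:
        raise ConfigError("resample_trace needs at least 2 samples")
    if target_rate <= 0:
        raise ConfigError("target_rate must be positive")
    if abs(trace.sample_rate - target_rate) < 1e-9:
        return trace
    t0, t1 = trace.timestamps[0], trace.timestamps[-1]
    n_out = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    new_t = t0 + np.arange(n_out) / target_rate

    def interp_cols(arr: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.interp(new_t, trace.timestamps, arr[:, j]) for j in range(arr.shape[1])]
        )

    return GazeTrace(
        timestamps=new_t,
        eye_pos=interp_cols(trace.eye_pos),
        head_pos=interp_cols(trace.head_pos),
        body_pos=interp_cols(trace.body_pos),
        head_height=np.interp(new_t, trace.timestamps, trace.head_height),
        sample_rate=target_rate,
    )


def compute_gaze(trace: GazeTrace) -> np.ndarray:
    """Gaze position (degrees): the per-sample sum of eye and head position."""
    if trace.eye_pos.shape != trace.head_pos.shape:
        raise ConfigError("eye and head channels are not aligned")
    return trace.eye_pos + trace.head_pos


def gaze_speed(gaze: np.ndarray, sample_rate: float) -> np.ndarray:
    """Gaze speed in deg/ms: magnitude of the central-difference 2D velocity."""
    gaze = np.atleast_2d(np.asarray(gaze, dtype=float))
    vel = np.gradient(gaze, axis=0) * sample_rate  # deg/s
    return np.hypot(vel[:, 0], vel[:, 1]) / 1000.0


def _merge_short_runs(labels: np.ndarray, min_samples: int) -> np.ndarray:
    """Flip runs shorter than ``min_samples`` into their neighbours."""
    if min_samples <= 1:
        return labels
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        bounds = np.flatnonzero(np.diff(labels)) + 1
        starts = np.r_[0, bounds]
        ends = np.r_[bounds, labels.size]
        lengths = ends - starts
        order = np.argsort(lengths)
        for k in order:
            if lengths[k] < min_samples and len(starts) > 1:
                labels[starts[k] : ends[k]] = ~labels[starts[k]]
                changed = True
                break
    return labels


def detect_events(
    gaze: np.ndarray,
    sample_rate: float,
    speed_threshold: float = 0.2,
    median_window_ms: float = 5.0,
    min_duration_ms: float = 5.0,
    t0: float = 0.0,
) -> list[GazeEvent]:
    """Segment a gaze trace into alternating shifts and fixations.

    Samples with gaze speed above ``speed_threshold`` (deg/ms) are labeled
    shift, the rest fixation; contiguous runs become events.  A short median
    pre-filter on speed suppresses single-sample threshold chatter and runs
    shorter than ``min_duration_ms`` are merged into their neighbour.  Shift
    amplitude is the gaze displacement from onset to offset.
    """
    gaze = np.atleast_2d(np.asarray(gaze, dtype=float))
    n = gaze.shape[0]
    if n < 2:
        raise ConfigError("detect_events needs at least 2 samples")
    if sample_rate < 200.0 - 1e-9:
        warnings.warn(
            f"sample rate {sample_rate:g} Hz is below the 200 Hz the segmentation "
            "assumes; short shifts may be missed",
            stacklevel=2,
        )
    dt = 1.0 / sample_rate
    speed = gaze_speed(gaze, sample_rate)
    k = max(3, int(round(median_window_ms * sample_rate / 1000.0)) | 1)
    speed_f = median_filter(speed, size=k, mode="nearest")
    labels = speed_f > speed_threshold
    min_samples = max(1, int(round(min_duration_ms * sample_rate / 1000.0)))
    labels = _merge_short_runs(labels, min_samples)

    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, bounds]
    ends = np.r_[bounds, n]  # exclusive sample index
    events: list[GazeEvent] = []
    times = t0 + np.arange(n) * dt
    for s, e in zip(starts, ends):
        onset = times[s]
        offset = times[e] if e < n else times[-1] + dt
        kind = SHIFT if labels[s] else FIXATION
        if kind == SHIFT:
            last = min(e, n - 1)
            amp = float(np.hypot(*(gaze[last] - gaze[s])))
            peak = float(speed[s:e].max())
            events.append(GazeEvent(SHIFT, onset, offset, peak_speed=peak, amplitude=amp))
        else:
            events.append(GazeEvent(FIXATION, onset, offset))
    return events


def detect_locomotion(
    body_pos: np.ndarray,
    head_height: np.ndarray,
    sample_rate: float,
    speed_cutoff: float = 3.0,
    lowpass_hz: float = 0.2,
    height_cutoff: float = 18.0,
    min_duration_s: float = 3.0,
    t0: float = 0.0,
) -> AnalysisMask:
    """Mask intervals of locomotion.

    An interval is excluded iff, simultaneously and contiguously for more
    than ``min_duration_s``: low-passed body speed exceeds ``speed_cutoff``
    (cm/s) and head height is below ``height_cutoff`` (cm).  The low-pass is
    a zero-phase second-order Butterworth at ``lowpass_hz``.
    """
    body_pos = np.atleast_2d(np.asarray(body_pos, dtype=float))
    head_height = np.asarray(head_height, dtype=float)
    if body_pos.shape[0] != head_height.size:
        raise ConfigError("body and head-height channels are not aligned")
    n = body_pos.shape[0]
    vel = np.gradient(body_pos, axis=0) * sample_rate
    speed = np.hypot(vel[:, 0], vel[:, 1])
    b, a = butter(2, lowpass_hz / (sample_rate / 2.0), btype="low")
    speed_f = filtfilt(b, a, speed)
    cond = (speed_f > speed_cutoff) & (head_height < height_cutoff)

    intervals: list[tuple[float, float]] = []
    dt = 1.0 / sample_rate
    bounds = np.flatnonzero(np.diff(cond)) + 1
    starts = np.r_[0, bounds]
    ends = np.r_[bounds, n]
    for s, e in zip(starts, ends):
        if cond[s] and (e - s) * dt > min_duration_s:
            intervals.append((t0 + s * dt, t0 + e * dt))
    return AnalysisMask(intervals=intervals, reason="locomotion")


def apply_mask(events: list[GazeEvent], mask: AnalysisMask) -> list[GazeEvent]:
    """Drop events whose onset falls inside an excluded interval."""
    if not mask.intervals:
        return list(events)
    onsets = np.array([e.onset for e in events])
    drop = mask.contains(onsets)
    return [e for e, d in zip(events, drop) if not d]
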