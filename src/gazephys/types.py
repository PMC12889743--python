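"""Shared data containers for the gaze/V1 analysis pipeline.

The containers here are deliberately thin: they hold validated numpy arrays
plus the metadata the downstream operations need (sample rates, degree/pixel
scales, event bookkeeping).  All heavier machinery lives in the operation
modules (:mod:`gazephys.events`, :mod:`gazephys.psth`, :mod:`gazephys.models`,
:mod:`gazephys.rf`).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SHIFT = "shift"
FIXATION = "fixation"

SACCADE_LOCKED = "saccade_locked"
TWO_STAGE = "two_stage"
NONE_MODEL = "none"
MODEL_KINDS = (SACCADE_LOCKED, TWO_STAGE)


class ConfigError(ValueError):
    """Raised for invalid configurations or malformed inputs."""


@dataclass
class GazeTrace:
    """Synchronized eye/head/body time series, uniformly sampled.

    Positions are in degrees (eye, head), centimeters (body, head height).
    ``eye_pos``/``head_pos``/``body_pos`` are ``(n, 2)`` arrays with
    (horizontal, vertical) / (x, y) columns.
    """

    timestamps: np.ndarray
    eye_pos: np.ndarray
    head_pos: np.ndarray
    body_pos: np.ndarray
    head_height: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.eye_pos = np.atleast_2d(np.asarray(self.eye_pos, dtype=float))
        self.head_pos = np.atleast_2d(np.asarray(self.head_pos, dtype=float))
        self.body_pos = np.atleast_2d(np.asarray(self.body_pos, dtype=float))
        self.head_height = np.asarray(self.head_height, dtype=float)
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        n = self.timestamps.size
        for name in ("eye_pos", "head_pos", "body_pos"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ConfigError(f"{name} length {arr.shape[0]} != {n} timestamps")
        if self.head_height.size != n:
            raise ConfigError("head_height length mismatch")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ConfigError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-9, rtol=0):
                raise ConfigError("timestamps are not uniform at sample_rate")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class GazeEvent:
    """One gaze shift or fixation interval. Times in seconds.

    ``amplitude`` (degrees, onset→offset gaze displacement) and
    ``peak_speed`` (deg/ms) are meaningful for shifts; fixations carry NaN.
    """

    kind: str
    onset: float
    offset: float
    peak_speed: float = np.nan
    amplitude: float = np.nan

    def __post_init__(self) -> None:
        if self.kind not in (SHIFT, FIXATION):
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if not self.offset > self.onset:
            raise ConfigError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def validate_event_sequence(events: Sequence[GazeEvent]) -> None:
    """Check ordering, non-overlap and alternation of an event list."""
    for prev, cur in zip(events, events[1:]):
        if cur.onset < prev.offset - 1e-9:
            raise ConfigError("events overlap")
        if cur.kind == prev.kind:
            raise ConfigError("consecutive events must alternate kinds")


def onsets_of(events: Iterable[GazeEvent], kind: str) -> np.ndarray:
    return np.array([e.onset for e in events if e.kind == kind], dtype=float)


@dataclass
class AnalysisMask:
    """Excluded time intervals (merged, non-overlapping), with reason tags."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    reason: str = "locomotion"

    def __post_init__(self) -> None:
        merged: list[tuple[float, float]] = []
        for start, end in sorted(self.intervals):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((float(start), float(end)))
        self.intervals = merged

    def contains(self, times: np.ndarray | float) -> np.ndarray:
        """Boolean membership of ``times`` in any excluded interval [start, end)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for start, end in self.intervals:
            out |= (t >= start) & (t < end)
        return out

    @property
    def total_duration(self) -> float:
        return float(sum(end - start for start, end in self.intervals))


@dataclass
class CosineComponent:
    """One raised-cosine lobe: amplitude ``a`` (normalized units, signed),
    width ``w`` (ms, full support) and latency ``l`` (ms, peak time)."""

    a: float
    w: float
    l: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ConfigError("raised-cosine width must be positive")


@dataclass
class BasisParams:
    """Suppression + enhancement raised-cosine parameters for one neuron."""

    suppression: CosineComponent
    enhancement: CosineComponent

    def __post_init__(self) -> None:
        if self.suppression.a > 0:
            raise ConfigError("suppression amplitude must be <= 0")
        if self.enhancement.a < 0:
            raise ConfigError("enhancement amplitude must be >= 0")

    def with_amplitudes(self, a_sup: float, a_enh: float) -> "BasisParams":
        return BasisParams(
            suppression=CosineComponent(a_sup, self.suppression.w, self.suppression.l),
            enhancement=CosineComponent(a_enh, self.enhancement.w, self.enhancement.l),
        )


@dataclass
class GroundTruth:
    """Oracle labels attached to a synthetic session.

    ``events`` tile the session (alternating fixations and shifts).
    ``true_model`` / ``true_basis`` / ``baseline_rate`` describe the generative
    firing-rate model; ``per_fixation_gain`` optionally scales the enhancement
    lobe of each fixation (two-stage model only).
    """

    events: list[GazeEvent]
    seed: int
    session_length: float
    true_model: str | None = None
    true_basis: BasisParams | None = None
    baseline_rate: float = 0.0
    per_fixation_gain: np.ndarray | None = None
    locomotion_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_event_sequence(self.events)
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be >= 0")

    def with_model(
        self,
        true_model: str,
        true_basis: BasisParams | None = None,
        baseline_rate: float = 10.0,
        per_fixation_gain: np.ndarray | None = None,
    ) -> "GroundTruth":
        """Return a copy carrying a generative spiking model."""
        if true_model not in MODEL_KINDS + (NONE_MODEL,):
            raise ConfigError(f"unknown model {true_model!r}")
        if true_model != NONE_MODEL and true_basis is None:
            raise ConfigError("true_basis required for a modulated model")
        return dataclasses.replace(
            self,
            true_model=true_model,
            true_basis=true_basis,
            baseline_rate=baseline_rate,
            per_fixation_gain=per_fixation_gain,
        )

    @property
    def shift_onsets(self) -> np.ndarray:
        return onsets_of(self.events, SHIFT)

    @property
    def fixation_onsets(self) -> np.ndarray:
        return onsets_of(self.events, FIXATION)

    @property
    def shifts(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == SHIFT]

    @property
    def fixations(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == FIXATION]


@dataclass
class SceneFrameSet:
    """World-camera frames with per-frame gaze bookkeeping.

    ``frames`` is ``(n_frames, h, w)`` grayscale in [0, 1];
    ``gaze_center_px`` holds (row, col) pixel coordinates of the gaze point in
    each frame; ``validity`` marks frames whose receptive-field crop lies
    fully inside the image.  ``tile_orientation``/``tile_sf`` record the wall
    grating patch under the RF crop center (generator ground truth).
    """

    frames: np.ndarray
    frame_times: np.ndarray
    gaze_center_px: np.ndarray
    validity: np.ndarray
    deg_per_px: float
    rf_offset_deg: tuple[float, float] = (0.0, 0.0)
    tile_orientation: np.ndarray | None = None
    tile_sf: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.deg_per_px <= 0:
            raise ConfigError("deg_per_px must be positive")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size >= 2 and np.any(np.diff(self.frame_times) <= 0):
            raise ConfigError("frame_times must be increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)
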