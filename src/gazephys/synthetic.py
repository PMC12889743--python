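"""Synthetic sessions: gaze traces, spike trains, gratings and scene frames.

The generators emulate the statistical structure the analysis assumes, with
ground-truth labels for oracle tests:

* Gaze behavior alternates fixations and gaze shifts.  During fixations the
  head drifts slowly and the eye counter-rotates (vestibulo-ocular reflex),
  so eye and head velocities are strongly anticorrelated while gaze stays
  still.  Gaze shifts are bell-shaped (sin²) velocity pulses shared by eye
  and head in the same direction; the labeled shift interval is exactly the
  span where gaze speed exceeds the segmentation threshold, so detector
  ground truth is well defined to within one sample.
* Spiking is an inhomogeneous Poisson process with rate
  r(t) = baseline · max(0, 1 + Σ f(t − anchor)), where the raised-cosine
  lobes follow either the saccade-locked or the two-stage model (or no
  modulation at all for the visually-unmodulated regime).
* Stimuli are sinusoidal gratings over a 12-orientation × 3-spatial-frequency
  grid, and the arena wall is a periodic patchwork of such gratings viewed
  through a head-centered world camera.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import models as models_mod
from . import rf as rf_mod
from .types import (
    FIXATION,
    NONE_MODEL,
    SHIFT,
    TWO_STAGE,
    BasisParams,
    ConfigError,
    CosineComponent,
    GazeEvent,
    GazeTrace,
    GroundTruth,
    SceneFrameSet,
)

__all__ = [
    "GazeConfig",
    "LocomotionSegment",
    "WallPattern",
    "generate_gaze_trace",
    "generate_spike_train",
    "generate_grating",
    "generate_tuning_session",
    "generate_scene_frames",
    "generate_dot_stimulus",
    "simulate_rf_neuron",
    "default_basis",
    "couple_gain_to_drive",
    "generate_coupled_session",
    "TuningResult",
    "CoupledSession",
]

ORIENTATIONS_DEG = tuple(range(0, 360, 30))[:12]  # 12 evenly-spaced orientations
SPATIAL_FREQS_CPD = (0.5, 1.0, 2.0)


@dataclass
class LocomotionSegment:
    """A planted bout of body movement; criteria met or violated on demand."""

    start_s: float
    end_s: float
    body_speed_cm_s: float = 6.0
    head_height_cm: float = 10.0

    @property
    def meets_criteria(self) -> bool:
        return (
            self.body_speed_cm_s > 3.0
            and self.head_height_cm < 18.0
            and self.end_s - self.start_s > 3.0
        )


@dataclass
class GazeConfig:
    """Conditions of a synthetic freely-moving session.

    Shift durations (time above the speed threshold) are uniform over
    ``shift_duration_ms`` and peak gaze speeds uniform over
    ``peak_speed_deg_per_ms``; fixation durations are uniform over
    ``fixation_duration_ms``.  Gaze shifts are head-dominant
    (``head_fraction`` of the displacement is carried by the head) and
    directions are biased back toward straight ahead beyond
    ``max_eccentricity_deg`` so gaze stays in a realistic range.
    """

    session_length_s: float = 60.0
    sample_rate: float = 200.0
    shift_duration_ms: tuple[float, float] = (20.0, 200.0)
    peak_speed_deg_per_ms: tuple[float, float] = (0.4, 1.0)
    fixation_duration_ms: tuple[float, float] = (100.0, 1000.0)
    n_shifts: int | None = None  # None = fill the session
    speed_threshold: float = 0.2  # deg/ms, matches the segmentation default
    head_fraction: float = 0.8
    max_eccentricity_deg: float = 30.0
    drift_pos_sigma_deg: float = 1.5
    drift_tau_s: float = 0.4
    eye_noise_deg_s: float = 1.0
    head_height_cm: float = 25.0
    arena_center_cm: tuple[float, float] = (100.0, 150.0)
    locomotion_segments: tuple[LocomotionSegment, ...] = ()

    def validate(self) -> None:
        if self.session_length_s <= 0 or self.sample_rate <= 0:
            raise ConfigError("session length and sample rate must be positive")
        if not (0.0 < self.head_fraction < 1.0):
            raise ConfigError("head_fraction must lie in (0, 1)")
        lo, hi = self.peak_speed_deg_per_ms
        if lo <= self.speed_threshold:
            raise ConfigError("peak speeds must exceed the segmentation threshold")
        segs = sorted(self.locomotion_segments, key=lambda s: s.start_s)
        for s in segs:
            if s.start_s < 0 or s.end_s > self.session_length_s or s.end_s <= s.start_s:
                raise ConfigError("locomotion segment outside the session")
        for a, b in zip(segs, segs[1:]):
            if b.start_s - a.end_s < 12.0:
                raise ConfigError("locomotion segments must be >= 12 s apart")


def _shift_profile_times(d: float, vp: float, thr: float) -> tuple[float, float]:
    """(total profile duration T, lead time) for a sin² speed pulse.

    The pulse v(t) = vp·sin²(πt/T) crosses ``thr`` at t* and T − t*; the time
    above threshold is the requested shift duration d, so
    T = d / (1 − (2/π)·asin(sqrt(thr/vp))) and the lead is (T − d)/2.
    """
    frac = 1.0 - (2.0 / math.pi) * math.asin(math.sqrt(thr / vp))
    T = d / frac
    return T, (T - d) / 2.0


def _ou_drift(n: int, dt: float, sigma: float, tau: float, rng, smooth_sigma_samples: float = 4.0):
    """Smoothed Ornstein–Uhlenbeck position drift, 2 channels."""
    x = np.zeros((n, 2))
    k = math.sqrt(2.0 * dt / tau)
    noise = rng.standard_normal((n, 2)) * sigma * k
    decay = 1.0 - dt / tau
    for i in range(1, n):
        x[i] = x[i - 1] * decay + noise[i]
    return gaussian_filter1d(x, smooth_sigma_samples, axis=0, mode="nearest")


def generate_gaze_trace(
    config: GazeConfig | None = None, seed: int = 0
) -> tuple[GazeTrace, GroundTruth]:
    """Generate a gaze trace plus its ground-truth event labels.

    Within fixations eye velocity mirrors head velocity (correlation near
    −1); during shifts eye and head move together and gaze speed exceeds the
    threshold exactly over the labeled interval.  Planted locomotion
    segments modulate body speed and head height so the locomotion criteria
    can be satisfied or violated on demand.
    """
    config = config or GazeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    fs, L = config.sample_rate, config.session_length_s
    dt = 1.0 / fs
    n = int(round(L * fs)) + 1
    t = np.arange(n) * dt
    thr = config.speed_threshold

    # --- event schedule -----------------------------------------------------
    events: list[GazeEvent] = []
    shift_specs = []  # (s0, T, vp, direction, amp)
    prev_off = 0.0
    prev_lead = 0.0
    gaze_anchor = np.zeros(2)
    count = 0
    while config.n_shifts is None or count < config.n_shifts:
        fd = rng.uniform(*config.fixation_duration_ms) / 1000.0
        d = rng.uniform(*config.shift_duration_ms) / 1000.0
        vp = rng.uniform(*config.peak_speed_deg_per_ms)
        T, lead = _shift_profile_times(d, vp, thr)
        fd = max(fd, prev_lead + lead + 0.01)  # keep profiles from overlapping
        onset = prev_off + fd
        s0 = onset - lead
        if s0 + T + 0.05 > L:
            break
        ecc = float(np.hypot(*gaze_anchor))
        if ecc > config.max_eccentricity_deg:
            ang = math.atan2(-gaze_anchor[1], -gaze_anchor[0]) + rng.normal(0.0, 0.6)
        else:
            ang = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(ang), math.sin(ang)])
        amp = vp * 1000.0 * T / 2.0  # deg; integral of the sin² pulse
        events.append(GazeEvent(FIXATION, prev_off, onset))
        events.append(GazeEvent(SHIFT, onset, onset + d, peak_speed=vp, amplitude=amp))
        shift_specs.append((s0, T, vp, direction, amp))
        gaze_anchor = gaze_anchor + amp * direction
        prev_off = onset + d
        prev_lead = lead
        count += 1
    if prev_off < L:
        events.append(GazeEvent(FIXATION, prev_off, L))

    # --- gaze position ------------------------------------------------------
    gaze = np.zeros((n, 2))
    for s0, T, vp, direction, amp in shift_specs:
        u = np.clip((t - s0) / T, 0.0, 1.0)
        s_curve = u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)
        gaze += amp * np.outer(s_curve, direction)

    drift = _ou_drift(n, dt, config.drift_pos_sigma_deg, config.drift_tau_s, rng)
    eye_noise = np.cumsum(
        rng.standard_normal((n, 2)) * config.eye_noise_deg_s * dt, axis=0
    )
    head = config.head_fraction * gaze + drift
    eye = (1.0 - config.head_fraction) * gaze - drift + eye_noise

    # --- body / head height -------------------------------------------------
    body = np.array(config.arena_center_cm) + _ou_drift(n, dt, 1.0, 5.0, rng, 50.0)
    head_height = config.head_height_cm + gaussian_filter1d(
        rng.standard_normal(n) * 0.2, 20.0, mode="nearest"
    )
    locomotion_truth: list[tuple[float, float]] = []
    margin, ramp = 5.0, 2.0
    for seg in config.locomotion_segments:
        t_lo = max(0.0, seg.start_s - margin)
        t_hi = min(L, seg.end_s + margin)
        sp = np.zeros(n)
        inside = (t >= t_lo) & (t <= t_hi)
        sp[inside] = seg.body_speed_cm_s
        up = inside & (t < t_lo + ramp)
        sp[up] = seg.body_speed_cm_s * 0.5 * (1 - np.cos(np.pi * (t[up] - t_lo) / ramp))
        down = inside & (t > t_hi - ramp)
        sp[down] = seg.body_speed_cm_s * 0.5 * (1 - np.cos(np.pi * (t_hi - t[down]) / ramp))
        body[:, 0] += np.cumsum(sp) * dt
        i0, i1 = int(round(seg.start_s * fs)), int(round(seg.end_s * fs))
        head_height[i0:i1] = seg.head_height_cm
        if seg.meets_criteria:
            locomotion_truth.append((t[i0], t[i1] if i1 < n else t[-1] + dt))

    trace = GazeTrace(
        timestamps=t,
        eye_pos=eye,
        head_pos=head,
        body_pos=body,
        head_height=head_height,
        sample_rate=fs,
    )
    truth = GroundTruth(
        events=events,
        seed=seed,
        session_length=L,
        locomotion_intervals=locomotion_truth,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# spiking

def default_basis(
    a_sup: float = -0.5,
    a_enh: float = 1.0,
    w_sup: float = 60.0,
    w_enh: float = 100.0,
    l_sup: float = 30.0,
    l_enh: float = 80.0,
) -> BasisParams:
    """Raised-cosine ground-truth parameters used across the simulations."""
    return BasisParams(
        suppression=CosineComponent(a_sup, w_sup, l_sup),
        enhancement=CosineComponent(a_enh, w_enh, l_enh),
    )


def generate_spike_train(truth: GroundTruth, seed: int, dt_ms: float = 1.0) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (s) from the ground-truth model.

    The rate is r(t) = baseline · max(0, 1 + m(t)) with m(t) the continuous
    raised-cosine response of the true model; ``true_model = 'none'`` gives a
    homogeneous Poisson train at the baseline rate.
    """
    if truth.true_model is None:
        raise ConfigError("ground truth carries no spiking model; call with_model()")
    rng = np.random.default_rng(seed)
    L = truth.session_length
    if truth.true_model == NONE_MODEL:
        n = rng.poisson(truth.baseline_rate * L)
        return np.sort(rng.uniform(0.0, L, n))
    t_ms, m = models_mod.predict_continuous(
        truth.events,
        truth.true_basis,
        truth.true_model,
        L,
        sample_step_ms=dt_ms,
        per_fixation_gain=truth.per_fixation_gain,
    )
    centers = 0.5 * (m[:-1] + m[1:])
    rate = truth.baseline_rate * np.maximum(0.0, 1.0 + centers)  # Hz per bin
    counts = rng.poisson(rate * dt_ms / 1000.0)
    nz = np.flatnonzero(counts)
    spikes = np.concatenate(
        [
            (i + rng.uniform(0.0, 1.0, counts[i])) * dt_ms / 1000.0
            for i in nz
        ]
    ) if nz.size else np.empty(0)
    return np.sort(spikes)


# ---------------------------------------------------------------------------
# gratings & tuning

def generate_grating(
    orientation_deg: float,
    spatial_frequency_cpd: float,
    size_deg: float,
    deg_per_px: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Sinusoidal luminance grating in [0, 1].

    ``orientation_deg`` is the direction of spatial modulation (perpendicular
    to the stripes); orientations 180° apart give identical images at zero
    phase.  The spatial frequency must be resolvable (>= 2 px per cycle).
    """
    if spatial_frequency_cpd <= 0 or size_deg <= 0 or deg_per_px <= 0:
        raise ConfigError("grating parameters must be positive")
    if spatial_frequency_cpd * deg_per_px > 0.5 + 1e-12:
        raise ConfigError(
            f"spatial frequency {spatial_frequency_cpd} c/deg aliases at "
            f"{deg_per_px} deg/px (need >= 2 px per cycle)"
        )
    n = int(round(size_deg / deg_per_px))
    c = (np.arange(n) - (n - 1) / 2.0) * deg_per_px
    th = math.radians(orientation_deg)
    u = math.cos(th) * c[None, :] + math.sin(th) * c[:, None]
    return 0.5 + 0.5 * np.cos(2.0 * np.pi * spatial_frequency_cpd * u + phase)


def condition_images(
    size_deg: float = rf_mod.RF_WINDOW_DEG,
    deg_per_px: float = 0.15,
    orientations=ORIENTATIONS_DEG,
    sfs=SPATIAL_FREQS_CPD,
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """The grating stimulus set over the orientation × spatial-frequency grid."""
    imgs, conds = [], []
    for ori in orientations:
        for sf in sfs:
            imgs.append(generate_grating(ori, sf, size_deg, deg_per_px))
            conds.append((float(ori), float(sf)))
    return imgs, conds


@dataclass
class TuningResult:
    conditions: list[tuple[float, float]]  # (orientation, sf)
    rates: np.ndarray  # measured mean rate per condition (Hz)
    expected: np.ndarray  # noiseless tuning curve (Hz)


def _circ_diff_deg(a: float, b: float, period: float = 180.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def generate_tuning_session(
    preferred_orientation: float,
    preferred_sf: float,
    tuning_widths: tuple[float, float] = (25.0, 0.8),
    baseline: float = 2.0,
    peak_rate: float = 20.0,
    n_repeats: int = 10,
    trial_duration_s: float = 1.0,
    seed: int = 0,
    orientations=ORIENTATIONS_DEG,
    sfs=SPATIAL_FREQS_CPD,
) -> TuningResult:
    """Per-condition firing rates with circular-Gaussian orientation tuning
    (period 180°, width in degrees) × log-Gaussian spatial-frequency tuning
    (width in octaves), plus Poisson trial noise.

    Width 0 collapses to a delta at the preferred condition; infinite width
    gives equal rates in expectation.
    """
    ori_w, sf_w = tuning_widths
    if ori_w < 0 or sf_w < 0:
        raise ConfigError("tuning widths must be >= 0")
    rng = np.random.default_rng(seed)
    conds, expected = [], []
    for ori in orientations:
        for sf in sfs:
            d_ori = _circ_diff_deg(ori, preferred_orientation)
            d_sf = math.log2(sf / preferred_sf)
            if ori_w == 0:
                g_ori = 1.0 if d_ori == 0 else 0.0
            else:
                g_ori = math.exp(-(d_ori**2) / (2.0 * ori_w**2)) if np.isfinite(ori_w) else 1.0
            if sf_w == 0:
                g_sf = 1.0 if d_sf == 0 else 0.0
            else:
                g_sf = math.exp(-(d_sf**2) / (2.0 * sf_w**2)) if np.isfinite(sf_w) else 1.0
            conds.append((float(ori), float(sf)))
            expected.append(baseline + peak_rate * g_ori * g_sf)
    expected = np.array(expected)
    exposure = n_repeats * trial_duration_s
    rates = rng.poisson(expected * exposure) / exposure
    return TuningResult(conditions=conds, rates=rates, expected=expected)


# ---------------------------------------------------------------------------
# scene frames

@dataclass
class WallPattern:
    """Periodic patchwork of grating tiles covering the arena wall.

    Luminance at world coordinates (degrees) is looked up from the tile
    grid; coordinates wrap, so arbitrarily large head excursions stay on the
    pattern.
    """

    tile_size_deg: float
    orientations: np.ndarray  # (nt, nt)
    sfs: np.ndarray
    phases: np.ndarray

    @classmethod
    def random(
        cls,
        seed: int,
        tile_size_deg: float = 12.0,
        n_tiles: int = 32,
        orientations=ORIENTATIONS_DEG[:6],
        sfs=SPATIAL_FREQS_CPD,
    ) -> "WallPattern":
        rng = np.random.default_rng(seed)
        return cls(
            tile_size_deg=tile_size_deg,
            orientations=rng.choice(orientations, size=(n_tiles, n_tiles)).astype(float),
            sfs=rng.choice(sfs, size=(n_tiles, n_tiles)).astype(float),
            phases=rng.uniform(0.0, 2.0 * np.pi, size=(n_tiles, n_tiles)),
        )

    def _tiles(self, x_deg: np.ndarray, y_deg: np.ndarray):
        nt = self.orientations.shape[0]
        ix = np.floor(x_deg / self.tile_size_deg).astype(int) % nt
        iy = np.floor(y_deg / self.tile_size_deg).astype(int) % nt
        return iy, ix

    def value(self, x_deg: np.ndarray, y_deg: np.ndarray) -> np.ndarray:
        iy, ix = self._tiles(x_deg, y_deg)
        th = np.radians(self.orientations[iy, ix])
        sf = self.sfs[iy, ix]
        ph = self.phases[iy, ix]
        u = np.cos(th) * x_deg + np.sin(th) * y_deg
        return 0.5 + 0.5 * np.cos(2.0 * np.pi * sf * u + ph)

    def label(self, x_deg: float, y_deg: float) -> tuple[float, float]:
        iy, ix = self._tiles(np.asarray(x_deg), np.asarray(y_deg))
        return float(self.orientations[iy, ix]), float(self.sfs[iy, ix])


def generate_scene_frames(
    trace: GazeTrace,
    wall: WallPattern,
    frame_rate: float = 10.0,
    rf_offset_deg: tuple[float, float] = (2.0, 2.0),
    frame_size_deg: float = 40.0,
    deg_per_px: float = 0.15,
    crop_size_deg: float = rf_mod.RF_WINDOW_DEG,
    fixations: list[GazeEvent] | None = None,
    max_frames_per_fixation: int | None = None,
) -> SceneFrameSet:
    """World-camera frames: the wall patch seen from the head direction.

    Each frame is the wall patch centered on the instantaneous head
    direction; the gaze point within the frame follows the eye-in-head
    position.  ``validity`` marks frames whose RF crop (``rf_offset_deg``
    from gaze, ``crop_size_deg`` wide) lies fully inside the frame, and the
    wall tile under the crop center is recorded as ground truth.  When
    ``fixations`` is given, only frames within fixations (optionally capped
    per fixation) are rendered, which keeps long sessions light.
    """
    if frame_rate <= 0 or frame_rate > trace.sample_rate:
        raise ConfigError("frame_rate must be positive and <= trace sample rate")
    times = np.arange(0.0, trace.duration, 1.0 / frame_rate)
    if fixations is not None:
        keep = []
        for fx in fixations:
            idx = np.flatnonzero((times >= fx.onset) & (times < fx.offset))
            if max_frames_per_fixation is not None:
                idx = idx[:max_frames_per_fixation]
            keep.extend(idx.tolist())
        times = times[np.array(sorted(set(keep)), dtype=int)] if keep else times[:0]

    def interp2(arr):
        return np.column_stack(
            [np.interp(times, trace.timestamps, arr[:, j]) for j in range(2)]
        )

    eye = interp2(trace.eye_pos)
    head = interp2(trace.head_pos)
    n_px = int(round(frame_size_deg / deg_per_px))
    center = (n_px - 1) / 2.0
    rel = (np.arange(n_px) - center) * deg_per_px
    frames = np.empty((times.size, n_px, n_px), dtype=np.float32)
    gaze_center_px = np.empty((times.size, 2))
    validity = np.zeros(times.size, dtype=bool)
    tile_ori = np.full(times.size, np.nan)
    tile_sf = np.full(times.size, np.nan)
    for i in range(times.size):
        wx = head[i, 0] + rel[None, :]
        wy = head[i, 1] + rel[:, None]
        frames[i] = wall.value(wx, wy)
        gaze_center_px[i] = (center + eye[i, 1] / deg_per_px, center + eye[i, 0] / deg_per_px)
        sl = rf_mod.crop_slices(
            (n_px, n_px), tuple(gaze_center_px[i]), rf_offset_deg, deg_per_px, crop_size_deg
        )
        validity[i] = sl is not None
        gx = head[i, 0] + eye[i, 0] + rf_offset_deg[0]
        gy = head[i, 1] + eye[i, 1] + rf_offset_deg[1]
        tile_ori[i], tile_sf[i] = wall.label(gx, gy)
    return SceneFrameSet(
        frames=frames,
        frame_times=times,
        gaze_center_px=gaze_center_px,
        validity=validity,
        deg_per_px=deg_per_px,
        rf_offset_deg=rf_offset_deg,
        tile_orientation=tile_ori,
        tile_sf=tile_sf,
    )


# ---------------------------------------------------------------------------
# head-fixed dot mapping

def generate_dot_stimulus(
    duration_s: float,
    seed: int,
    extent_deg: float = 20.0,
    deg_per_px: float = 0.5,
    n_dots: int = 120,
    rate_hz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flashing-dot frames (±1 contrast dots on a zero background) at 10 Hz."""
    rng = np.random.default_rng(seed)
    n_px = int(round(extent_deg / deg_per_px))
    n_frames = int(round(duration_s * rate_hz))
    frames = np.zeros((n_frames, n_px, n_px), dtype=np.float32)
    for i in range(n_frames):
        rows = rng.integers(0, n_px, n_dots)
        cols = rng.integers(0, n_px, n_dots)
        pol = rng.choice([-1.0, 1.0], n_dots)
        frames[i, rows, cols] = pol
    return frames, np.arange(n_frames) / rate_hz


def simulate_rf_neuron(
    frames: np.ndarray,
    frame_times: np.ndarray,
    rf_center_deg: tuple[float, float],
    rf_sigma_deg: float,
    deg_per_px: float,
    lag_ms: float = 50.0,
    baseline: float = 10.0,
    gain: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Linear-Gaussian RF neuron driven by the dot stimulus (for map_rf tests)."""
    rng = np.random.default_rng(seed)
    n_px = frames.shape[1]
    c = (np.arange(n_px) - (n_px - 1) / 2.0) * deg_per_px
    ky = np.exp(-((c - rf_center_deg[1]) ** 2) / (2 * rf_sigma_deg**2))
    kx = np.exp(-((c - rf_center_deg[0]) ** 2) / (2 * rf_sigma_deg**2))
    kernel = np.outer(ky, kx)
    drive = np.tensordot(frames, kernel, axes=((1, 2), (0, 1)))
    frame_dt = frame_times[1] - frame_times[0]
    rate = np.maximum(0.0, baseline * (1.0 + gain * drive))
    spikes = []
    for i, r in enumerate(rate):
        k = rng.poisson(r * frame_dt)
        if k:
            spikes.append(frame_times[i] + lag_ms / 1000.0 + rng.uniform(0, frame_dt, k))
    return np.sort(np.concatenate(spikes)) if spikes else np.empty(0)


# ---------------------------------------------------------------------------
# coupled free-viewing session (drive-dependent enhancement)

def couple_gain_to_drive(
    drives: np.ndarray, gain_range: tuple[float, float] = (0.5, 1.5)
) -> np.ndarray:
    """Monotone (rank-based) map from per-fixation drive D to enhancement gain.

    Excluded fixations (NaN drive) get gain 1.  The map being monotone means
    tertile membership by D is exactly tertile membership by gain, which is
    the contrast the conditioned-PSTH analysis must detect.
    """
    d = np.asarray(drives, dtype=float)
    gains = np.ones_like(d)
    valid = np.isfinite(d)
    nv = int(valid.sum())
    if nv >= 2:
        ranks = np.empty(nv)
        ranks[np.argsort(d[valid], kind="stable")] = np.arange(nv)
        lo, hi = gain_range
        gains[valid] = lo + (hi - lo) * ranks / (nv - 1)
    return gains


@dataclass
class NeuronRecord:
    preferred_orientation: float
    preferred_sf: float
    tuning: TuningResult
    f_pref: rf_mod.PreferredSpectrum
    drives: list[rf_mod.RfDrive]
    gains: np.ndarray
    truth: GroundTruth
    spikes: np.ndarray


@dataclass
class CoupledSession:
    trace: GazeTrace
    truth: GroundTruth
    frameset: SceneFrameSet
    images: list[np.ndarray]
    conditions: list[tuple[float, float]]
    neurons: list[NeuronRecord] = field(default_factory=list)


def generate_coupled_session(
    seed: int,
    n_neurons: int = 30,
    session_length_s: float = 240.0,
    baseline_rate: float = 15.0,
    basis: BasisParams | None = None,
    gain_range: tuple[float, float] = (0.5, 1.5),
    deg_per_px: float = 0.15,
    rf_offset_deg: tuple[float, float] = (2.0, 2.0),
    preferred_conditions: list[tuple[float, float]] | None = None,
) -> CoupledSession:
    """A free-viewing session whose enhancement gain follows the RF drive.

    One behavioral session (trace, events, world-camera frames) is shared by
    all neurons; each neuron gets its own preferred grating condition, hence
    its own F_PREF, per-fixation drives, gains, and spike train generated
    under the two-stage model with drive-coupled enhancement.
    """
    basis = basis or default_basis()
    rng = np.random.default_rng(seed)
    trace, truth = generate_gaze_trace(
        GazeConfig(session_length_s=session_length_s), seed=seed
    )
    fixations = truth.fixations
    frameset = generate_scene_frames(
        trace,
        WallPattern.random(seed + 1),
        frame_rate=10.0,
        rf_offset_deg=rf_offset_deg,
        deg_per_px=deg_per_px,
        fixations=fixations,
        max_frames_per_fixation=4,
    )
    imgs, conds = condition_images(deg_per_px=deg_per_px)
    session = CoupledSession(trace, truth, frameset, imgs, conds)
    for k in range(n_neurons):
        if preferred_conditions is not None and k < len(preferred_conditions):
            pref_ori, pref_sf = preferred_conditions[k]
        else:
            pref_ori = float(rng.choice(ORIENTATIONS_DEG[:6]))
            pref_sf = float(rng.choice(SPATIAL_FREQS_CPD))
        tuning = generate_tuning_session(
            pref_ori, pref_sf, seed=int(rng.integers(2**31))
        )
        f_pref = rf_mod.preferred_spectrum(tuning.rates, imgs, deg_per_px)
        drives = rf_mod.compute_fixation_drives(frameset, fixations, f_pref)
        gains = couple_gain_to_drive(
            np.array([d.D for d in drives]), gain_range
        )
        truth_k = truth.with_model(
            TWO_STAGE, basis, baseline_rate, per_fixation_gain=gains
        )
        spikes = generate_spike_train(truth_k, seed=int(rng.integers(2**31)))
        session.neurons.append(
            NeuronRecord(
                preferred_orientation=pref_ori,
                preferred_sf=pref_sf,
                tuning=tuning,
                f_pref=f_pref,
                drives=drives,
                gains=gains,
                truth=truth_k,
                spikes=spikes,
            )
        )
    return session
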