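"""Receptive-field mapping, preferred spectra, and per-fixation RF drive.

A neuron's receptive field is mapped by reverse correlation (spike-triggered
average of flashing-dot frames) and a 5×5 degree window is placed on the RF
center.  The preferred spectrum F_PREF is the rate-weighted sum of the FFT
log-magnitude spectra of the grating stimulus conditions, min-max normalized
to [0, 1].  During free viewing, the RF input for each fixation is cropped
from the world-camera frame (5×5 deg around the RF position relative to
gaze), mean-subtracted, tapered with a 2D raised-cosine window, and Fourier
transformed; the predicted RF drive is

    D = (1/N) Σ_{m,n} F_RF(m, n) · F_PREF(m, n),

the elementwise-product mean of the crop's log-magnitude spectrum with
F_PREF.  Fixations in the top/bottom tertile of D are labeled preferred /
non-preferred visual-input events.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import psth as psth_mod
from .types import ConfigError, GazeEvent, SceneFrameSet

__all__ = [
    "log_magnitude_spectrum",
    "raised_cosine_taper",
    "spectrum_freqs",
    "map_rf",
    "preferred_spectrum",
    "select_fixation_frame",
    "extract_rf_input",
    "rf_spectrum",
    "rf_drive",
    "tertile_labels",
    "compute_fixation_drives",
    "conditioned_psths",
    "ReceptiveField",
    "PreferredSpectrum",
    "RfDrive",
]

RF_WINDOW_DEG = 5.0

PREFERRED = "preferred"
NON_PREFERRED = "non_preferred"
MIDDLE = "middle"
EXCLUDED = "excluded"


class DegenerateSpectrumError(ValueError):
    """All condition rates are zero (or the weighted spectrum is constant)."""


# ---------------------------------------------------------------------------
# shared spectral helpers (both F_PREF and F_RF go through these, so the two
# spectra live on the identical grid with identical taper and log convention)

def raised_cosine_taper(shape: tuple[int, int]) -> np.ndarray:
    """Radially symmetric 2D raised-cosine (Hann) window over an image."""
    h, w = shape
    ry = (np.arange(h) - (h - 1) / 2.0) / (h / 2.0)
    rx = (np.arange(w) - (w - 1) / 2.0) / (w / 2.0)
    r = np.hypot(ry[:, None], rx[None, :])
    return 0.5 * (1.0 + np.cos(np.pi * np.minimum(r, 1.0)))


def log_magnitude_spectrum(
    image: np.ndarray, taper: bool = True, mean_subtract: bool = True
) -> np.ndarray:
    """log(1 + |FFT|) of a (mean-subtracted, tapered) image, fftshifted."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigError("expected a 2D grayscale image")
    if mean_subtract:
        img = img - img.mean()
    if taper:
        img = img * raised_cosine_taper(img.shape)
    return np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(img))))


def spectrum_freqs(n: int, deg_per_px: float) -> np.ndarray:
    """Spatial-frequency axis (cycles/degree) matching the fftshifted grid."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=deg_per_px))


# ---------------------------------------------------------------------------
# receptive-field mapping (head-fixed paradigm)

@dataclass
class ReceptiveField:
    """Reverse-correlation map with its peak center and 5×5 deg window."""

    map: np.ndarray
    center_px: tuple[int, int]
    center_deg: tuple[float, float]
    best_lag_ms: float
    deg_per_px: float
    window_deg: float = RF_WINDOW_DEG


def map_rf(
    spikes: np.ndarray,
    frames: np.ndarray,
    frame_times: np.ndarray,
    deg_per_px: float,
    lag_grid_ms: np.ndarray | None = None,
) -> ReceptiveField:
    """Spike-triggered average of dot frames at the best single lag.

    For each candidate lag the frame on screen at (spike time − lag) is
    averaged; the best lag maximizes the map's peak absolute deviation from
    its median.  The window center is the peak of |map|, automating the
    manual 5×5 deg window placement.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        raise ConfigError("map_rf needs at least one spike")
    frames = np.asarray(frames, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if lag_grid_ms is None:
        lag_grid_ms = np.arange(0.0, 201.0, 10.0)
    best = None
    for lag in lag_grid_ms:
        idx = np.searchsorted(frame_times, spikes - lag / 1000.0, side="right") - 1
        idx = idx[idx >= 0]
        if idx.size == 0:
            continue
        sta = frames[idx].mean(axis=0)
        score = float(np.abs(sta - np.median(sta)).max())
        if best is None or score > best[0]:
            best = (score, lag, sta)
    if best is None:
        raise ConfigError("no spikes fall within the stimulus period")
    _, lag, sta = best
    r, c = np.unravel_index(np.argmax(np.abs(sta - np.median(sta))), sta.shape)
    h, w = sta.shape
    center_deg = (
        (r - (h - 1) / 2.0) * deg_per_px,
        (c - (w - 1) / 2.0) * deg_per_px,
    )
    return ReceptiveField(
        map=sta,
        center_px=(int(r), int(c)),
        center_deg=center_deg,
        best_lag_ms=float(lag),
        deg_per_px=deg_per_px,
    )


# ---------------------------------------------------------------------------
# preferred spectrum (F_PREF)

@dataclass
class PreferredSpectrum:
    """Rate-weighted mean FFT log-magnitude spectrum, min-max scaled to [0,1]."""

    F: np.ndarray
    freqs_cpd: np.ndarray
    deg_per_px: float


def preferred_spectrum(
    rates: np.ndarray,
    condition_images: list[np.ndarray],
    deg_per_px: float,
    taper: bool = True,
    mean_subtract: bool = True,
) -> PreferredSpectrum:
    """F_PREF: firing-rate-weighted sum of condition log-magnitude spectra.

    Condition images go through the same spectral helper as the fixation
    crops so that F_PREF and F_RF share grid, taper and log convention.
    """
    rates = np.asarray(rates, dtype=float).ravel()
    if len(condition_images) != rates.size:
        raise ConfigError("one rate per condition image required")
    shapes = {img.shape for img in condition_images}
    if len(shapes) != 1:
        raise ConfigError("condition images must share a common shape")
    if not np.any(rates > 0):
        raise DegenerateSpectrumError("all condition rates are zero")
    acc = np.zeros(condition_images[0].shape)
    for r, img in zip(rates, condition_images):
        if r != 0.0:
            acc += r * log_magnitude_spectrum(img, taper=taper, mean_subtract=mean_subtract)
    lo, hi = acc.min(), acc.max()
    if hi - lo <= 0:
        raise DegenerateSpectrumError("weighted spectrum is constant")
    return PreferredSpectrum(
        F=(acc - lo) / (hi - lo),
        freqs_cpd=spectrum_freqs(acc.shape[0], deg_per_px),
        deg_per_px=deg_per_px,
    )


# ---------------------------------------------------------------------------
# fixation-wise RF input

def select_fixation_frame(validity: list[bool] | np.ndarray) -> int | None:
    """Pick the frame to use for a fixation: 2nd, then 3rd, then 1st.

    Among the frames recorded during one fixation (ordered in time), the
    second is preferred (the first is more likely to carry residual
    head-motion artifacts), then the third, then the first, then any later
    frame in order.  Returns the 0-based index, or None when no frame is
    valid (the fixation is excluded).
    """
    validity = list(np.asarray(validity, dtype=bool))
    n = len(validity)
    order = [i for i in (1, 2, 0) if i < n] + list(range(3, n))
    for i in order:
        if validity[i]:
            return i
    return None


def crop_slices(
    frame_shape: tuple[int, int],
    gaze_center_px: tuple[float, float],
    rf_offset_deg: tuple[float, float],
    deg_per_px: float,
    crop_size_deg: float = RF_WINDOW_DEG,
) -> tuple[slice, slice] | None:
    """Pixel slices of the RF crop, or None when it exceeds the frame."""
    n = int(round(crop_size_deg / deg_per_px))
    cr = gaze_center_px[0] + rf_offset_deg[1] / deg_per_px  # row ~ vertical
    cc = gaze_center_px[1] + rf_offset_deg[0] / deg_per_px
    top = int(round(cr - (n - 1) / 2.0))
    left = int(round(cc - (n - 1) / 2.0))
    if top < 0 or left < 0 or top + n > frame_shape[0] or left + n > frame_shape[1]:
        return None
    return slice(top, top + n), slice(left, left + n)


def extract_rf_input(
    frame: np.ndarray,
    gaze_center_px: tuple[float, float],
    rf_offset_deg: tuple[float, float],
    deg_per_px: float,
    crop_size_deg: float = RF_WINDOW_DEG,
) -> np.ndarray | None:
    """5×5 deg crop centered on the RF position relative to gaze.

    Returns None when any part of the window falls outside the frame
    (unavailability is a value, not an error).
    """
    sl = crop_slices(frame.shape, gaze_center_px, rf_offset_deg, deg_per_px, crop_size_deg)
    if sl is None:
        return None
    return np.asarray(frame, dtype=float)[sl]


def rf_spectrum(crop: np.ndarray, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """F_RF: log-magnitude FFT of the mean-subtracted, raised-cosine-tapered crop."""
    crop = np.asarray(crop, dtype=float)
    if crop.ndim != 2 or crop.shape[0] != crop.shape[1]:
        raise ConfigError("RF crop must be square")
    if expected_shape is not None and crop.shape != tuple(expected_shape):
        raise ConfigError(f"crop shape {crop.shape} does not match the F_PREF grid")
    return log_magnitude_spectrum(crop, taper=True, mean_subtract=True)


def rf_drive(F_RF: np.ndarray, F_PREF: np.ndarray) -> float:
    """D = (1/N) Σ F_RF(m,n)·F_PREF(m,n) — the elementwise-product mean."""
    F_RF = np.asarray(F_RF, dtype=float)
    F_PREF = np.asarray(F_PREF, dtype=float)
    if F_RF.shape != F_PREF.shape:
        raise ConfigError("F_RF and F_PREF shapes differ")
    return float(np.mean(F_RF * F_PREF))


def tertile_labels(drives: np.ndarray) -> list[str]:
    """Label fixations by drive tertile.

    Thresholds are the 1/3 and 2/3 linear-interpolation quantiles of the
    finite drives; strictly above the upper tertile → preferred, strictly
    below the lower tertile → non-preferred, the rest → middle.  NaN drives
    (no valid frame) are labeled excluded.
    """
    d = np.asarray(drives, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size < 3:
        raise ConfigError("tertile_labels needs >= 3 non-excluded fixations")
    q1, q2 = np.quantile(finite, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2 and finite.min() == finite.max():
        warnings.warn("all drives identical; no preferred/non-preferred events", stacklevel=2)
    labels = []
    for v in d:
        if not np.isfinite(v):
            labels.append(EXCLUDED)
        elif v > q2:
            labels.append(PREFERRED)
        elif v < q1:
            labels.append(NON_PREFERRED)
        else:
            labels.append(MIDDLE)
    return labels


@dataclass
class RfDrive:
    """Per-fixation predicted RF drive."""

    fixation_id: int
    onset_s: float
    D: float  # NaN when excluded
    label: str = MIDDLE
    frame_used: int = -1  # global frame index, -1 when excluded


def compute_fixation_drives(
    frameset: SceneFrameSet,
    fixations: list[GazeEvent],
    f_pref: PreferredSpectrum,
    crop_size_deg: float = RF_WINDOW_DEG,
) -> list[RfDrive]:
    """RF drive D for every fixation, with tertile labels.

    For each fixation the frames recorded within [onset, offset) are tried in
    the 2nd → 3rd → 1st preference order; the crop of the selected frame is
    Fourier transformed and compared with F_PREF.  Fixations without any
    valid frame are excluded (D = NaN).
    """
    out: list[RfDrive] = []
    shape = f_pref.F.shape
    for i, fx in enumerate(fixations):
        idx = np.flatnonzero(
            (frameset.frame_times >= fx.onset) & (frameset.frame_times < fx.offset)
        )
        crops = [
            extract_rf_input(
                frameset.frames[j],
                tuple(frameset.gaze_center_px[j]),
                frameset.rf_offset_deg,
                frameset.deg_per_px,
                crop_size_deg,
            )
            for j in idx
        ]
        sel = select_fixation_frame([c is not None for c in crops]) if len(idx) else None
        if sel is None:
            out.append(RfDrive(i, fx.onset, np.nan, EXCLUDED, -1))
            continue
        F_RF = rf_spectrum(crops[sel], expected_shape=shape)
        out.append(RfDrive(i, fx.onset, rf_drive(F_RF, f_pref.F), MIDDLE, int(idx[sel])))
    labels = tertile_labels(np.array([r.D for r in out]))
    for r, lab in zip(out, labels):
        r.label = lab
    return out


@dataclass
class ConditionedPsths:
    """Fixation-aligned PSTHs and metrics per visual-input group."""

    psths: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)


def conditioned_psths(
    spikes: np.ndarray,
    fixations: list[GazeEvent],
    labels: list[str],
    session_length_s: float,
    groups: tuple[str, ...] = (PREFERRED, NON_PREFERRED),
    n_folds: int = psth_mod.N_FOLDS,
) -> ConditionedPsths:
    """Fixation-aligned normalized PSTHs grouped by drive label.

    Groups with fewer events than jackknife folds are skipped and flagged.
    """
    from .models import _full_window_anchors  # shared anchor filtering

    out = ConditionedPsths()
    for group in groups:
        onsets = np.array(
            [fx.onset for fx, lab in zip(fixations, labels) if lab == group]
        )
        onsets = _full_window_anchors(onsets, session_length_s)
        if onsets.size < n_folds:
            out.skipped.append(group)
            continue
        p = psth_mod.compute_normalized_psth(
            spikes, onsets, anchor_kind="fixation_onset", n_folds=n_folds
        )
        out.psths[group] = p
        out.metrics[group] = psth_mod.extract_metrics(p)
    return out
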