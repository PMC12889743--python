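"""Event-aligned PSTHs with jackknife errors, normalization and metrics.

PSTHs are computed at 1 ms resolution in a −200..400 ms window around event
onsets.  A 10-fold jackknife (contiguous folds of events) yields the mean and
standard error; each jackknife replicate is smoothed with a Gaussian kernel
(σ = 5 ms).  The normalized PSTH divides by the pre-event baseline (mean over
−200..−100 ms) and subtracts 1, so a flat neuron sits at 0.  Suppression and
enhancement amplitudes are the maximum dip and the subsequent maximum peak;
significance uses z = amplitude / jackknife SE at the extremum bin (|z| > 2);
the response latency is the zero crossing between suppression and
enhancement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import ConfigError

__all__ = [
    "NormalizedPsth",
    "ResponseMetrics",
    "BaselineError",
    "compute_raw_psth",
    "jackknife_psth",
    "normalize_psth",
    "compute_normalized_psth",
    "extract_metrics",
    "exclude_low_rate",
    "population_average",
    "population_summary",
    "find_extrema",
]

WINDOW_MS = (-200.0, 400.0)
BASELINE_WINDOW_MS = (-200.0, -100.0)
BIN_MS = 1.0
N_FOLDS = 10
SMOOTHING_SIGMA_MS = 5.0
Z_THRESHOLD = 2.0
MIN_RATE_HZ = 1.0


class BaselineError(ValueError):
    """Raised when a neuron's pre-event baseline is zero (not normalizable)."""


@dataclass
class NormalizedPsth:
    """Jackknifed, smoothed, baseline-normalized event-aligned response.

    ``time_bins`` are 1 ms bin left edges (ms relative to the anchor); bin t
    covers [t, t+1) ms.  ``mean`` is in normalized units (0 = baseline) and
    ``se`` is the per-bin jackknife standard error on the same scale.
    """

    time_bins: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    baseline_rate: float
    n_events: int
    anchor_kind: str = "shift_onset"


@dataclass
class ResponseMetrics:
    """Suppression/enhancement amplitudes, significance, and latency.

    ``a_sup`` and ``a_enh`` are magnitudes (>= 0); the dip's sign is negative
    by convention and is re-applied where the model interface needs signed
    amplitudes.  ``latency_ms`` is NaN when no zero crossing exists between
    the trough and the peak (``latency_defined`` False).
    """

    a_sup: float
    a_enh: float
    latency_ms: float
    z_sup: float
    z_enh: float
    significant_sup: bool
    significant_enh: bool
    latency_defined: bool
    trough_time_ms: float
    peak_time_ms: float


def _bin_edges(window_ms: tuple[float, float], bin_ms: float) -> np.ndarray:
    lo, hi = window_ms
    return np.arange(lo, hi + bin_ms + 1e-9, bin_ms)


def compute_raw_psth(
    spikes: np.ndarray,
    anchors: np.ndarray,
    window_ms: tuple[float, float] = WINDOW_MS,
    bin_ms: float = BIN_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event spike-count matrix around each anchor.

    Returns ``(counts, time_bins)`` where ``counts[i, j]`` is the number of
    spikes in the half-open bin [t_j, t_j + bin) ms relative to anchor i, and
    ``time_bins`` are the bin left edges (−200..400 ms at 1 ms by default,
    601 bins).
    """
    spikes = np.sort(np.asarray(spikes, dtype=float))
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ConfigError("compute_raw_psth needs at least one anchor")
    edges = _bin_edges(window_ms, bin_ms)
    time_bins = edges[:-1]
    n_bins = time_bins.size
    counts = np.zeros((anchors.size, n_bins), dtype=float)
    lo_s, hi_s = edges[0] / 1000.0, edges[-1] / 1000.0
    for i, a in enumerate(anchors):
        s = np.searchsorted(spikes, a + lo_s, side="left")
        e = np.searchsorted(spikes, a + hi_s, side="left")
        if e > s:
            rel = (spikes[s:e] - a) * 1000.0
            idx = np.floor((rel - edges[0]) / bin_ms).astype(int)
            idx = idx[(idx >= 0) & (idx < n_bins)]
            np.add.at(counts[i], idx, 1.0)
    return counts, time_bins


def jackknife_psth(
    counts: np.ndarray,
    n_folds: int = N_FOLDS,
    smoothing_sigma_ms: float = SMOOTHING_SIGMA_MS,
    bin_ms: float = BIN_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Jackknifed mean firing rate (Hz) and standard error per bin.

    Events are partitioned into ``n_folds`` contiguous folds; each
    leave-one-fold-out replicate is the mean rate over the retained events,
    Gaussian-smoothed (reflect padding).  The reported mean is the average of
    the replicates and se = sqrt((n−1)/n · Σ(θ_i − θ̄)²).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n_events = counts.shape[0]
    if n_events < n_folds:
        raise ConfigError(f"need >= {n_folds} events for the jackknife, got {n_events}")
    rate = counts / (bin_ms / 1000.0)
    folds = np.array_split(np.arange(n_events), n_folds)
    sigma_bins = smoothing_sigma_ms / bin_ms
    keep = np.ones(n_events, dtype=bool)
    thetas = np.empty((n_folds, counts.shape[1]))
    for i, fold in enumerate(folds):
        keep[:] = True
        keep[fold] = False
        theta = rate[keep].mean(axis=0)
        thetas[i] = gaussian_filter1d(theta, sigma_bins, mode="reflect")
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_folds - 1) / n_folds * ((thetas - mean) ** 2).sum(axis=0))
    # identical replicates have zero spread by definition; guard against the
    # rounding of mean-of-identical-floats re-introducing ~1e-10 jitter
    se[np.all(thetas == thetas[0], axis=0)] = 0.0
    return mean, se


def normalize_psth(
    mean: np.ndarray,
    se: np.ndarray,
    time_bins: np.ndarray,
    n_events: int,
    anchor_kind: str = "shift_onset",
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS,
) -> NormalizedPsth:
    """Divide by the pre-event baseline and subtract 1.

    The baseline is the mean rate over ``baseline_window_ms`` (bins with left
    edge in [−200, −100) ms by default).  A zero baseline raises
    :class:`BaselineError` — the neuron cannot be normalized and is excluded
    upstream.
    """
    sel = (time_bins >= baseline_window_ms[0]) & (time_bins < baseline_window_ms[1])
    baseline = float(np.mean(mean[sel]))
    if baseline <= 0:
        raise BaselineError("pre-event baseline is zero; neuron not normalizable")
    return NormalizedPsth(
        time_bins=np.asarray(time_bins, dtype=float),
        mean=mean / baseline - 1.0,
        se=se / baseline,
        baseline_rate=baseline,
        n_events=int(n_events),
        anchor_kind=anchor_kind,
    )


def compute_normalized_psth(
    spikes: np.ndarray,
    anchors: np.ndarray,
    anchor_kind: str = "shift_onset",
    window_ms: tuple[float, float] = WINDOW_MS,
    bin_ms: float = BIN_MS,
    n_folds: int = N_FOLDS,
    smoothing_sigma_ms: float = SMOOTHING_SIGMA_MS,
    baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS,
) -> NormalizedPsth:
    """Convenience: raw counts → jackknife → normalization in one call."""
    counts, time_bins = compute_raw_psth(spikes, anchors, window_ms, bin_ms)
    mean, se = jackknife_psth(counts, n_folds, smoothing_sigma_ms, bin_ms)
    return normalize_psth(
        mean, se, time_bins, counts.shape[0], anchor_kind, baseline_window_ms
    )


def find_extrema(
    time_bins: np.ndarray,
    values: np.ndarray,
    search_window_ms: tuple[float, float] = (0.0, 400.0),
    ordered: bool = False,
) -> dict:
    """Maximum dip and peak of a normalized response curve over ``(lo, hi]``.

    By default the two extrema are searched independently: on
    fixation-aligned responses the enhancement peak precedes the (smeared)
    suppression of the next gaze shift, so constraining the peak to follow
    the trough would mis-measure it.  ``ordered=True`` restricts the peak to
    times at or after the trough (appropriate for shift-aligned responses
    only).  Returns bin indices (into the full arrays), values and times.
    """
    lo, hi = search_window_ms
    sel = np.flatnonzero((time_bins > lo) & (time_bins <= hi))
    if sel.size == 0:
        raise ConfigError("empty extremum search window")
    trough_rel = int(np.argmin(values[sel]))
    trough_idx = int(sel[trough_rel])
    peak_sel = sel[sel >= trough_idx] if ordered else sel
    peak_idx = int(peak_sel[np.argmax(values[peak_sel])])
    return {
        "trough_idx": trough_idx,
        "trough_val": float(values[trough_idx]),
        "trough_time": float(time_bins[trough_idx]),
        "peak_idx": peak_idx,
        "peak_val": float(values[peak_idx]),
        "peak_time": float(time_bins[peak_idx]),
    }


def extract_metrics(
    psth: NormalizedPsth,
    search_window_ms: tuple[float, float] = (0.0, 400.0),
    z_threshold: float = Z_THRESHOLD,
) -> ResponseMetrics:
    """Amplitudes, z-scores, significance flags and zero-crossing latency.

    Latency is the last negative→positive zero crossing of the normalized
    mean before the peak (linearly interpolated between bins); it is
    undefined (NaN) when the curve has no sign change between trough and
    peak.
    """
    ext = find_extrema(psth.time_bins, psth.mean, search_window_ms)
    a_sup = max(0.0, -ext["trough_val"])
    a_enh = max(0.0, ext["peak_val"])

    def z_at(amp: float, idx: int) -> float:
        se = psth.se[idx]
        if se > 0:
            return amp / se
        return np.inf if amp > 0 else 0.0

    z_sup = z_at(a_sup, ext["trough_idx"])
    z_enh = z_at(a_enh, ext["peak_idx"])

    latency = np.nan
    m = psth.mean
    for i in range(ext["peak_idx"] - 1, ext["trough_idx"] - 1, -1):
        if m[i] < 0.0 <= m[i + 1]:
            frac = -m[i] / (m[i + 1] - m[i])
            latency = float(psth.time_bins[i] + frac * (psth.time_bins[i + 1] - psth.time_bins[i]))
            break
    defined = np.isfinite(latency)
    return ResponseMetrics(
        a_sup=a_sup,
        a_enh=a_enh,
        latency_ms=latency,
        z_sup=z_sup,
        z_enh=z_enh,
        significant_sup=bool(z_sup > z_threshold),
        significant_enh=bool(z_enh > z_threshold),
        latency_defined=bool(defined),
        trough_time_ms=ext["trough_time"],
        peak_time_ms=ext["peak_time"],
    )


def exclude_low_rate(
    spike_trains: dict, session_length: float, min_rate: float = MIN_RATE_HZ
) -> dict:
    """Drop neurons whose session-mean firing rate is below ``min_rate`` Hz.

    The inequality is strict: a neuron at exactly ``min_rate`` is retained.
    """
    if session_length <= 0:
        raise ConfigError("session_length must be positive")
    return {
        nid: np.asarray(sp, dtype=float)
        for nid, sp in spike_trains.items()
        if len(sp) / session_length >= min_rate
    }


def population_average(psths: list[NormalizedPsth]) -> tuple[np.ndarray, np.ndarray]:
    """Population-average normalized PSTH with propagated per-bin SE.

    Neurons are treated as independent: se = sqrt(Σ se_i²) / N.
    """
    mat = np.vstack([p.mean for p in psths])
    ses = np.vstack([p.se for p in psths])
    return mat.mean(axis=0), np.sqrt((ses**2).sum(axis=0)) / len(psths)


@dataclass
class PopulationSummary:
    """Latency-sorted population views of normalized PSTHs and amplitudes."""

    order: np.ndarray
    sorted_matrix: np.ndarray
    latencies: np.ndarray
    latency_hist: tuple[np.ndarray, np.ndarray]
    group_masks: dict = field(default_factory=dict)
    group_psths: dict = field(default_factory=dict)
    a_sup: np.ndarray = field(default_factory=lambda: np.empty(0))
    a_enh: np.ndarray = field(default_factory=lambda: np.empty(0))


def population_summary(
    metrics: list[ResponseMetrics],
    psths: list[NormalizedPsth],
    quantiles: tuple[float, float] = (0.1, 0.9),
    n_hist_bins: int = 20,
) -> PopulationSummary:
    """Latency-sorted PSTH matrix, latency histogram, early/middle/late group
    averages (split at the 0.1 and 0.9 latency quantiles) and amplitude
    scatter data.  Neurons without a defined latency are dropped."""
    keep = [i for i, m in enumerate(metrics) if m.latency_defined]
    if len(keep) < 2:
        raise ConfigError("population_summary needs >= 2 neurons with defined latency")
    lat = np.array([metrics[i].latency_ms for i in keep])
    mat = np.vstack([psths[i].mean for i in keep])
    order = np.argsort(lat, kind="stable")
    q_lo, q_hi = np.quantile(lat, quantiles)
    masks = {
        "early": lat < q_lo,
        "late": lat > q_hi,
    }
    masks["middle"] = ~(masks["early"] | masks["late"])
    group_psths = {
        name: mat[mask].mean(axis=0) for name, mask in masks.items() if mask.any()
    }
    return PopulationSummary(
        order=order,
        sorted_matrix=mat[order],
        latencies=lat,
        latency_hist=np.histogram(lat, bins=n_hist_bins),
        group_masks=masks,
        group_psths=group_psths,
        a_sup=np.array([metrics[i].a_sup for i in keep]),
        a_enh=np.array([metrics[i].a_enh for i in keep]),
    )
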