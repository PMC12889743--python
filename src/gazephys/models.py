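"""Raised-cosine response models of peri-gaze-shift V1 activity.

Two parametric models describe a neuron's normalized response to gaze
movements.  Each of the suppression and enhancement components is a
raised-cosine lobe

    f(t) = a/2 · (1 + cos(2π (t − l) / w))   for |t − l| ≤ w/2, else 0,

with amplitude ``a``, width ``w`` and latency ``l``.  In the saccade-locked
model both lobes are anchored at every gaze-shift onset; in the two-stage
model suppression is anchored at gaze-shift onsets and enhancement at the
subsequent fixation onsets.  Lobes from all events sum into a continuous
normalized response; predicted event-aligned PSTHs are windowed averages of
that response, passed through the same smoothing and baseline normalization
as the empirical PSTHs.  Widths and latencies are fixed from the data; the
two amplitudes are fitted by constrained minimization (a_sup ≤ 0, a_enh ≥ 0)
of

    ℒ = ½ [(A_sup^pre − A_sup^emp)² + (A_enh^pre − A_enh^emp)²],

stopping when ℒ < 1e−6 or after 20 iterations.  Models are compared by the
mean squared amplitude error across both alignments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from . import psth as psth_mod
from .types import (
    FIXATION,
    SACCADE_LOCKED,
    SHIFT,
    TWO_STAGE,
    BasisParams,
    ConfigError,
    CosineComponent,
    GazeEvent,
    onsets_of,
)

__all__ = [
    "raised_cosine",
    "init_params",
    "predict_continuous",
    "predict_psths",
    "fit_amplitudes",
    "model_error",
    "compare_models",
    "pair_loss",
    "EmpiricalAmplitudes",
    "ModelFit",
    "ModelComparison",
]

LOSS_TOL = 1e-6
MAX_ITER = 20
DEFAULT_WIDTH_MS = 50.0
TIE_REL_TOL = 1e-6


def raised_cosine(t, a: float, w: float, l: float):
    """Evaluate the raised-cosine lobe at time(s) ``t`` (ms).

    Peak value ``a`` at t = l; compact support [l − w/2, l + w/2]; zero at
    the support boundary and a/2 at l ± w/4.
    """
    if w <= 0:
        raise ConfigError("raised-cosine width must be positive")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    inside = np.abs(t - l) <= w / 2.0
    out[inside] = 0.5 * a * (1.0 + np.cos(2.0 * np.pi * (t[inside] - l) / w))
    return out if out.ndim else float(out)


def pair_loss(pre: tuple[float, float], emp: tuple[float, float]) -> float:
    """ℒ = ½[(A_sup^pre − A_sup^emp)² + (A_enh^pre − A_enh^emp)²]."""
    return 0.5 * ((pre[0] - emp[0]) ** 2 + (pre[1] - emp[1]) ** 2)


@dataclass
class EmpiricalAmplitudes:
    """Dip/peak magnitudes measured from both PSTH alignments."""

    shift_sup: float
    shift_enh: float
    fix_sup: float
    fix_enh: float

    @classmethod
    def from_metrics(
        cls,
        metrics_shift: psth_mod.ResponseMetrics,
        metrics_fix: psth_mod.ResponseMetrics,
    ) -> "EmpiricalAmplitudes":
        return cls(
            shift_sup=metrics_shift.a_sup,
            shift_enh=metrics_shift.a_enh,
            fix_sup=metrics_fix.a_sup,
            fix_enh=metrics_fix.a_enh,
        )

    def pair_for(self, model_kind: str) -> tuple[float, float]:
        """The (A_sup, A_enh) pair the loss uses for ``model_kind``:
        saccade-locked takes both from the shift alignment; two-stage takes
        suppression from the shift alignment and enhancement from the
        fixation alignment."""
        if model_kind == SACCADE_LOCKED:
            return (self.shift_sup, self.shift_enh)
        if model_kind == TWO_STAGE:
            return (self.shift_sup, self.fix_enh)
        raise ConfigError(f"unknown model kind {model_kind!r}")


@dataclass
class ModelFit:
    model_kind: str
    params: BasisParams
    loss: float
    n_iterations: int
    converged: bool
    predicted: dict = field(default_factory=dict)  # alignment -> (A_sup, A_enh)
    model_error: float | None = None
    init_flags: dict = field(default_factory=dict)


@dataclass
class ModelComparison:
    saccade_locked: ModelFit
    two_stage: ModelFit
    winner: str
    empirical: EmpiricalAmplitudes | None = None
    metrics_shift: psth_mod.ResponseMetrics | None = None
    metrics_fix: psth_mod.ResponseMetrics | None = None
    psth_shift: psth_mod.NormalizedPsth | None = None
    psth_fix: psth_mod.NormalizedPsth | None = None


# ---------------------------------------------------------------------------
# initialization

def _fwhm(time: np.ndarray, vals: np.ndarray, idx: int) -> float:
    """Full width at half amplitude of the lobe peaking/dipping at ``idx``."""
    extremum = vals[idx]
    half = extremum / 2.0
    sign = 1.0 if extremum >= 0 else -1.0
    # walk outward until the (signed) curve falls below half amplitude
    def cross(direction: int) -> float:
        i = idx
        while 0 <= i + direction < vals.size:
            j = i + direction
            if sign * vals[j] < sign * half:
                frac = (half - vals[i]) / (vals[j] - vals[i])
                return float(time[i] + frac * (time[j] - time[i]))
            i = j
        return float(time[i])

    return cross(+1) - cross(-1)


def init_params(
    shift_psth: psth_mod.NormalizedPsth,
    fix_psth: psth_mod.NormalizedPsth,
    model_kind: str,
    search_window_ms: tuple[float, float] = (0.0, 400.0),
    default_width_ms: float = DEFAULT_WIDTH_MS,
) -> tuple[BasisParams, dict]:
    """Initialize (a, w, l) per component from the empirical PSTHs.

    Latency is the extremum time, amplitude the (signed) extremum value, and
    the width is read off the lobe's full width at half amplitude: a
    raised-cosine lobe of width ``w`` reaches half amplitude at l ± w/4, so
    w = 2 × FWHM inverts the shape exactly.  The saccade-locked
    model takes both components from the shift-aligned PSTH; the two-stage
    model takes suppression from the shift-aligned and enhancement from the
    fixation-aligned PSTH.  A missing lobe is initialized at a = 0 with the
    default width and flagged.
    """
    flags = {"missing_sup": False, "missing_enh": False}
    ext_shift = psth_mod.find_extrema(shift_psth.time_bins, shift_psth.mean, search_window_ms)
    if ext_shift["trough_val"] < 0:
        w_sup = 2.0 * _fwhm(shift_psth.time_bins, shift_psth.mean, ext_shift["trough_idx"])
        sup = CosineComponent(ext_shift["trough_val"], max(w_sup, 1.0), ext_shift["trough_time"])
    else:
        flags["missing_sup"] = True
        sup = CosineComponent(0.0, default_width_ms, 30.0)

    enh_src = shift_psth if model_kind == SACCADE_LOCKED else fix_psth
    ext_enh = psth_mod.find_extrema(enh_src.time_bins, enh_src.mean, search_window_ms)
    if ext_enh["peak_val"] > 0:
        w_enh = 2.0 * _fwhm(enh_src.time_bins, enh_src.mean, ext_enh["peak_idx"])
        enh = CosineComponent(ext_enh["peak_val"], max(w_enh, 1.0), ext_enh["peak_time"])
    else:
        flags["missing_enh"] = True
        enh = CosineComponent(0.0, default_width_ms, 80.0)
    return BasisParams(suppression=sup, enhancement=enh), flags


# ---------------------------------------------------------------------------
# prediction

def _add_component(
    t_ms: np.ndarray,
    resp: np.ndarray,
    anchors_ms: np.ndarray,
    comp: CosineComponent,
    step: float,
    gains: np.ndarray | None = None,
) -> None:
    n = t_ms.size
    for k, anc in enumerate(anchors_ms):
        a = comp.a * (gains[k] if gains is not None else 1.0)
        if a == 0.0:
            continue
        lo = anc + comp.l - comp.w / 2.0
        hi = anc + comp.l + comp.w / 2.0
        i0 = max(0, int(np.ceil(lo / step)))
        i1 = min(n - 1, int(np.floor(hi / step)))
        if i1 < i0:
            continue
        tt = t_ms[i0 : i1 + 1]
        resp[i0 : i1 + 1] += 0.5 * a * (
            1.0 + np.cos(2.0 * np.pi * (tt - anc - comp.l) / comp.w)
        )


def _anchor_sets(events: list[GazeEvent], model_kind: str):
    shift_on = onsets_of(events, SHIFT) * 1000.0
    if model_kind == SACCADE_LOCKED:
        return shift_on, shift_on
    if model_kind == TWO_STAGE:
        return shift_on, onsets_of(events, FIXATION) * 1000.0
    raise ConfigError(f"unknown model kind {model_kind!r}")


def predict_continuous(
    events: list[GazeEvent],
    params: BasisParams,
    model_kind: str,
    session_length_s: float,
    sample_step_ms: float = 1.0,
    per_fixation_gain: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous normalized response over the session (1 ms grid).

    Suppression lobes are placed at every gaze-shift onset; enhancement lobes
    at shift onsets (saccade-locked) or fixation onsets (two-stage).
    Overlapping lobes sum linearly.  ``per_fixation_gain`` multiplies each
    fixation's enhancement amplitude (two-stage only).
    """
    t_ms = np.arange(0.0, session_length_s * 1000.0 + sample_step_ms / 2, sample_step_ms)
    resp = np.zeros_like(t_ms)
    if not events:
        return t_ms, resp
    sup_anchors, enh_anchors = _anchor_sets(events, model_kind)
    gains = None
    if per_fixation_gain is not None:
        if model_kind != TWO_STAGE:
            raise ConfigError("per_fixation_gain requires the two-stage model")
        gains = np.asarray(per_fixation_gain, dtype=float)
        if gains.size != enh_anchors.size:
            raise ConfigError("per_fixation_gain length must match fixation count")
    _add_component(t_ms, resp, sup_anchors, params.suppression, sample_step_ms)
    _add_component(t_ms, resp, enh_anchors, params.enhancement, sample_step_ms, gains)
    return t_ms, resp


@dataclass
class PredictedPsths:
    time_bins: np.ndarray
    shift_aligned: np.ndarray
    fixation_aligned: np.ndarray
    amplitudes: dict  # 'shift'/'fix' -> (A_sup, A_enh) magnitudes


def _full_window_anchors(
    anchors_s: np.ndarray, session_length_s: float, window_ms=psth_mod.WINDOW_MS
) -> np.ndarray:
    lo, hi = window_ms[0] / 1000.0, (window_ms[1] + 1.0) / 1000.0
    return anchors_s[(anchors_s + lo >= 0.0) & (anchors_s + hi <= session_length_s)]


def _windowed_average(
    t_ms: np.ndarray,
    resp: np.ndarray,
    anchors_ms: np.ndarray,
    time_bins: np.ndarray,
) -> np.ndarray:
    taus = time_bins + 0.5  # bin centers
    acc = np.zeros_like(taus)
    for anc in anchors_ms:
        acc += np.interp(anc + taus, t_ms, resp)
    return acc / max(len(anchors_ms), 1)


def _renormalize(curve: np.ndarray, time_bins: np.ndarray, baseline_window_ms) -> np.ndarray:
    sel = (time_bins >= baseline_window_ms[0]) & (time_bins < baseline_window_ms[1])
    b = float(curve[sel].mean())
    denom = max(1.0 + b, 0.05)
    return (1.0 + curve) / denom - 1.0


def _amplitudes_of(curve: np.ndarray, time_bins: np.ndarray, search_window_ms) -> tuple[float, float]:
    ext = psth_mod.find_extrema(time_bins, curve, search_window_ms)
    return (max(0.0, -ext["trough_val"]), max(0.0, ext["peak_val"]))


def predict_psths(
    t_ms: np.ndarray,
    resp: np.ndarray,
    events: list[GazeEvent],
    window_ms: tuple[float, float] = psth_mod.WINDOW_MS,
    baseline_window_ms: tuple[float, float] = psth_mod.BASELINE_WINDOW_MS,
    smoothing_sigma_ms: float = psth_mod.SMOOTHING_SIGMA_MS,
    search_window_ms: tuple[float, float] = (0.0, 400.0),
) -> PredictedPsths:
    """Predicted normalized PSTHs for both alignments, plus amplitudes.

    The continuous response is averaged over event windows, smoothed with the
    same Gaussian kernel as the empirical PSTHs, and renormalized so the
    pre-event baseline sits at 0 (mirroring the empirical normalization).
    Amplitudes use the same trough-then-peak extremum rules as
    :func:`gazephys.psth.extract_metrics`.
    """
    time_bins = np.arange(window_ms[0], window_ms[1] + 1.0)
    session_length_s = t_ms[-1] / 1000.0
    curves = {}
    for name, kind in (("shift", SHIFT), ("fix", FIXATION)):
        anchors = _full_window_anchors(onsets_of(events, kind), session_length_s, window_ms)
        raw = _windowed_average(t_ms, resp, anchors * 1000.0, time_bins)
        if smoothing_sigma_ms > 0:
            raw = gaussian_filter1d(raw, smoothing_sigma_ms, mode="reflect")
        curves[name] = _renormalize(raw, time_bins, baseline_window_ms)
    return PredictedPsths(
        time_bins=time_bins,
        shift_aligned=curves["shift"],
        fixation_aligned=curves["fix"],
        amplitudes={
            name: _amplitudes_of(c, time_bins, search_window_ms)
            for name, c in curves.items()
        },
    )


# ---------------------------------------------------------------------------
# fitting

class _AmplitudePredictor:
    """Predicted amplitudes as a function of (a_sup, a_enh).

    The windowed-average and smoothing steps are linear in the amplitudes, so
    unit-amplitude component curves are precomputed once; only the (cheap)
    baseline renormalization and extremum extraction run per loss evaluation.
    """

    def __init__(
        self,
        events: list[GazeEvent],
        params: BasisParams,
        model_kind: str,
        session_length_s: float,
        sample_step_ms: float = 1.0,
        smoothing_sigma_ms: float = psth_mod.SMOOTHING_SIGMA_MS,
        window_ms: tuple[float, float] = psth_mod.WINDOW_MS,
        baseline_window_ms: tuple[float, float] = psth_mod.BASELINE_WINDOW_MS,
        search_window_ms: tuple[float, float] = (0.0, 400.0),
    ) -> None:
        self.time_bins = np.arange(window_ms[0], window_ms[1] + 1.0)
        self.baseline_window_ms = baseline_window_ms
        self.search_window_ms = search_window_ms
        sup_anchors, enh_anchors = _anchor_sets(events, model_kind)
        unit = {
            "sup": CosineComponent(1.0, params.suppression.w, params.suppression.l),
            "enh": CosineComponent(1.0, params.enhancement.w, params.enhancement.l),
        }
        anchor_map = {"sup": sup_anchors, "enh": enh_anchors}
        t_ms = np.arange(0.0, session_length_s * 1000.0 + sample_step_ms / 2, sample_step_ms)
        self.unit_curves: dict[tuple[str, str], np.ndarray] = {}
        align_anchors = {
            "shift": _full_window_anchors(onsets_of(events, SHIFT), session_length_s, window_ms) * 1000.0,
            "fix": _full_window_anchors(onsets_of(events, FIXATION), session_length_s, window_ms) * 1000.0,
        }
        for comp_name, comp in unit.items():
            resp = np.zeros_like(t_ms)
            _add_component(t_ms, resp, anchor_map[comp_name], comp, sample_step_ms)
            for align, anchors in align_anchors.items():
                raw = _windowed_average(t_ms, resp, anchors, self.time_bins)
                if smoothing_sigma_ms > 0:
                    raw = gaussian_filter1d(raw, smoothing_sigma_ms, mode="reflect")
                self.unit_curves[(align, comp_name)] = raw

    def curves(self, a_sup: float, a_enh: float) -> dict[str, np.ndarray]:
        out = {}
        for align in ("shift", "fix"):
            raw = (
                a_sup * self.unit_curves[(align, "sup")]
                + a_enh * self.unit_curves[(align, "enh")]
            )
            out[align] = _renormalize(raw, self.time_bins, self.baseline_window_ms)
        return out

    def amplitudes(self, a_sup: float, a_enh: float) -> dict[str, tuple[float, float]]:
        return {
            align: _amplitudes_of(c, self.time_bins, self.search_window_ms)
            for align, c in self.curves(a_sup, a_enh).items()
        }


def fit_amplitudes(
    params0: BasisParams,
    events: list[GazeEvent],
    model_kind: str,
    empirical: EmpiricalAmplitudes,
    session_length_s: float,
    loss_tol: float = LOSS_TOL,
    max_iter: int = MAX_ITER,
    sample_step_ms: float = 1.0,
    init_flags: dict | None = None,
) -> ModelFit:
    """Fit (a_sup, a_enh) by constrained minimization of the amplitude loss.

    Widths and latencies stay fixed at their initialized values; amplitudes
    are constrained to a_sup ≤ 0, a_enh ≥ 0.  Optimization stops when the
    loss falls below ``loss_tol`` or after ``max_iter`` iterations.
    """
    predictor = _AmplitudePredictor(
        events, params0, model_kind, session_length_s, sample_step_ms
    )
    emp_pair = empirical.pair_for(model_kind)
    align_sup = "shift"
    align_enh = "shift" if model_kind == SACCADE_LOCKED else "fix"

    def loss_fn(x: np.ndarray) -> float:
        amps = predictor.amplitudes(x[0], x[1])
        pre = (amps[align_sup][0], amps[align_enh][1])
        return pair_loss(pre, emp_pair)

    x0 = np.array([min(params0.suppression.a, 0.0), max(params0.enhancement.a, 0.0)])
    loss0 = loss_fn(x0)
    if loss0 < loss_tol:
        x, loss, n_iter, success = x0, loss0, 0, True
    else:
        res = minimize(
            loss_fn,
            x0,
            method="SLSQP",
            bounds=[(-1e3, 0.0), (0.0, 1e3)],
            options={"maxiter": max_iter, "ftol": 1e-14},
        )
        x = res.x
        loss = float(loss_fn(x))
        if loss0 < loss:  # keep the best iterate if the optimizer went uphill
            x, loss = x0, loss0
        n_iter = int(min(getattr(res, "nit", max_iter), max_iter))
        success = bool(res.success)
    fitted = params0.with_amplitudes(float(min(x[0], 0.0)), float(max(x[1], 0.0)))
    predicted = predictor.amplitudes(fitted.suppression.a, fitted.enhancement.a)
    return ModelFit(
        model_kind=model_kind,
        params=fitted,
        loss=float(loss),
        n_iterations=n_iter,
        converged=bool(loss < loss_tol or success),
        predicted=predicted,
        init_flags=init_flags or {},
    )


def model_error(fit: ModelFit, empirical: EmpiricalAmplitudes) -> float:
    """Mean squared amplitude error across both alignments (four terms)."""
    pre_shift = fit.predicted["shift"]
    pre_fix = fit.predicted["fix"]
    errs = [
        pre_shift[0] - empirical.shift_sup,
        pre_shift[1] - empirical.shift_enh,
        pre_fix[0] - empirical.fix_sup,
        pre_fix[1] - empirical.fix_enh,
    ]
    err = float(np.mean(np.square(errs)))
    fit.model_error = err
    return err


def compare_models(
    spikes: np.ndarray,
    events: list[GazeEvent],
    session_length_s: float,
    n_folds: int = psth_mod.N_FOLDS,
    tie_rel_tol: float = TIE_REL_TOL,
) -> ModelComparison:
    """Fit both models to one neuron and pick the smaller-error model.

    Empirical amplitudes come from the shift- and fixation-aligned
    normalized PSTHs (full-window anchors only).  The winner is the model
    with the smaller four-term mean squared amplitude error; errors within a
    relative ``tie_rel_tol`` are declared a tie.
    """
    psths = {}
    for name, kind, anchor_kind in (
        ("shift", SHIFT, "shift_onset"),
        ("fix", FIXATION, "fixation_onset"),
    ):
        anchors = _full_window_anchors(onsets_of(events, kind), session_length_s)
        psths[name] = psth_mod.compute_normalized_psth(
            spikes, anchors, anchor_kind=anchor_kind, n_folds=n_folds
        )
    metrics_shift = psth_mod.extract_metrics(psths["shift"])
    metrics_fix = psth_mod.extract_metrics(psths["fix"])
    emp = EmpiricalAmplitudes.from_metrics(metrics_shift, metrics_fix)
    fits = {}
    for kind in (SACCADE_LOCKED, TWO_STAGE):
        params0, flags = init_params(psths["shift"], psths["fix"], kind)
        fit = fit_amplitudes(params0, events, kind, emp, session_length_s, init_flags=flags)
        model_error(fit, emp)
        fits[kind] = fit
    e_sl = fits[SACCADE_LOCKED].model_error
    e_ts = fits[TWO_STAGE].model_error
    denom = max(e_sl, e_ts)
    if denom < 1e-15 or abs(e_sl - e_ts) / denom < tie_rel_tol:
        winner = "tie"
    else:
        winner = SACCADE_LOCKED if e_sl < e_ts else TWO_STAGE
    return ModelComparison(
        saccade_locked=fits[SACCADE_LOCKED],
        two_stage=fits[TWO_STAGE],
        winner=winner,
        empirical=emp,
        metrics_shift=metrics_shift,
        metrics_fix=metrics_fix,
        psth_shift=psths["shift"],
        psth_fix=psths["fix"],
    )
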