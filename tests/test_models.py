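"""Raised-cosine models: prediction, initialization, fitting, comparison."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazephys import models, psth, synthetic as syn
from gazephys.types import (
    SACCADE_LOCKED,
    TWO_STAGE,
    BasisParams,
    ConfigError,
    CosineComponent,
    GazeEvent,
)

TIME = np.arange(-200.0, 401.0)


def _alternating_events(durations_s, fixation_s=0.5, start=1.0):
    # starts with a shift so every fixation has a preceding shift (fixation
    # anchors at the session start would contribute an extra enhancement
    # lobe with no saccade-locked counterpart)
    events, cursor = [], start
    for d in durations_s:
        events.append(GazeEvent("shift", cursor, cursor + d))
        events.append(GazeEvent("fixation", cursor + d, cursor + d + fixation_s))
        cursor += d + fixation_s
    return events, cursor


class TestRaisedCosine:
    def test_peak_boundary_and_quarter_points(self):
        assert models.raised_cosine(50.0, 1.0, 80.0, 50.0) == pytest.approx(1.0)
        assert models.raised_cosine(90.0, 1.0, 80.0, 50.0) == pytest.approx(0.0, abs=1e-12)
        assert models.raised_cosine(70.0, 0.8, 80.0, 50.0) == pytest.approx(0.4)

    def test_invalid_width_rejected(self):
        with pytest.raises(ConfigError):
            models.raised_cosine(0.0, 1.0, 0.0, 0.0)
        with pytest.raises(ConfigError):
            CosineComponent(1.0, -5.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(-2.0, 2.0),
        w=st.floats(1.0, 300.0),
        l=st.floats(-100.0, 300.0),
    )
    def test_compact_support_and_peak_bound(self, a, w, l):
        t = np.linspace(l - w, l + w, 401)
        f = models.raised_cosine(t, a, w, l)
        outside = np.abs(t - l) > w / 2
        assert np.all(f[outside] == 0.0)
        assert np.max(np.abs(f)) <= abs(a) + 1e-12


class TestLoss:
    def test_printed_example(self):
        assert models.pair_loss((0.6, 1.2), (0.5, 1.0)) == pytest.approx(0.025)

    def test_model_error_examples(self):
        fit = models.ModelFit(
            model_kind=SACCADE_LOCKED,
            params=syn.default_basis(),
            loss=0.0,
            n_iterations=0,
            converged=True,
            predicted={"shift": (0.5, 1.0), "fix": (0.2, 1.1)},
        )
        emp = models.EmpiricalAmplitudes(0.5, 1.0, 0.2, 1.1)
        assert models.model_error(fit, emp) == 0.0
        emp2 = models.EmpiricalAmplitudes(0.6, 1.1, 0.3, 1.2)
        assert models.model_error(fit, emp2) == pytest.approx(0.01)


class TestInitParams:
    def _psth(self, curve):
        return psth.NormalizedPsth(
            time_bins=TIME, mean=curve, se=np.full(TIME.size, 0.01),
            baseline_rate=10.0, n_events=100,
        )

    def test_recovers_raised_cosine_parameters(self):
        shift_curve = models.raised_cosine(TIME, -0.5, 60.0, 30.0)
        fix_curve = models.raised_cosine(TIME, 1.0, 100.0, 80.0)
        params, flags = models.init_params(
            self._psth(shift_curve), self._psth(fix_curve), TWO_STAGE
        )
        assert params.suppression.l == pytest.approx(30.0, abs=1.0)
        assert params.suppression.a == pytest.approx(-0.5, abs=0.01)
        assert params.suppression.w == pytest.approx(60.0, abs=2.0)
        assert params.enhancement.l == pytest.approx(80.0, abs=1.0)
        assert params.enhancement.w == pytest.approx(100.0, abs=2.0)
        assert not flags["missing_sup"] and not flags["missing_enh"]

    def test_two_stage_takes_enhancement_from_fixation_psth(self):
        shift_curve = models.raised_cosine(TIME, -0.5, 60.0, 30.0) + models.raised_cosine(
            TIME, 0.4, 100.0, 200.0
        )
        fix_curve = models.raised_cosine(TIME, 1.0, 100.0, 80.0)
        ts, _ = models.init_params(self._psth(shift_curve), self._psth(fix_curve), TWO_STAGE)
        sl, _ = models.init_params(self._psth(shift_curve), self._psth(fix_curve), SACCADE_LOCKED)
        assert ts.enhancement.l == pytest.approx(80.0, abs=1.0)
        assert sl.enhancement.l == pytest.approx(200.0, abs=1.0)

    def test_flat_psths_initialize_at_zero(self):
        flat = self._psth(np.zeros(TIME.size))
        params, flags = models.init_params(flat, flat, SACCADE_LOCKED)
        assert params.suppression.a == 0.0 and params.enhancement.a == 0.0
        assert flags["missing_sup"] and flags["missing_enh"]


class TestPredict:
    def test_no_events_gives_zero_response(self):
        t, r = models.predict_continuous([], syn.default_basis(), TWO_STAGE, 10.0)
        assert not r.any()

    def test_single_shift_superposition(self):
        basis = syn.default_basis()
        events = [GazeEvent("shift", 2.0, 2.1)]
        t, r = models.predict_continuous(events, basis, SACCADE_LOCKED, 10.0)
        rel = t - 2000.0
        expected = models.raised_cosine(
            rel, basis.suppression.a, basis.suppression.w, basis.suppression.l
        ) + models.raised_cosine(
            rel, basis.enhancement.a, basis.enhancement.w, basis.enhancement.l
        )
        assert np.allclose(r, expected, atol=1e-12)

    def test_two_stage_enhancement_displaced_by_duration(self):
        basis = syn.default_basis(a_sup=-0.0001)  # isolate the enhancement lobe
        d = 0.150
        events = [GazeEvent("shift", 2.0, 2.0 + d), GazeEvent("fixation", 2.0 + d, 4.0)]
        t, r_ts = models.predict_continuous(events, basis, TWO_STAGE, 10.0)
        _, r_sl = models.predict_continuous(events, basis, SACCADE_LOCKED, 10.0)
        shift_samples = int(d * 1000)
        assert np.allclose(r_ts[shift_samples:], r_sl[:-shift_samples], atol=1e-4)

    def test_superposition_over_event_lists(self):
        basis = syn.default_basis()
        ev_a, _ = _alternating_events([0.05, 0.1])
        ev_b = [GazeEvent("shift", 6.0, 6.08), GazeEvent("fixation", 6.08, 7.0)]
        _, r_ab = models.predict_continuous(ev_a + ev_b, basis, TWO_STAGE, 10.0)
        _, r_a = models.predict_continuous(ev_a, basis, TWO_STAGE, 10.0)
        _, r_b = models.predict_continuous(ev_b, basis, TWO_STAGE, 10.0)
        assert np.allclose(r_ab, r_a + r_b, atol=1e-12)

    def test_degenerate_equivalence_with_constant_durations(self):
        # identical shift durations make the two-stage model with enhancement
        # latency l prediction-identical to saccade-locked with latency l + d
        d = 0.100
        events, _ = _alternating_events([d] * 8, fixation_s=0.6)
        b_ts = syn.default_basis()
        b_sl = syn.default_basis(l_enh=b_ts.enhancement.l + d * 1000.0)
        L = events[-1].offset + 1.0
        _, r_ts = models.predict_continuous(events, b_ts, TWO_STAGE, L)
        _, r_sl = models.predict_continuous(events, b_sl, SACCADE_LOCKED, L)
        assert np.max(np.abs(r_ts - r_sl)) < 1e-9

    def test_zero_response_gives_zero_psths(self):
        events, L = _alternating_events([0.05, 0.08])
        t = np.arange(0.0, (L + 1) * 1000.0)
        pred = models.predict_psths(t, np.zeros_like(t), events)
        assert not pred.shift_aligned.any() and not pred.fixation_aligned.any()
        assert pred.amplitudes["shift"] == (0.0, 0.0)

    def test_single_event_psth_equals_windowed_response(self):
        basis = syn.default_basis()
        events = [GazeEvent("shift", 2.0, 2.1)]
        t, r = models.predict_continuous(events, basis, SACCADE_LOCKED, 10.0)
        pred = models.predict_psths(t, r, events, smoothing_sigma_ms=0.0)
        rel = TIME + 0.5
        expected = models.raised_cosine(
            rel, basis.suppression.a, basis.suppression.w, basis.suppression.l
        ) + models.raised_cosine(
            rel, basis.enhancement.a, basis.enhancement.w, basis.enhancement.l
        )
        assert np.allclose(pred.shift_aligned, expected, atol=1e-3)


class TestFit:
    def test_fixed_point_leaves_amplitudes_unchanged(self):
        events, L = _alternating_events([0.08] * 12, fixation_s=0.7)
        params0 = syn.default_basis()
        predictor = models._AmplitudePredictor(events, params0, TWO_STAGE, L + 1)
        amps = predictor.amplitudes(-0.5, 1.0)
        emp = models.EmpiricalAmplitudes(
            shift_sup=amps["shift"][0], shift_enh=amps["shift"][1],
            fix_sup=amps["fix"][0], fix_enh=amps["fix"][1],
        )
        fit = models.fit_amplitudes(params0, events, TWO_STAGE, emp, L + 1)
        assert fit.loss < 1e-6
        assert fit.n_iterations == 0 and fit.converged
        assert fit.params.suppression.a == -0.5
        assert fit.params.enhancement.a == 1.0

    def test_constraints_enforced_and_iteration_cap(self):
        events, L = _alternating_events([0.08] * 12, fixation_s=0.7)
        params0 = syn.default_basis(a_sup=-0.1, a_enh=0.1)
        emp = models.EmpiricalAmplitudes(0.7, 0.2, 0.1, 1.3)
        fit = models.fit_amplitudes(params0, events, TWO_STAGE, emp, L + 1)
        assert fit.params.suppression.a <= 0.0 <= fit.params.enhancement.a
        assert fit.n_iterations <= 20
        assert fit.loss < models.pair_loss((0.0, 0.0), emp.pair_for(TWO_STAGE))


class TestCompare:
    def test_two_stage_truth_recovers_and_wins(self, two_stage_study):
        amps = two_stage_study.fitted_amplitudes
        assert amps.shape == (50, 2)
        # amplitudes constrained to their signs
        assert np.all(amps[:, 0] <= 0) and np.all(amps[:, 1] >= 0)
        assert two_stage_study.win_fraction(TWO_STAGE) > 0.5

    def test_losses_are_nonnegative_and_errors_finite(self, two_stage_study):
        for n in two_stage_study.neurons:
            for fit in (n.comparison.saccade_locked, n.comparison.two_stage):
                assert fit.loss >= 0.0
                assert np.isfinite(fit.model_error) and fit.model_error >= 0.0
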