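"""Generator statistics: determinism, gaze structure, spiking, stimuli."""
import numpy as np
import pytest

from gazephys import events as ev, models, rf, synthetic as syn
from gazephys.types import (
    FIXATION,
    SHIFT,
    TWO_STAGE,
    ConfigError,
    GazeTrace,
    validate_event_sequence,
)


class TestGazeTrace:
    def test_deterministic_under_fixed_seed(self):
        cfg = syn.GazeConfig(session_length_s=80.0, n_shifts=100)
        t1, g1 = syn.generate_gaze_trace(cfg, seed=5)
        t2, g2 = syn.generate_gaze_trace(cfg, seed=5)
        assert np.array_equal(t1.eye_pos, t2.eye_pos)
        assert np.array_equal(t1.body_pos, t2.body_pos)
        assert [(e.kind, e.onset, e.offset) for e in g1.events] == [
            (e.kind, e.onset, e.offset) for e in g2.events
        ]
        assert len(g1.shifts) == 100

    def test_zero_shift_config_is_one_quiet_fixation(self):
        trace, truth = syn.generate_gaze_trace(
            syn.GazeConfig(session_length_s=30.0, n_shifts=0), seed=3
        )
        assert len(truth.events) == 1
        fx = truth.events[0]
        assert fx.kind == FIXATION and fx.onset == 0.0 and fx.offset == 30.0
        speed = ev.gaze_speed(ev.compute_gaze(trace), trace.sample_rate)
        assert speed.max() < 0.2

    def test_events_tile_the_session(self, short_session):
        _, truth = short_session
        validate_event_sequence(truth.events)
        assert truth.events[0].onset == 0.0
        assert truth.events[-1].offset == pytest.approx(truth.session_length)
        for a, b in zip(truth.events, truth.events[1:]):
            assert a.offset == pytest.approx(b.onset)

    def test_eye_head_velocity_anticorrelated_in_fixations(self, short_session):
        trace, truth = short_session
        vel_e = np.gradient(trace.eye_pos, axis=0) * trace.sample_rate
        vel_h = np.gradient(trace.head_pos, axis=0) * trace.sample_rate
        t = trace.timestamps
        mask = np.zeros(trace.n_samples, dtype=bool)
        for fx in truth.fixations:
            mask |= (t >= fx.onset + 0.05) & (t < fx.offset - 0.05)
        for axis in (0, 1):
            r = np.corrcoef(vel_e[mask, axis], vel_h[mask, axis])[0, 1]
            assert r <= -0.8

    def test_shift_speed_above_threshold_and_shared_sign(self, short_session):
        trace, truth = short_session
        gaze = ev.compute_gaze(trace)
        speed = ev.gaze_speed(gaze, trace.sample_rate)
        vel_e = np.gradient(trace.eye_pos, axis=0) * trace.sample_rate
        vel_h = np.gradient(trace.head_pos, axis=0) * trace.sample_rate
        t = trace.timestamps
        agree = []
        for sh in truth.shifts:
            inner = (t >= sh.onset + 0.01) & (t <= sh.offset - 0.01)
            if inner.sum() < 2:
                continue
            assert speed[inner].min() > 0.2
            dom = np.argmax(np.abs(vel_h[inner].mean(axis=0)))
            agree.append(np.sign(vel_e[inner, dom].mean()) == np.sign(vel_h[inner, dom].mean()))
        assert np.mean(agree) > 0.9

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigError):
            syn.generate_gaze_trace(syn.GazeConfig(session_length_s=-1.0), seed=0)
        with pytest.raises(ConfigError):
            syn.generate_gaze_trace(syn.GazeConfig(sample_rate=0.0), seed=0)


class TestSpikes:
    def test_homogeneous_poisson_count(self):
        _, truth = syn.generate_gaze_trace(
            syn.GazeConfig(session_length_s=100.0, n_shifts=0), seed=9
        )
        truth = truth.with_model("none", baseline_rate=10.0)
        spikes = syn.generate_spike_train(truth, seed=2)
        assert abs(len(spikes) - 1000) < 4 * np.sqrt(1000)

    def test_rate_floor_at_zero(self):
        # a = -1 drives the rate to zero at the lobe peak
        basis = syn.default_basis(a_sup=-1.0)
        f = models.raised_cosine(basis.suppression.l, basis.suppression.a,
                                 basis.suppression.w, basis.suppression.l)
        assert f == pytest.approx(-1.0)
        assert max(0.0, 1.0 + f) == 0.0

    def test_counts_match_rate_integral(self):
        _, truth = syn.generate_gaze_trace(syn.GazeConfig(session_length_s=100.0), seed=13)
        truth = truth.with_model(TWO_STAGE, syn.default_basis(), 10.0)
        t_ms, m = models.predict_continuous(
            truth.events, truth.true_basis, TWO_STAGE, truth.session_length
        )
        expected = np.trapezoid(10.0 * np.maximum(0.0, 1.0 + m), t_ms / 1000.0)
        counts = [
            len(syn.generate_spike_train(truth, seed=s)) for s in range(30)
        ]
        z = (np.mean(counts) - expected) / (np.sqrt(expected) / np.sqrt(30))
        assert abs(z) < 4.0

    def test_model_required(self):
        _, truth = syn.generate_gaze_trace(syn.GazeConfig(session_length_s=10.0), seed=1)
        with pytest.raises(ConfigError):
            syn.generate_spike_train(truth, seed=0)


class TestGrating:
    def test_opposite_orientations_identical(self):
        a = syn.generate_grating(0.0, 1.0, 5.0, 0.1)
        b = syn.generate_grating(180.0, 1.0, 5.0, 0.1)
        assert np.allclose(a, b)

    def test_cycles_per_degree(self):
        # 1 c/deg over a 5 deg window -> dominant frequency at 5 cycles/window
        img = syn.generate_grating(0.0, 1.0, 5.0, 0.1)
        row = img[img.shape[0] // 2] - img[img.shape[0] // 2].mean()
        k = np.argmax(np.abs(np.fft.rfft(row)))
        assert k == 5

    def test_orthogonal_spectra_are_transposes(self):
        s0 = rf.log_magnitude_spectrum(syn.generate_grating(0.0, 1.0, 5.0, 0.1))
        s90 = rf.log_magnitude_spectrum(syn.generate_grating(90.0, 1.0, 5.0, 0.1))
        assert np.allclose(s0, s90.T, atol=1e-9)

    def test_range_and_aliasing(self):
        img = syn.generate_grating(30.0, 2.0, 5.0, 0.15)
        assert img.min() >= 0.0 and img.max() <= 1.0
        with pytest.raises(ConfigError):
            syn.generate_grating(0.0, 4.0, 5.0, 0.15)  # < 2 px per cycle


class TestTuning:
    def test_preferred_condition_is_argmax(self):
        # the 12 directions cover each orientation twice (30° steps over
        # 360°), so the argmax is checked modulo 180°
        res = syn.generate_tuning_session(90.0, 1.0, n_repeats=20, seed=2)
        ori, sf = res.conditions[int(np.argmax(res.rates))]
        assert (ori % 180.0, sf) == (90.0, 1.0)
        ori_e, sf_e = res.conditions[int(np.argmax(res.expected))]
        assert (ori_e % 180.0, sf_e) == (90.0, 1.0)

    def test_delta_tuning_limit(self):
        res = syn.generate_tuning_session(60.0, 0.5, tuning_widths=(0.0, 0.0), seed=0)
        mask = np.array([(c[0] % 180.0, c[1]) == (60.0, 0.5) for c in res.conditions])
        assert np.all(res.expected[~mask] == res.expected[~mask][0])
        assert res.expected[mask][0] > res.expected[~mask][0]

    def test_flat_tuning_limit(self):
        res = syn.generate_tuning_session(
            60.0, 0.5, tuning_widths=(np.inf, np.inf), seed=0
        )
        assert np.allclose(res.expected, res.expected[0])


class TestSceneFrames:
    @staticmethod
    def _static_trace(eye=(1.0, -2.0), head=(3.0, 4.0), n=50, rate=200.0):
        return GazeTrace(
            timestamps=np.arange(n) / rate,
            eye_pos=np.tile(eye, (n, 1)),
            head_pos=np.tile(head, (n, 1)),
            body_pos=np.zeros((n, 2)),
            head_height=np.full(n, 25.0),
            sample_rate=rate,
        )

    def test_static_gaze_gives_identical_frames(self):
        fs = syn.generate_scene_frames(
            self._static_trace(), syn.WallPattern.random(0), frame_rate=10.0
        )
        assert fs.n_frames >= 2
        assert np.array_equal(fs.frames[0], fs.frames[1])

    def test_validity_false_when_crop_leaves_frame(self):
        # eye far off-axis pushes the gaze+RF crop outside the 40 deg frame
        fs = syn.generate_scene_frames(
            self._static_trace(eye=(19.0, 0.0)), syn.WallPattern.random(0), frame_rate=10.0
        )
        assert not fs.validity.any()

    def test_validity_flag_agrees_with_crop_extraction(self, drive_fixture):
        frameset = drive_fixture.session.frameset
        for j in range(0, frameset.n_frames, 37):
            crop = rf.extract_rf_input(
                frameset.frames[j],
                tuple(frameset.gaze_center_px[j]),
                frameset.rf_offset_deg,
                frameset.deg_per_px,
            )
            assert frameset.validity[j] == (crop is not None)

    def test_frame_rate_validation(self):
        with pytest.raises(ConfigError):
            syn.generate_scene_frames(
                self._static_trace(), syn.WallPattern.random(0), frame_rate=500.0
            )


class TestGainCoupling:
    def test_monotone_and_neutral_for_excluded(self):
        d = np.array([0.3, np.nan, 0.1, 0.5, 0.2])
        g = syn.couple_gain_to_drive(d, (0.5, 1.5))
        assert g[1] == 1.0
        finite = np.isfinite(d)
        order_d = np.argsort(d[finite])
        assert np.all(np.diff(g[finite][order_d]) > 0)
        assert g[finite].min() == 0.5 and g[finite].max() == 1.5
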