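# gazephys

Analysis of primary visual cortex (V1) activity during natural gaze behavior
in freely moving animals.  When an animal redirects its gaze with a combined
eye–head movement, V1 responses show a brief *suppression* time-locked to the
gaze shift followed by an *enhancement* associated with the new fixation.
`gazephys` implements the full analysis chain needed to measure and model
this sequence from raw behavioral traces and spike times, together with a
synthetic-session generator that produces ground-truth-labeled data for
validating every stage.

The package is aimed at systems neuroscientists working with chronic
recordings plus head-mounted eye tracking: it turns eye/head/body time
series into labeled gaze events, computes event-aligned firing statistics,
fits compact parametric response models, and scores the visual content each
fixation delivers to a neuron's receptive field.

## What it computes

**Gaze events.** Eye and head position are upsampled to 200 Hz (linear
interpolation) and summed into gaze position.  Samples whose gaze speed
exceeds 0.2 deg/ms are gaze shifts, the rest fixations.  Locomotion bouts
(body speed > 3 cm/s after a 0.2 Hz low-pass, head height < 18 cm, duration
> 3 s) are excluded.

**Normalized PSTHs.** Spike counts in 1 ms bins over −200..400 ms around
event onsets; a 10-fold jackknife (contiguous folds) with Gaussian smoothing
(σ = 5 ms) gives the mean and standard error; dividing by the pre-event
baseline (−200..−100 ms) and subtracting 1 normalizes the response.
Suppression and enhancement amplitudes are the maximum dip and peak;
significance is |z| > 2 at the extremum bin; the response latency is the
suppression-to-enhancement zero crossing.  Neurons under 1 Hz are excluded.

**Parametric models.** Each response component is a raised cosine

    f(t) = a/2 · (1 + cos(2π (t − l) / w)),   |t − l| ≤ w/2,

with amplitude *a*, width *w*, latency *l*.  The *saccade-locked* model
anchors both components at gaze-shift onsets; the *two-stage* model anchors
suppression at shift onsets and enhancement at fixation onsets.  Lobes sum
into a continuous response over the whole session; predicted event-aligned
PSTHs are extracted exactly like the empirical ones.  With *w*, *l* fixed
from the data, the amplitudes minimize

    ℒ(a_sup, a_enh) = ½ [(A_sup^pre − A_sup^emp)² + (A_enh^pre − A_enh^emp)²]

subject to a_sup ≤ 0 ≤ a_enh (stop at ℒ < 10⁻⁶ or 20 iterations), and the
models are compared by the mean squared amplitude error across both
alignments.  Because gaze-shift durations vary, the two models are
distinguishable; with identical durations they become prediction-identical.

**Receptive-field drive.** Reverse correlation (spike-triggered average of
flashing-dot frames) locates the RF; a 5×5 deg window is placed on its
center.  The preferred spectrum F_PREF is the firing-rate-weighted sum of
the FFT log-magnitude spectra of the grating stimulus conditions
(12 orientations × 3 spatial frequencies), scaled to [0, 1].  For each
fixation, the RF crop of the world-camera frame (2nd → 3rd → 1st frame
preference) is mean-subtracted, raised-cosine tapered, Fourier transformed,
and scored against the preferred spectrum:

    D = (1/N) Σ_{m,n} F_RF(m,n) · F_PREF(m,n).

Fixations in the top/bottom tertile of D are the preferred / non-preferred
visual-input events whose conditioned PSTHs reveal whether enhancement is
stimulus-driven.

## Worked example

```python
import numpy as np
from gazephys import events, models, synthetic as syn

# simulate a 2-minute freely-moving session with a two-stage neuron
config = syn.GazeConfig(session_length_s=120.0)
trace, truth = syn.generate_gaze_trace(config, seed=42)
truth = truth.with_model("two_stage", syn.default_basis(), baseline_rate=10.0)
spikes = syn.generate_spike_train(truth, seed=43)

# segment gaze into shifts and fixations
gaze = events.compute_gaze(trace)
evts = events.detect_events(gaze, trace.sample_rate)
print(f"detected {sum(e.kind == 'shift' for e in evts)} gaze shifts")

# fit both response models and compare
comp = models.compare_models(spikes, evts, trace.duration)
m = comp.metrics_shift
print(f"shift-aligned: A_sup={m.a_sup:.2f} A_enh={m.a_enh:.2f} "
      f"latency={m.latency_ms:.0f} ms")
ts = comp.two_stage
print(f"two-stage fit: a_sup={ts.params.suppression.a:.2f} "
      f"a_enh={ts.params.enhancement.a:.2f} model_error={ts.model_error:.4f}")
print(f"saccade-locked model_error={comp.saccade_locked.model_error:.4f} "
      f"-> winner: {comp.winner}")
```

prints

```
detected 179 gaze shifts
shift-aligned: A_sup=0.41 A_enh=0.86 latency=69 ms
two-stage fit: a_sup=-0.37 a_enh=1.02 model_error=0.1058
saccade-locked model_error=0.2089 -> winner: two_stage
```

The neuron was generated with a_sup = −0.5, a_enh = 1.0 anchored at shift
and fixation onsets respectively.  The shift-aligned enhancement (0.86) is
smaller than the fitted fixation-anchored amplitude (1.02) because variable
shift durations smear a fixation-locked lobe in shift-aligned coordinates —
exactly the signature that makes the two-stage model win (its four-term
amplitude error is half the saccade-locked model's).

A command-line pipeline wraps the same machinery:

```bash
gazephys simulate --out session/ --seed 1 --n-neurons 5
gazephys run --data session/ --out results/
gazephys report --results results/
```

## Layout

| module                | contents                                                      |
| --------------------- | ------------------------------------------------------------- |
| `gazephys.synthetic`  | gaze/spike/stimulus/scene generators with ground truth        |
| `gazephys.events`     | resampling, gaze computation, event & locomotion detection    |
| `gazephys.psth`       | raw/jackknifed/normalized PSTHs, response metrics, population |
| `gazephys.models`     | raised-cosine models, continuous prediction, fitting          |
| `gazephys.rf`         | RF mapping, preferred spectra, fixation drive, tertiles       |
| `gazephys.studies`    | end-to-end simulation studies used by tests and reports       |
| `gazephys.io`         | CSV/JSON/TIFF readers and writers                             |
| `gazephys.cli`        | `gazephys simulate / run / report`                            |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
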