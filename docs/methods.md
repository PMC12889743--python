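# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `gazephys`, and what the synthetic-data validation does
and does not establish.

## Gaze segmentation

Gaze is the per-sample sum of eye-in-head and head position (degrees), after
linear upsampling of all channels to 200 Hz.  "Gaze velocity" is the
magnitude of the central-difference 2D velocity; the 0.2 deg/ms threshold is
applied to this scalar speed.  A signed threshold on a single channel would
be direction-dependent; the magnitude is the only sign-free reading, and the
channel choice is configurable.  Two robustness measures guard the
threshold: a short median pre-filter on speed (5 ms nominal, never fewer
than 3 samples) removes single-sample chatter, and runs shorter than 5 ms
(1 sample at 200 Hz) are merged into their neighbour.  Both are no-ops on
clean traces; neither moves a threshold crossing on monotone speed segments
by more than one sample.

Locomotion exclusion requires all three criteria simultaneously: low-passed
body speed above 3 cm/s, head height below 18 cm, and more than 3 s of
contiguous duration.  The low-pass is a zero-phase second-order Butterworth
at 0.2 Hz applied to the speed signal.  Events are dropped, not split, when
their onset falls inside an excluded interval; partial overlap at mask
boundaries is not clipped.

## PSTH statistics

PSTHs use 1 ms bins with left-edge convention (bin *t* covers [t, t+1) ms)
over −200..400 ms (601 bins).  The jackknife partitions events into 10
contiguous folds in time order — contiguity preserves slow nonstationarity
within folds instead of hiding it — and each leave-one-fold-out replicate is
Gaussian-smoothed (σ = 5 ms, reflect padding) before the mean and
SE = sqrt((n−1)/n·Σ(θᵢ−θ̄)²) are formed.  When all replicates are
bit-identical the SE is set to exactly 0 (mean-of-identical-floats rounding
would otherwise leave ~1e−10 jitter).  Normalization divides by the mean
rate over −200..−100 ms and subtracts 1; a zero baseline raises an error
and excludes the neuron, as does a session-mean rate below 1 Hz (strict
inequality; exactly 1 Hz is retained).

Amplitudes are the maximum dip (A_sup, reported as a magnitude) and maximum
peak (A_enh) of the normalized mean over (0, 400] ms.  The two extrema are
searched **independently**: on fixation-aligned responses the enhancement
peak precedes the smeared suppression of the next gaze shift, so
constraining the peak to follow the trough mis-measures it; an ordered
variant remains available (`find_extrema(..., ordered=True)`).  Latency is
the last negative→positive zero crossing before the peak, linearly
interpolated, and is defined only when the trough precedes the peak (the
shift-aligned case); the *last* crossing is robust to baseline ripple from
neighbouring events.  Significance uses z = amplitude / jackknife SE at the
extremum bin with |z| > 2, with no multiple-comparison correction.

A consequence worth stating plainly: because the extremum is selected over a
400-ms window (~24 effective independent bins after smoothing), the null
rate of |z| > 2 at the selected bin is far above the nominal 2.3% — most
unmodulated neurons acquire a "significant" extremum by selection alone.
The null study therefore treats the *population-average* flatness, not the
per-neuron flag rate, as the informative null statistic.  For the
population-average band we use the across-neuron SEM (the propagated
per-neuron jackknife SE omits the baseline-division common-mode noise: a
neuron's noisy baseline estimate shifts its whole normalized curve by a few
percent, which only the between-neuron scatter captures).  The band test
was calibrated on null simulations: at least 75% of bins within ±2 SEM and
no bin beyond 8 SEM, thresholds placed midway between the null regime
(≥ 0.82 within-band fraction, max |z| ≤ ~4.5 across calibration seeds) and
a strongly modulated regime (≤ 0.55, max |z| ≈ 24).

## Parametric response models

Both models superpose compact raised-cosine lobes
f(t) = a/2·(1+cos(2π(t−l)/w)) on the event sequence: suppression at every
gaze-shift onset, enhancement at shift onsets (saccade-locked) or fixation
onsets (two-stage).  Fixations at the session start without a preceding
shift still contribute their enhancement lobe.  The continuous response is
evaluated exactly (lobes placed at real-valued anchor times on a 1 ms grid),
which makes the degenerate identity exact: with every shift duration equal
to *d*, the two-stage model with enhancement latency *l* is
prediction-identical to the saccade-locked model with latency *l* + *d*.

Predicted event-aligned PSTHs are windowed averages of the continuous
response over full-window anchors, then passed through the **same** σ = 5 ms
smoothing and the same baseline renormalization ((1+p)/(1+b) − 1, with *b*
the predicted baseline-window mean) as the empirical PSTHs.  Matching the
two pipelines is essential: smoothing attenuates a 60 ms lobe peak by ~7%,
and flanking lobes from neighbouring events elevate or depress the baseline
window; applying both transforms to predictions and data alike makes the
amplitude comparison like-for-like and the amplitude fit unbiased.

Initialization fixes *l* at the extremum time, *a* at the signed extremum
value, and *w* at **twice** the measured full width at half amplitude — a
raised cosine reaches a/2 at l ± w/4, so w = 2·FWHM inverts the shape
exactly (initializing at the FWHM itself would halve the width and, through
the shared smoothing, inflate fitted amplitudes by tens of percent).  A
missing lobe initializes at a = 0 with a 50 ms default width and is flagged.
The two amplitudes are then fitted by SLSQP under a_sup ≤ 0 ≤ a_enh,
stopping at loss < 10⁻⁶ or 20 iterations; the loss is evaluated from
precomputed unit-amplitude component curves (the windowed-average and
smoothing steps are linear in the amplitudes), so each evaluation costs
microseconds.  If the optimizer ends above the starting loss the initial
iterate is kept.  Model comparison averages the four squared amplitude
deviations (both components × both alignments); error differences below a
relative 10⁻⁶ are declared ties.

## Receptive fields and drive

F_PREF and F_RF share one spectral helper — mean subtraction, a radially
symmetric raised-cosine (Hann) taper, FFT, log(1+|·|) — so the two spectra
live on an identical grid with identical conventions.  The log offset of 1
avoids −∞ at empty bins; mean subtraction zeroes the DC bin for crops and is
applied to condition images as well for consistency (both toggleable).  The
drive D is the plain elementwise-product mean, exactly as defined; a
cosine-similarity variant is deliberately *not* the default since the
normalization in "normalized dot product" is read as the 1/N factor that the
definition spells out.  Tertile thresholds use linear-interpolation
quantiles with strict inequalities, so boundary ties land in the middle
group; all-equal drives produce only middle labels and a warning.  The STA
lag is chosen over a 0–200 ms grid by peak map deviation, and the 5×5 deg
window is centered on the |map| peak, automating what is otherwise a manual
window placement (a manual center override exists).

## What the synthetic generator emulates

* **Gaze behavior.**  Alternating fixations (uniform 100–1000 ms) and gaze
  shifts whose above-threshold duration is uniform 20–200 ms with peak
  speeds 0.4–1.0 deg/ms.  Shifts follow a sin² speed pulse, so the labeled
  interval is exactly the span above threshold and detector ground truth is
  well-defined to one sample.  During fixations the head drifts as a
  smoothed Ornstein–Uhlenbeck process (σ = 1.5 deg, τ = 0.4 s) and the eye
  counter-rotates exactly (plus ~1 deg/s noise), reproducing the strong
  eye–head velocity anticorrelation of the vestibulo-ocular reflex.  Shifts
  are head-dominant (80% of the displacement) and directions bias back
  toward straight ahead beyond 30 deg eccentricity, keeping eye-in-head
  within a realistic range.  These are phenomenological choices — the
  generator makes no claim to match any species' movement statistics, and
  the amplitude/duration distributions are configurable.
* **Spiking.**  Inhomogeneous Poisson with rate
  baseline·max(0, 1 + Σf(t−anchor)), sampled per 1 ms bin at the bin-center
  rate; the none-model regime (no visual modulation, as in darkness) is
  homogeneous Poisson.  Default baselines: 10 Hz for model-recovery studies,
  15 Hz for drive studies (typical V1 rates).
* **Scenes.**  The arena wall is a periodic patchwork of 12-deg grating
  tiles (6 orientations × 3 spatial frequencies, random phases) viewed by a
  head-centered 40-deg camera at 0.15 deg/px — wide-FOV, as head-mounted
  scene cameras are, so RF crops rarely leave the frame; frames are rendered
  only within fixations (at most 4 per fixation) to keep long sessions
  light.  The enhancement gain of each fixation can be coupled to its RF
  drive through a rank-based monotone map onto [0.5, 1.5], creating the
  preferred/non-preferred contrast the conditioned-PSTH analysis must
  detect.

Passing on this generator demonstrates that the pipeline measures what it
claims when its assumptions hold.  It does not establish robustness to eye-
tracker calibration error, camera distortion, blinks, spike-sorting
contamination, bursty or history-dependent spiking, or non-stationary
baselines — none of which the generator produces.

## Study sizes

The validation studies use one shared 10-minute behavioral session per
population (≈900 gaze shifts), 50 neurons for recovery/model-selection, 20
for the null regime, and a 4-minute free-viewing session with 30 neurons for
the drive analysis; these sizes give each per-neuron statistic enough events
(≈100 per drive tertile) for stable amplitude estimates while keeping a full
validation run within a few minutes on one CPU.

## Known limitations

* The extremum-selected z > 2 rule has a high null flag rate by
  construction (see above); comparisons of flag *rates* between conditions
  are informative only when effect sizes are large.
* Amplitude recovery assumes the raised-cosine shape; heavily skewed
  response lobes would bias the FWHM-based width initialization.
* The drive score inherits the coarse spectral resolution of a 33×33 crop
  FFT; orientation contrast between D values is modest (the tertile split,
  not the absolute D difference, carries the analysis).
* Events are dropped whole at locomotion-mask boundaries; analyses near
  mask edges lose a fraction of events rather than gaining partial ones.
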