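# Methods

This note records the model, the numerical choices, and the reasoning
behind the synthetic benchmark — the things a maintainer would want to
know before changing a default.

## Signal model and pipeline

Both modalities are views of one cardiac source. The color path models
pulse-induced skin-color change as a fixed direction in RGB space (the
pulse blood-volume signature, default `(0.33, 0.77, 0.53)` normalized —
the widely used camera signature with green dominant, configurable). Per
ROI, channels are mean-centered and combined with the weight vector
`w = Q⁻¹p / (pᵀQ⁻¹p)` where `Q` is the 3x3 channel covariance and `p`
the signature: the least-squares combination with unit gain along `p`
that minimizes variance from distortions in other color directions
(common-mode illumination in particular). A singular or non-finite `Q`
solve falls back to direct projection onto `p`.

The motion path uses only the vertical coordinate of the 80 tracked
points — the cardiac recoil is vertical; the horizontal coordinates
serve only the re-detection rule. The 2-sigma mean-replacement is a
single pass with thresholds from pre-replacement statistics; it is
deliberately not iterated.

Stage order is: (color) normalize → PBV → band-pass → ICA → select;
(motion) normalize → band-pass → amplitude correction → SNR pruning →
PCA → select. Pruning after conditioning means channel quality is judged
on the signal the decomposition will actually see.

### Component selection

Every selection step uses the max-bin statistic
`SNR = max(PS) / (ΣPS − max(PS))` on the 0.75–2.5 Hz band-limited power
spectrum — band-limited everywhere so the statistic is comparable across
stages. Two refinements:

* **Windowed selection.** The selection SNR is the mean of the statistic
  over consecutive 30-s windows rather than one whole-recording value. A
  wandering heart rate smears the whole-recording spectrum of exactly
  the component that carries the pulse, to the point where narrowband
  noise out-scores it; within a half-minute window the pulse is
  near-tonal. On 120-s ramp recordings this changes fused tracking error
  from tens of bpm to fractions of a bpm. Signals shorter than one
  window fall back to the whole-signal statistic.
* **Deterministic ties.** Components whose SNRs differ by less than
  1e-9 (or are both infinite, e.g. two bin-exact tones) resolve to the
  lower dominant frequency.

### Fusion

Ensemble averaging is exactly `(RPPG + RBCG) / 2`. Both extraction
chains already return zero-mean unit-variance signals, so no further
standardization is applied at the fusion boundary — pixel and color
units never meet at incomparable scales. Blind-source outputs carry an
arbitrary sign, and an anti-phase pair would cancel its shared cardiac
component under averaging, so the pipeline flips the rBCG signal when it
anti-correlates with the rPPG signal before fusing.

A consequence of exact unit-variance inputs: 2-channel PCA fusion has
exactly equal channel variances, so its components are always the
45-degree sum/difference pair, making PCA fusion an ensemble average
with a second candidate (the difference) and SNR-based choice between
them. This matches its observed behavior (PCA ≈ EA).

### Spectral estimation

Spectra are rectangular-windowed (no taper), mean-centered, and
zero-padded to a power of two giving bin spacing ≤ 1/120 Hz (0.5 bpm),
so spectral quantization stays below reported accuracies. Dominant-peak
ties break toward the lower frequency. `HR = 60 × f_dominant`.

The band-pass is a design-order-2 Butterworth applied forward-backward
(zero phase, squared magnitude response). Pass-band identity holds near
the geometric band center; tones near the band edges see the filter
skirts, which is intentional — it is how out-of-band flicker leaks into
the analysis band in reality.

### Geometry

ROI fractions follow the fixed scheme in the README; the right cheek
mirrors the left to 65–80% of face width. Fractional pixel coordinates
round half-away-from-zero; rectangles are half-open. Grid layouts are
8x4 (forehead) and 8x6 (nose), row-major. The optical-flow engine is
pluggable; the default is a vectorized 3-level pyramidal Lucas–Kanade
(bilinear window sampling, batched 2x2 normal equations, up to 8 Newton
iterations per level, textureless windows flagged failed and carried
over). The tracker window is `round(max(face_w, face_h) / 10)` — the
larger dimension, conservatively, since "face size" does not name one.
Face detection is consulted only at frame 0 and after a re-detection
trigger (any point jumping > 10 px); between triggers the similarity
transform fitted to the tracked points carries the ROIs. Trajectories
stay rectangular across re-detections: row k continues as point k of
the new grid, with reset frames logged.

## Evaluation

Windowed estimates (default 30 s window, 1 s stride — at least 0.033 Hz
of native resolution before padding, compatible with 1–3-minute
recordings) are stamped at window ends and aligned to the reference by
nearest neighbor within 0.5 s. The reference for a time-varying rate is
the window-mean true HR over the same window, so a ramp is compared
like for like. SDAE is the sample standard deviation of the absolute
errors (literal reading of the name). Pearson correlation for a
constant series is reported as NaN rather than 0 — constant agreement
is undefined, not absent. Limits of agreement use the sample SD
(ddof = 1) of signed differences.

## The synthetic benchmark

The simulator emulates the raw material of both modalities under three
presets mirroring common study conditions — `normal` (stationary
subject, illum 0.2), `expressions` (expression artifacts on 40% of
points, 2 movements/min, sway 0.4 px), `hci` (illum 1.5, 6
movements/min, sway 1.0 px, expressions) — with one shared cardiac
waveform (fundamental + 0.3 second harmonic, phase-integrated so the
instantaneous frequency follows the configured HR trajectory).

Default amplitudes, chosen once for realism:

* `pulse_amp_rgb = 0.5` 8-bit units — typical AC amplitude of facial
  pulse color at webcam scale; slowly amplitude-modulated (±30%).
* `bcg_amp = 0.45` px — the ~0.5 mm head recoil at the nominal 140-px
  (~15 cm) face, i.e. ≈ 0.93 px/mm.
* `jitter_px = 0.3` — per-point tracking noise of a consumer webcam.
* `rgb_noise = 0.7` — 8-bit sensor noise per channel.

Noise families follow the opposite spectral characters of the two
modalities:

* **Illumination** is a flicker whose instantaneous frequency drifts
  (Ornstein–Uhlenbeck, ~10 s correlation) inside a high band (3–8 Hz)
  with excursions down to ~1.7 Hz — the slice that leaks into the
  cardiac band sits near its upper edge, which is why color estimates
  bias *high* — over a 1/f broadband floor (0.3 relative). It is
  dominated by a global source (screen/room light on the whole face,
  70%) with local per-ROI shading (30%), and each part splits into a
  common-mode component across R, G, B and a chromatic per-channel
  component (50% — screens are strongly non-neutral). Pure common-mode
  illumination would be exactly nulled by the PBV weighting and
  therefore harmless at any amplitude; the chromatic share is what
  makes illumination genuinely dangerous, as it is for real cameras.
* **Head motion** combines brief half-sine excursions (0.5–2 s, shared
  by all points) with sustained postural sway: 1/f-shaped noise
  band-limited to 0.2–1.0 Hz with a slowly waxing envelope. Its in-band
  tail sits at the *lower* edge of the cardiac band, which is why
  motion estimates bias *low*. Sway is rotational (nodding), so its
  amplitude grows linearly toward the top of the face (±30% around the
  mean) — a mixing direction distinct from the spatially uniform
  cardiac recoil, which is what lets PCA partially separate the two.
* **Expressions** add slow (0.3–1.2 Hz) band-limited noise to a random
  subset of trajectory channels (localized muscles), and a weaker,
  mostly achromatic shading term to the color traces (an ROI sliding
  over inhomogeneous skin changes brightness much more than chroma).

What the simulator does *not* model: photorealistic appearance, skin
segmentation issues, detector failures, rolling-shutter and compression
artifacts, physiological waveform variety beyond one harmonic, or
coupling between head motion and the color traces (tracked ROIs are
assumed to compensate motion perfectly on the color side). Passing tests
therefore demonstrate the pipeline's signal-processing behavior under
controlled, physically motivated noise — not clinical performance.

The rendered-clip generator draws a flat skin-colored face with a static
texture (so Lucas–Kanade has gradients), paints each ROI's interior with
its simulated color trace, and translates the face with sub-pixel
bilinear placement following the recoil + motion series; true face boxes
are emitted per frame, so the tracking stage can be exercised without
any detector.

Evaluation seeds also draw per-recording heart-rate trajectories
(baseline uniform in 60–90 bpm, piecewise-linear wander of ±3 bpm every
15 s) — resting heart rate is not constant, and a perfectly constant
rate would make windowed agreement trivially exact.

## Known limitations

* ICA fusion inherits the full error of a modality on recordings where
  that modality's extraction locked onto noise and the noise spectrum is
  sharper than the pulse's; the windowed selection SNR makes this rare
  but cannot eliminate it.
* The Lucas–Kanade tracker assumes brightness constancy; strong
  illumination flicker on a real face perturbs tracking, a coupling the
  simulator does not reproduce.
* MP4/AVI decoding requires an ffmpeg-backed reader; the library
  operates on in-memory frame arrays and leaves container decoding to
  the caller.
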