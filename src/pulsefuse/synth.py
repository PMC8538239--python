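"""Synthetic facial-pulse data with known ground truth.

Generates the raw material of both modalities — per-ROI RGB traces and
80-point head-motion trajectories — from a shared cardiac waveform at a
configured (possibly time-varying) heart rate, plus the two noise
families that plague real recordings:

* illumination variance for the color channel: a flicker-like component
  whose instantaneous frequency wanders inside a high-frequency band
  (light sources and screens vary faster than humans perceive), over a
  1/f broadband floor. Mostly common-mode across R, G, B, with a minority
  chromatic part, since real lighting is not spectrally neutral.
* motion artifacts for the trajectories: brief voluntary head movements
  (half-sine excursions shared by all points) and expression artifacts
  (slow band-limited noise on the subset of points over active muscles),
  both concentrated at low frequencies.

Three scenario presets mirror typical study conditions: ``normal``
(stationary subject), ``expressions`` (posed facial expressions), and
``hci`` (screen interaction with strong illumination changes and free
head movement). A minimal renderer turns the simulated traces into a
flat textured face clip for end-to-end exercise of the tracking stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sps

from .geometry import FaceBox, TrajectoryBank, compute_rois, make_point_grid
from .ppg import PbvVector, RgbTrace
from .signal_core import Signal1D

HR_MIN, HR_MAX = 45.0, 150.0

#: Relative amplitude of the second harmonic in the pulse template.
SECOND_HARMONIC = 0.3


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator.

    ``hr_bpm`` is either a constant rate or a piecewise-linear trajectory
    given as (time_s, bpm) breakpoints. Amplitudes are in 8-bit units for
    color and pixels for motion; see docs/methods.md for the rationale
    behind each default.
    """

    duration: float = 60.0  # s
    fps: float = 30.0
    hr_bpm: float | tuple[tuple[float, float], ...] = 72.0
    pulse_amp_rgb: float = 0.5  # 8-bit units, peak pulse color change
    pbv: PbvVector = field(default_factory=PbvVector)
    bcg_amp: float = 0.45  # px: ~0.5 mm recoil at a 140-px (~15 cm) face
    illum_amp: float = 0.2  # 8-bit units (std of the illumination term)
    illum_band: tuple[float, float] = (3.0, 8.0)  # Hz, flicker range
    motion_rate: float = 0.0  # voluntary movements per minute
    motion_amp: float = 10.0  # px
    expression_fraction: float = 0.0  # fraction of points with artifacts
    jitter_px: float = 0.3  # px, per-point tracking noise (std)
    seed: int = 0
    # secondary realism knobs
    rgb_noise: float = 0.7  # 8-bit units, per-channel sensor noise (std)
    pulse_amp_mod: float = 0.3  # fractional slow pulse-amplitude wander
    expression_amp: float = 1.0  # px, artifact amplitude on affected points
    expression_band: tuple[float, float] = (0.3, 1.2)  # Hz
    rgb_expression_amp: float = 0.6  # 8-bit units per unit expression_fraction
    expression_chroma: float = 0.15  # shading is mostly achromatic brightness
    illum_chroma: float = 0.5  # chromatic (per-channel) illumination share
    illum_local: float = 0.3  # per-ROI (local shading) illumination share
    illum_floor: float = 0.3  # relative amplitude of the 1/f floor
    sway_amp: float = 0.0  # px, sustained slow head-sway amplitude
    sway_band: tuple[float, float] = (0.2, 1.0)  # Hz, sway frequency range
    sway_tilt: float = 0.6  # fractional top-to-bottom sway-amplitude gradient
    baseline_rgb: tuple[float, float, float] = (140.0, 110.0, 90.0)

    def __post_init__(self) -> None:
        if self.duration < 20:
            raise ValueError("duration must be >= 20 s")
        if self.fps < 10:
            raise ValueError("fps must be >= 10")
        for name in ("pulse_amp_rgb", "bcg_amp", "illum_amp", "motion_amp",
                     "jitter_px", "rgb_noise", "expression_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.expression_fraction <= 1:
            raise ValueError("expression_fraction must be in [0, 1]")
        hr = self.hr_values(np.array([0.0, self.duration]))
        if np.any(hr < HR_MIN) or np.any(hr > HR_MAX):
            raise ValueError(f"hr_bpm must stay within {HR_MIN}-{HR_MAX} bpm")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    def hr_values(self, t: np.ndarray) -> np.ndarray:
        """Configured heart rate (bpm) at times ``t`` (piecewise linear)."""
        if np.isscalar(self.hr_bpm):
            return np.full_like(np.asarray(t, dtype=float), float(self.hr_bpm))
        bp = np.asarray(self.hr_bpm, dtype=float)
        if bp.ndim != 2 or bp.shape[1] != 2 or bp.shape[0] < 2:
            raise ValueError("hr_bpm trajectory needs >= 2 (time, bpm) pairs")
        out = np.interp(t, bp[:, 0], bp[:, 1])
        bad = np.any((out < HR_MIN) | (out > HR_MAX))
        if bad:
            raise ValueError(f"hr trajectory leaves {HR_MIN}-{HR_MAX} bpm")
        return out


@dataclass(frozen=True)
class GroundTruth:
    """The generating heart-rate trajectory, sampled for evaluation."""

    times: np.ndarray  # s
    bpm: np.ndarray

    def windowed(self, window_s: float, stride_s: float) -> tuple[np.ndarray, np.ndarray]:
        """Window-mean reference HR stamped at window ends.

        Matches the windowing of the estimators, so a time-varying rate is
        compared like for like.
        """
        t_end = self.times[-1]
        ends = np.arange(window_s, t_end + 1e-9, stride_s)
        bpm = np.array(
            [self.bpm[(self.times > e - window_s) & (self.times <= e)].mean()
             for e in ends]
        )
        return ends, bpm


def _times(cfg: SimConfig) -> np.ndarray:
    return np.arange(cfg.n_frames) / cfg.fps


def pulse_waveform(cfg: SimConfig) -> Signal1D:
    """Unit-amplitude cardiac waveform following the configured rate.

    A fundamental plus a 0.3-relative second harmonic; the instantaneous
    frequency tracks the HR trajectory through phase integration, so a
    ramping rate produces a smooth chirp rather than stitched tones.
    """
    t = _times(cfg)
    f_inst = cfg.hr_values(t) / 60.0
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fps
    w = np.sin(phase) + SECOND_HARMONIC * np.sin(2 * phase)
    return Signal1D(w / np.max(np.abs(w)), cfg.fps)


def _ground_truth(cfg: SimConfig, dt: float = 0.25) -> GroundTruth:
    t = np.arange(0.0, cfg.duration + 1e-9, dt)
    return GroundTruth(t, cfg.hr_values(t))


def _unit_std(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped broadband noise, zero mean, unit std."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    return _unit_std(x - x.mean())


def _slow_noise(rng: np.random.Generator, n: int, fs: float,
                cutoff_hz: float = 0.1) -> np.ndarray:
    """Low-pass-filtered noise (unit std): slow drifts and modulations."""
    sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return _unit_std(sps.sosfiltfilt(sos, rng.standard_normal(n)))


def _wandering_tone(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    reach_below: float = 0.0,
    reach_above: float = 0.0,
) -> np.ndarray:
    """A tone whose instantaneous frequency drifts slowly, unit std.

    The frequency follows an Ornstein-Uhlenbeck walk around a per-run
    anchor inside ``band``, clipped to ``[lo - reach_below, hi +
    reach_above]`` — excursions below a high-frequency band are the slice
    of real flicker that leaks into the cardiac analysis range. The
    amplitude wanders slowly as well.
    """
    lo, hi = band
    anchor = rng.uniform(lo, hi)
    tau_samples = 10.0 * fs  # ~10 s correlation time
    sd = (hi - lo) / 3.0
    theta = 1.0 / tau_samples
    f = np.empty(n)
    f[0] = anchor
    drive = rng.standard_normal(n) * sd * np.sqrt(2 * theta)
    for i in range(1, n):
        f[i] = f[i - 1] + theta * (anchor - f[i - 1]) + drive[i]
    f = np.clip(f, max(0.05, lo - reach_below), hi + reach_above)
    phase = 2 * np.pi * np.cumsum(f) / fs
    envelope = 1.0 + 0.5 * _slow_noise(rng, n, fs)
    return _unit_std(np.sin(phase) * np.clip(envelope, 0.1, None))


def _illumination(rng: np.random.Generator, n: int, fs: float,
                  cfg: SimConfig) -> np.ndarray:
    """One illumination realization (unit-std before scaling by illum_amp)."""
    hf = _wandering_tone(rng, n, fs, cfg.illum_band,
                         reach_below=1.3, reach_above=1.0)
    floor = _pink_noise(rng, n)
    return _unit_std(hf + cfg.illum_floor * floor)


def _amp_modulation(rng: np.random.Generator, n: int, fs: float,
                    depth: float) -> np.ndarray:
    if depth == 0:
        return np.ones(n)
    return np.clip(1.0 + depth * _slow_noise(rng, n, fs), 0.2, None)


PPG_ROI_NAMES = ("nose", "left_cheek", "right_cheek")


def _expression_shading(rng: np.random.Generator, n: int,
                        cfg: SimConfig) -> np.ndarray:
    """Slow shading artifact from expression-driven ROI displacement."""
    if cfg.expression_fraction == 0:
        return np.zeros(n)
    envelope = np.clip(1.0 + 0.7 * _slow_noise(rng, n, cfg.fps), 0.0, None)
    return _unit_std(
        _bandlimited(rng, n, cfg.fps, cfg.expression_band) * envelope
    )


def simulate_rgb(cfg: SimConfig) -> tuple[list[RgbTrace], GroundTruth]:
    """Per-ROI RGB traces carrying the pulse plus illumination noise.

    Each ROI shares the cardiac waveform (colored along the PBV direction,
    slowly amplitude-modulated). Illumination is dominated by a global
    source (room or screen light reflecting off the whole face) with a
    smaller per-ROI local-shading part (``illum_local``); each part
    splits into a common-mode component across R, G, B and a chromatic
    (per-channel) component (``illum_chroma``) — real light sources,
    especially screens, are not spectrally neutral. Facial expressions
    disturb the color traces as well: muscle movement slides each ROI
    over inhomogeneous skin, adding slow shading artifacts per ROI in
    proportion to ``expression_fraction``. White sensor noise is added
    per channel and the result is clipped to the 8-bit range.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    pulse = pulse_waveform(cfg).samples
    mod = _amp_modulation(rng, n, cfg.fps, cfg.pulse_amp_mod)
    pulse_term = cfg.pulse_amp_rgb * mod * pulse

    a_local = cfg.illum_local
    a_chroma = cfg.illum_chroma
    global_common = _illumination(rng, n, cfg.fps, cfg)
    global_chroma = [_illumination(rng, n, cfg.fps, cfg) for _ in range(3)]
    shade_amp = cfg.rgb_expression_amp * cfg.expression_fraction
    traces = []
    for roi in PPG_ROI_NAMES:
        local_common = _illumination(rng, n, cfg.fps, cfg)
        shade_common = _expression_shading(rng, n, cfg)
        channels = np.empty((3, n))
        for c in range(3):
            local_chroma = _illumination(rng, n, cfg.fps, cfg)
            glob = (1 - a_chroma) * global_common + a_chroma * global_chroma[c]
            local = (1 - a_chroma) * local_common + a_chroma * local_chroma
            illum = cfg.illum_amp * ((1 - a_local) * glob + a_local * local)
            shade = shade_amp * (
                (1 - cfg.expression_chroma) * shade_common
                + cfg.expression_chroma * _expression_shading(rng, n, cfg)
            )
            channels[c] = (
                cfg.baseline_rgb[c]
                + cfg.pbv.weights[c] * pulse_term
                + illum
                + shade
                + cfg.rgb_noise * rng.standard_normal(n)
            )
        channels = np.clip(channels, 0.0, 255.0)
        traces.append(RgbTrace(roi, *channels, fps=cfg.fps))
    return traces, _ground_truth(cfg)


#: Nominal face geometry used to seed synthetic trajectories and clips.
NOMINAL_FACE = FaceBox(90, 50, 140, 140)


def _motion_events(rng: np.random.Generator, n: int, fs: float,
                   rate_per_min: float, amp: float) -> np.ndarray:
    """Sum of half-sine voluntary-movement excursions, shared by all points."""
    out = np.zeros(n)
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    for _ in range(n_events):
        dur = rng.uniform(0.5, 2.0)
        onset = rng.uniform(0.0, max(1e-6, n / fs - dur))
        i0 = int(onset * fs)
        length = max(2, int(dur * fs))
        i1 = min(n, i0 + length)
        bump = np.sin(np.linspace(0, np.pi, i1 - i0))
        out[i0:i1] += rng.choice([-1.0, 1.0]) * amp * rng.uniform(0.5, 1.0) * bump
    return out


def _sway(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Sustained slow head sway: 1/f-weighted noise with a slow envelope.

    Seated subjects drift and rock intermittently rather than oscillating
    coherently: postural sway has a red (roughly 1/f^2) spectrum, so the
    band-limited noise is additionally 1/f-shaped inside ``sway_band``
    and waxes and wanes over tens of seconds.
    """
    if cfg.sway_amp == 0:
        return np.zeros(n)
    sos = sps.butter(2, cfg.sway_band, btype="bandpass", fs=cfg.fps,
                     output="sos")
    red = sps.sosfiltfilt(sos, _pink_noise(rng, n))
    envelope = np.clip(1.0 + 0.7 * _slow_noise(rng, n, cfg.fps), 0.0, None)
    return cfg.sway_amp * _unit_std(_unit_std(red) * envelope)


def _head_motion(rng: np.random.Generator, n: int, cfg: SimConfig,
                 horizontal: bool = False) -> np.ndarray:
    """Voluntary head motion: brief excursions plus sustained slow sway.

    Both components are common-mode across all tracked points (the whole
    head moves); the horizontal variant is attenuated since nodding and
    vertical shifts dominate seated motion.
    """
    atten = 0.5 if horizontal else 1.0
    out = _motion_events(rng, n, cfg.fps, cfg.motion_rate,
                         atten * cfg.motion_amp)
    return out + atten * _sway(rng, n, cfg)


def _bandlimited(rng: np.random.Generator, n: int, fs: float,
                 band: tuple[float, float]) -> np.ndarray:
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return _unit_std(sps.sosfiltfilt(sos, rng.standard_normal(n)))


def simulate_trajectories(cfg: SimConfig) -> tuple[TrajectoryBank, GroundTruth]:
    """Tracked-point trajectories with cardiac recoil and motion noise.

    Each of the 80 grid points oscillates vertically with the shared pulse
    (``bcg_amp`` px), on top of independent tracking jitter, common-mode
    voluntary-movement bumps, sustained slow head sway, and expression
    artifacts on a random ``expression_fraction`` subset of points.
    The sway is rotational (nodding about the neck), so its amplitude
    grows linearly from the bottom to the top of the face
    (``sway_tilt``), unlike the spatially uniform cardiac recoil.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_frames
    pulse = pulse_waveform(cfg).samples
    mod = _amp_modulation(rng, n, cfg.fps, cfg.pulse_amp_mod)
    rois = {r.name: r for r in compute_rois(NOMINAL_FACE)}
    grid = make_point_grid(rois["forehead"], rois["nose"])

    bumps_y = _motion_events(rng, n, cfg.fps, cfg.motion_rate, cfg.motion_amp)
    bumps_x = _motion_events(rng, n, cfg.fps, cfg.motion_rate,
                             0.5 * cfg.motion_amp)
    sway = _sway(rng, n, cfg)

    y0 = grid.points[:, 1]
    span = np.ptp(y0) or 1.0
    # nodding pivot is below the face: points higher up sway more
    sway_gain = 1.0 + cfg.sway_tilt * ((y0.mean() - y0) / span)

    n_expr = int(round(cfg.expression_fraction * 80))
    expr_idx = rng.choice(80, size=n_expr, replace=False)

    ys = np.empty((80, n))
    xs = np.empty((80, n))
    bcg = cfg.bcg_amp * mod * pulse
    for k in range(80):
        jitter_y = cfg.jitter_px * rng.standard_normal(n)
        jitter_x = cfg.jitter_px * rng.standard_normal(n)
        ys[k] = grid.points[k, 1] + bcg + bumps_y + sway_gain[k] * sway + jitter_y
        xs[k] = grid.points[k, 0] + bumps_x + 0.5 * sway_gain[k] * sway + jitter_x
    for k in expr_idx:
        ys[k] += cfg.expression_amp * _bandlimited(
            rng, n, cfg.fps, cfg.expression_band
        )

    bank = TrajectoryBank(xs, ys, cfg.fps, region=grid.region)
    return bank, _ground_truth(cfg)


def random_hr_trajectory(
    seed: int,
    duration: float,
    base_range: tuple[float, float] = (60.0, 90.0),
    wander_bpm: float = 3.0,
    step_s: float = 15.0,
) -> tuple[tuple[float, float], ...]:
    """A realistic slowly wandering heart-rate trajectory.

    Resting heart rate is not constant: vagal tone and respiration move
    it by a few bpm over tens of seconds. This draws a per-seed baseline
    in ``base_range`` and piecewise-linear excursions of up to
    ``wander_bpm`` around it, one breakpoint every ``step_s`` seconds —
    suitable as the ``hr_bpm`` field of :class:`SimConfig`.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(*base_range)
    t = np.arange(0.0, duration + step_s, step_s)
    bpm = np.clip(base + rng.uniform(-wander_bpm, wander_bpm, size=t.size),
                  HR_MIN, HR_MAX)
    return tuple(zip(t.tolist(), bpm.tolist()))


def scenario(name: str) -> SimConfig:
    """Preset configurations for the three study conditions."""
    presets = {
        "normal": dict(illum_amp=0.2, motion_rate=0.0, expression_fraction=0.0,
                       sway_amp=0.0),
        "expressions": dict(illum_amp=0.2, motion_rate=2.0,
                            expression_fraction=0.4, sway_amp=0.4),
        "hci": dict(illum_amp=1.5, motion_rate=6.0, expression_fraction=0.4,
                    sway_amp=1.0),
    }
    if name not in presets:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(presets)}"
        )
    return SimConfig(**presets[name])


@dataclass
class RenderedClip:
    """A rendered synthetic clip plus everything that generated it."""

    frames: np.ndarray  # (n_frames, h, w, 3) uint8
    face_boxes: dict[int, FaceBox]
    traces: list[RgbTrace]  # the driving per-ROI color traces
    ground_truth: GroundTruth
    fps: float


def render_clip(
    cfg: SimConfig,
    frame_shape: tuple[int, int] = (240, 320),
    face: FaceBox = NOMINAL_FACE,
    motion_jump_px: float | None = None,
    jump_frame: int | None = None,
) -> RenderedClip:
    """Render a flat textured face whose ROI colors follow the simulation.

    The face is a skin-colored rectangle with a static texture (so the
    point tracker has gradients to lock onto); each pulse ROI's interior
    additionally follows its simulated color trace. The whole face
    translates with the cardiac recoil and voluntary-motion series, with
    sub-pixel bilinear placement; true face boxes are emitted per frame.
    ``motion_jump_px``/``jump_frame`` inject a step displacement to
    exercise the re-detection rule.
    """
    h, w = frame_shape
    rng = np.random.default_rng(cfg.seed + 2)
    traces, gt = simulate_rgb(cfg)
    n = cfg.n_frames
    pulse = pulse_waveform(cfg).samples
    dy = cfg.bcg_amp * pulse + _head_motion(rng, n, cfg)
    dx = _head_motion(rng, n, cfg, horizontal=True)
    if motion_jump_px is not None and jump_frame is not None:
        dy[jump_frame:] += motion_jump_px

    fw, fh = int(face.w), int(face.h)
    base = np.empty((fh, fw, 3))
    for c in range(3):
        base[..., c] = cfg.baseline_rgb[c]
    texture = ndimage.gaussian_filter(
        rng.standard_normal((fh, fw, 1)) * 12.0, sigma=(1.0, 1.0, 0)
    )
    base = base + texture

    rois = {r.name: r for r in compute_rois(FaceBox(0, 0, face.w, face.h))}
    masks = {}
    for name in PPG_ROI_NAMES:
        r = rois[name]
        m = np.zeros((fh, fw, 1), dtype=bool)
        m[r.y0:r.y1, r.x0:r.x1] = True
        masks[name] = m

    background = 60.0
    x0, y0 = int(face.x), int(face.y)
    # shift only a padded box around the face, not the whole canvas
    pad = int(np.ceil(max(np.abs(dy).max(), np.abs(dx).max()))) + 2
    py0, py1 = max(0, y0 - pad), min(h, y0 + fh + pad)
    px0, px1 = max(0, x0 - pad), min(w, x0 + fw + pad)
    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    boxes: dict[int, FaceBox] = {}
    trace_ch = {t.roi: t.channels() for t in traces}
    baseline = np.array(cfg.baseline_rgb)
    for i in range(n):
        patch = base.copy()
        for name in PPG_ROI_NAMES:
            delta = trace_ch[name][:, i] - baseline
            patch += masks[name] * delta[None, None, :]
        box = np.full((py1 - py0, px1 - px0, 3), background)
        box[y0 - py0 : y0 - py0 + fh, x0 - px0 : x0 - px0 + fw] = patch
        shifted = ndimage.shift(box, (dy[i], dx[i], 0), order=1, mode="nearest")
        canvas = np.full((h, w, 3), background)
        canvas[py0:py1, px0:px1] = shifted
        frames[i] = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
        boxes[i] = FaceBox(face.x + dx[i], face.y + dy[i], face.w, face.h, i)
    return RenderedClip(frames, boxes, traces, gt, cfg.fps)
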