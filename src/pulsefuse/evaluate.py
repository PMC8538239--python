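"""Windowed heart-rate series, agreement statistics, and orchestration.

A recording's pulse signal is turned into a time-resolved HR series by
sliding a spectral-estimation window (default 30 s, 1 s stride) and
taking the dominant in-band frequency of each window. Estimated series
are compared to a reference series with the standard agreement metrics:
MAE, the standard deviation of absolute error (SDAE), RMSE, Pearson
correlation, and Bland-Altman bias with 95% limits of agreement
(bias +- 1.96 x SD of the differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import bcg, geometry, ppg
from .fusion import FusionMethod, align_sign, fuse
from .signal_core import DEFAULT_BAND, Signal1D, dominant_hr
from .synth import GroundTruth

log = logging.getLogger(__name__)

#: Maximum timestamp gap for pairing estimated with reference samples, s.
ALIGN_TOLERANCE_S = 0.5


@dataclass(frozen=True)
class HrSeries:
    """A time-resolved heart-rate estimate with its method label."""

    times: np.ndarray  # s, strictly increasing
    bpm: np.ndarray
    method: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        b = np.asarray(self.bpm, dtype=np.float64)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "bpm", b)
        if t.shape != b.shape or t.ndim != 1:
            raise ValueError("times and bpm must be matching 1-D arrays")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between an estimated and a reference HR series."""

    mae: float
    sdae: float
    rmse: float
    cc: float  # NaN when either series has zero variance
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def windowed_hr(
    signal: Signal1D,
    window_s: float = 30.0,
    stride_s: float = 1.0,
    method: str = "",
    band: tuple[float, float] = DEFAULT_BAND,
) -> HrSeries:
    """Dominant-frequency HR over a sliding window, stamped at window ends."""
    win = int(round(window_s * signal.fs))
    stride = max(1, int(round(stride_s * signal.fs)))
    n = len(signal)
    if win > n:
        log.warning("signal shorter than window; single whole-signal estimate")
        est = dominant_hr(signal, band)
        return HrSeries(np.array([signal.duration]), np.array([est.bpm]), method)
    starts = range(0, n - win + 1, stride)
    times, bpms = [], []
    for s0 in starts:
        seg = Signal1D(signal.samples[s0 : s0 + win], signal.fs)
        times.append((s0 + win) / signal.fs)
        bpms.append(dominant_hr(seg, band).bpm)
    return HrSeries(np.array(times), np.array(bpms), method)


def _align(est: HrSeries, ref: HrSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pair each estimate with the nearest reference sample within 0.5 s."""
    idx = np.searchsorted(ref.times, est.times)
    idx = np.clip(idx, 1, len(ref.times) - 1) if len(ref.times) > 1 else idx * 0
    left = np.clip(idx - 1, 0, len(ref.times) - 1)
    choose_left = (np.abs(ref.times[left] - est.times)
                   <= np.abs(ref.times[np.clip(idx, 0, len(ref.times) - 1)]
                             - est.times))
    nearest = np.where(choose_left, left, np.clip(idx, 0, len(ref.times) - 1))
    gap = np.abs(ref.times[nearest] - est.times)
    ok = gap <= ALIGN_TOLERANCE_S
    dropped = int((~ok).sum())
    if dropped:
        log.info("dropped %d estimate(s) without a reference within %.1f s",
                 dropped, ALIGN_TOLERANCE_S)
    return est.bpm[ok], ref.bpm[nearest[ok]]


def agreement(est: HrSeries, ref: HrSeries) -> AgreementStats:
    """Agreement metrics between aligned estimated and reference series.

    SDAE is the sample standard deviation of the absolute errors; limits
    of agreement are ``bias +- 1.96 x SD`` of the signed differences.
    Pearson correlation is NaN if either matched series is constant.
    """
    e, r = _align(est, ref)
    if e.size < 2:
        raise ValueError("need at least 2 matched pairs for agreement stats")
    d = e - r
    abs_d = np.abs(d)
    sd_d = d.std(ddof=1)
    if e.std() == 0 or r.std() == 0:
        cc = np.nan
    else:
        cc = float(np.corrcoef(e, r)[0, 1])
    bias = float(d.mean())
    return AgreementStats(
        mae=float(abs_d.mean()),
        sdae=float(abs_d.std(ddof=1)),
        rmse=float(np.sqrt((d**2).mean())),
        cc=cc,
        bias=bias,
        loa_low=bias - 1.96 * sd_d,
        loa_high=bias + 1.96 * sd_d,
        n=int(e.size),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the end-to-end pipeline."""

    band: tuple[float, float] = DEFAULT_BAND
    window_s: float = 30.0
    stride_s: float = 1.0
    pbv: ppg.PbvVector = field(default_factory=ppg.PbvVector)
    ica_seed: int = 0


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    hr: dict[str, HrSeries]  # keys: RPPG, RBCG and the fused method label
    fused: Signal1D
    rppg: Signal1D
    rbcg: Signal1D
    method: str


def run_traces(
    traces: Sequence[ppg.RgbTrace],
    trajectories: geometry.TrajectoryBank,
    method: FusionMethod | str = FusionMethod.EA,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the pipeline from pre-extracted traces and trajectories."""
    cfg = config or PipelineConfig()
    method = FusionMethod(method.lower() if isinstance(method, str) else method)
    rppg = ppg.rppg_from_traces(list(traces), pbv=cfg.pbv, band=cfg.band,
                                seed=cfg.ica_seed)
    rbcg = bcg.rbcg_from_trajectories(trajectories, band=cfg.band)
    rbcg = align_sign(rppg, rbcg)  # BSS sign ambiguity would cancel under EA
    fused = fuse(rppg, rbcg, method, band=cfg.band, seed=cfg.ica_seed)
    label = method.name
    hr = {
        "RPPG": windowed_hr(rppg, cfg.window_s, cfg.stride_s, "RPPG", cfg.band),
        "RBCG": windowed_hr(rbcg, cfg.window_s, cfg.stride_s, "RBCG", cfg.band),
        label: windowed_hr(fused, cfg.window_s, cfg.stride_s, label, cfg.band),
    }
    return PipelineResult(hr, fused, rppg, rbcg, label)


def run_video(
    frames: Sequence[np.ndarray],
    face_boxes,
    fps: float,
    method: FusionMethod | str = FusionMethod.EA,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline from raw frames plus face detections.

    ``face_boxes`` is a mapping frame_index -> FaceBox (e.g. from a CSV
    sidecar) or a callable detector; it is consulted on frame 0 and after
    re-detection triggers only.
    """
    if not len(frames):
        raise ValueError("empty frame sequence")
    tracking = geometry.track_video(frames, face_boxes, fps)
    traces = ppg.extract_rgb_traces(frames, tracking.rois_per_frame, fps)
    return run_traces(traces, tracking.trajectories, method, config)


def reference_series(gt: GroundTruth, window_s: float = 30.0,
                     stride_s: float = 1.0) -> HrSeries:
    """Ground truth windowed like the estimators, for apples-to-apples MAE."""
    t, bpm = gt.windowed(window_s, stride_s)
    return HrSeries(t, bpm, "REF")
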