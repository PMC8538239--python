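"""Remote photoplethysmography: pulse extraction from ROI color traces.

Blood-volume changes in superficial skin vessels modulate the light
reflected by the face. Per ROI (nose and both cheeks), the per-frame
spatial mean of each RGB channel is taken, the channel means (the static
melanin/skin-tone component) are subtracted, and the three channels are
combined along the pulse blood-volume (PBV) direction — the
characteristic signature of pulse-induced color change in RGB space —
which suppresses distortions lying in other color directions (notably
common-mode illumination). The three per-ROI pulse candidates are
band-passed to 0.75–2.5 Hz, unmixed by ICA, and the component with the
highest max-bin SNR is the rPPG signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .geometry import RoiRect
from .signal_core import (
    DEFAULT_BAND,
    Signal1D,
    bandpass,
    best_by_snr,
)

log = logging.getLogger(__name__)

PPG_ROIS = ("nose", "left_cheek", "right_cheek")


@dataclass(frozen=True)
class RgbTrace:
    """Per-frame spatial-mean RGB values of one ROI (8-bit scale)."""

    roi: str
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64)
            )
        if not (len(self.r) == len(self.g) == len(self.b)):
            raise ValueError("channel traces must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("r", "g", "b"):
            ch = getattr(self, name)
            if np.any(ch < 0) or np.any(ch > 255):
                raise ValueError(f"{name} channel outside the 8-bit range")

    def __len__(self) -> int:
        return len(self.r)

    def channels(self) -> np.ndarray:
        """Channels stacked as a (3, n_frames) matrix (R, G, B rows)."""
        return np.stack([self.r, self.g, self.b])


@dataclass(frozen=True, eq=False)
class PbvVector:
    """Unit direction of pulse-induced color change in RGB space.

    The default (0.33, 0.77, 0.53), normalized, is the widely used
    skin-reflection pulse signature for RGB cameras — green dominates
    because hemoglobin absorption peaks in the green band.
    """

    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = self.weights
        if w is None:
            w = np.array([0.33, 0.77, 0.53])
        w = np.asarray(w, dtype=np.float64)
        if w.shape != (3,):
            raise ValueError("PBV vector must have 3 components")
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("PBV vector must be non-zero")
        object.__setattr__(self, "weights", w / norm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PbvVector):
            return NotImplemented
        return bool(np.array_equal(self.weights, other.weights))

    def __hash__(self) -> int:
        return hash(tuple(self.weights))


def extract_rgb_traces(
    frames, rois_per_frame: list[dict[str, RoiRect]], fps: float
) -> list[RgbTrace]:
    """Spatially average each RGB channel over each pulse ROI, per frame.

    ROIs falling partly outside the frame are clipped (with a warning);
    an empty intersection is an error.
    """
    traces: dict[str, list[list[float]]] = {roi: [[], [], []] for roi in PPG_ROIS}
    clipped = False
    for frame, rois in zip(frames, rois_per_frame):
        img = np.asarray(frame, dtype=np.float64)
        h, w = img.shape[:2]
        for name in PPG_ROIS:
            rect = rois[name]
            x0, x1 = max(0, rect.x0), min(w, rect.x1)
            y0, y1 = max(0, rect.y0), min(h, rect.y1)
            if (x0, x1, y0, y1) != (rect.x0, rect.x1, rect.y0, rect.y1):
                clipped = True
            if x1 <= x0 or y1 <= y0:
                raise ValueError(f"ROI {name} lies fully outside the frame")
            patch = img[y0:y1, x0:x1]
            for c in range(3):
                traces[name][c].append(float(patch[..., c].mean()))
    if clipped:
        log.warning("some ROIs extended beyond the frame and were clipped")
    return [
        RgbTrace(name, *(np.array(ch) for ch in traces[name]), fps=fps)
        for name in PPG_ROIS
    ]


def pbv_project(trace: RgbTrace, pbv: PbvVector | None = None) -> Signal1D:
    """Combine the RGB channels of one ROI along the PBV direction.

    Channels are mean-centered (melanin removal), then weighted by
    ``w = Q^-1 p / (p^T Q^-1 p)`` where ``Q`` is the 3x3 channel
    covariance and ``p`` the PBV signature. This is the least-squares
    combination whose output has unit alignment with the PBV direction,
    cancelling distortions along other color directions. A singular
    covariance falls back to direct projection onto the signature.
    """
    if len(trace) < 64:
        raise ValueError("trace too short (need >= 64 frames)")
    pbv = pbv or PbvVector()
    c = trace.channels()
    c = c - c.mean(axis=1, keepdims=True)
    q = (c @ c.T) / c.shape[1]
    p = pbv.weights
    try:
        w = np.linalg.solve(q, p)
        w = w / (p @ w)
    except np.linalg.LinAlgError:
        log.warning("singular channel covariance; projecting directly onto PBV")
        w = p
    if not np.all(np.isfinite(w)):
        log.warning("ill-conditioned channel covariance; projecting onto PBV")
        w = p
    return Signal1D(w @ c, trace.fps)


def ppg_signal(
    roi_signals: list[Signal1D],
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
) -> Signal1D:
    """Unmix the per-ROI pulse candidates and keep the cleanest component.

    FastICA with 3 components (whitened, deterministic seed) separates
    the shared cardiac source from ROI-specific distortions; the component
    with maximal max-bin SNR is returned at unit variance. If ICA fails to
    converge the selection falls back to PCA components.
    """
    if len(roi_signals) != 3:
        raise ValueError("expected exactly 3 per-ROI signals")
    fs = roi_signals[0].fs
    n = len(roi_signals[0])
    if any(s.fs != fs or len(s) != n for s in roi_signals):
        raise ValueError("per-ROI signals must share fs and length")
    x = np.stack([s.samples for s in roi_signals], axis=1)
    sources = decompose(x, n_components=3, seed=seed)
    return best_by_snr(sources.T, fs, band)


def decompose(x: np.ndarray, n_components: int, seed: int = 0) -> np.ndarray:
    """ICA source estimates for column-channel data, PCA on non-convergence.

    Returns an (n_samples, n_components) source matrix. Degenerate inputs
    (effective rank below ``n_components``) also route to PCA, which is
    well-defined at reduced rank.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica = FastICA(
                n_components=n_components,
                whiten="unit-variance",
                max_iter=500,
                random_state=seed,
            )
            return ica.fit_transform(x)
        except (ConvergenceWarning, ValueError) as exc:
            log.warning("ICA failed (%s); falling back to PCA components", exc)
    pca = PCA(n_components=min(n_components, min(x.shape)))
    return pca.fit_transform(x)


def rppg_from_traces(
    traces: list[RgbTrace],
    pbv: PbvVector | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int = 0,
) -> Signal1D:
    """Full rPPG chain: normalize -> PBV -> band-pass -> ICA -> SNR select."""
    by_roi = {t.roi: t for t in traces}
    missing = [r for r in PPG_ROIS if r not in by_roi]
    if missing:
        raise ValueError(f"missing ROI traces: {missing}")
    filtered = [
        bandpass(pbv_project(by_roi[r], pbv), *band) for r in PPG_ROIS
    ]
    return ppg_signal(filtered, band=band, seed=seed)
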