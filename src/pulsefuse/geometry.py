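"""Face-relative ROI geometry and sparse point tracking.

The face rectangle supplied by any detector is carved into four
sub-regions: the forehead (middle 50% of the width, top 20% of the
height), the nose (middle 50% of the width, vertically centered 25% of
the height), and the two cheeks (20–35% of the width, 45–70% of the
height, mirrored on the right). A fixed grid of 80 points — 32 on the
forehead (8x4 cells) and 48 on the nose (8x6 cells) — is placed at cell
centers and tracked frame to frame with a pyramidal Lucas-Kanade flow
engine. If any point jumps more than 10 px the grid is re-seeded from a
fresh detection; otherwise a least-squares similarity transform fitted
to the tracked points carries the ROIs forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import SimilarityTransform as _SkSimilarity

log = logging.getLogger(__name__)

#: Re-detection threshold, px: a point jumping farther than this re-seeds the grid.
REDETECT_PX = 10.0

#: Minimum usable face size, px.
MIN_FACE_PX = 20

ROI_NAMES = ("forehead", "nose", "left_cheek", "right_cheek")

# (x0, x1, y0, y1) as fractions of face width/height.
_ROI_FRACTIONS = {
    "forehead": (0.25, 0.75, 0.00, 0.20),
    "nose": (0.25, 0.75, 0.375, 0.625),
    "left_cheek": (0.20, 0.35, 0.45, 0.70),
    "right_cheek": (0.65, 0.80, 0.45, 0.70),
}

# Grid layout (cols, rows) per region; 8x4 + 8x6 = 32 + 48 = 80 points.
GRID_LAYOUT = {"forehead": (8, 4), "nose": (8, 6)}


def _round_half_away(v: float) -> int:
    return int(np.sign(v) * np.floor(np.abs(v) + 0.5))


@dataclass(frozen=True)
class FaceBox:
    """An axis-aligned face rectangle on one frame."""

    x: float
    y: float
    w: float
    h: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("face box must have positive size")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass(frozen=True)
class RoiRect:
    """A half-open pixel rectangle [x0, x1) x [y0, y1) with a region label."""

    name: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate rect {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def corners(self) -> np.ndarray:
        return np.array(
            [
                [self.x0, self.y0],
                [self.x1, self.y0],
                [self.x1, self.y1],
                [self.x0, self.y1],
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class PointGrid:
    """The 80 tracked facial points with their region labels."""

    points: np.ndarray  # (80, 2) float, (x, y)
    region: tuple[str, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "region", tuple(self.region))
        if pts.shape != (80, 2):
            raise ValueError("point grid must hold exactly 80 (x, y) points")
        counts = {r: self.region.count(r) for r in set(self.region)}
        if counts != {"forehead": 32, "nose": 48}:
            raise ValueError(f"expected 32 forehead + 48 nose points, got {counts}")


@dataclass(frozen=True)
class SimilarityTransform:
    """Translation + rotation + isotropic scale (4 degrees of freedom)."""

    scale: float
    rotation: float
    tx: float
    ty: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array(
            [
                [self.scale * c, -self.scale * s, self.tx],
                [self.scale * s, self.scale * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        m = self.matrix()
        return pts @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        inv_scale = 1.0 / self.scale
        tx = -inv_scale * (c * self.tx - s * self.ty)
        ty = -inv_scale * (s * self.tx + c * self.ty)
        return SimilarityTransform(inv_scale, -self.rotation, tx, ty)


@dataclass
class TrajectoryBank:
    """Per-point pixel trajectories over a recording.

    Rows are points (80 when produced by the tracker), columns frames.
    Re-detections reset point positions in place — row k always follows
    point k of the current grid — and are logged in ``reset_frames``.
    """

    xs: np.ndarray  # (n_points, n_frames)
    ys: np.ndarray
    fps: float
    region: tuple[str, ...] = ()
    reset_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=np.float64)
        self.ys = np.asarray(self.ys, dtype=np.float64)
        if self.xs.shape != self.ys.shape or self.xs.ndim != 2:
            raise ValueError("xs and ys must be matching 2-D matrices")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (np.all(np.isfinite(self.xs)) and np.all(np.isfinite(self.ys))):
            raise ValueError("trajectories must be finite")

    @property
    def n_points(self) -> int:
        return self.xs.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xs.shape[1]


def compute_rois(face: FaceBox) -> list[RoiRect]:
    """Carve the four analysis sub-regions out of a face box.

    Fractional coordinates are rounded half-away-from-zero to integer
    pixels; rectangles are half-open.
    """
    if face.w < MIN_FACE_PX or face.h < MIN_FACE_PX:
        raise ValueError(f"face box too small to analyse ({face.w}x{face.h} px)")
    rois = []
    for name in ROI_NAMES:
        fx0, fx1, fy0, fy1 = _ROI_FRACTIONS[name]
        rois.append(
            RoiRect(
                name,
                _round_half_away(face.x + fx0 * face.w),
                _round_half_away(face.y + fy0 * face.h),
                _round_half_away(face.x + fx1 * face.w),
                _round_half_away(face.y + fy1 * face.h),
            )
        )
    return rois


def make_point_grid(forehead: RoiRect, nose: RoiRect) -> PointGrid:
    """Place 80 points at the centers of an 8x4 forehead / 8x6 nose lattice."""
    points: list[tuple[float, float]] = []
    region: list[str] = []
    for rect in (forehead, nose):
        cols, rows = GRID_LAYOUT[rect.name]
        cell_w = rect.width / cols
        cell_h = rect.height / rows
        if cell_w < 2 or cell_h < 2:
            raise ValueError(
                f"{rect.name} rect too small for a {cols}x{rows} grid"
            )
        for i in range(rows):  # row-major ordering
            for j in range(cols):
                points.append(
                    (rect.x0 + (j + 0.5) * cell_w, rect.y0 + (i + 0.5) * cell_h)
                )
                region.append(rect.name)
    return PointGrid(np.array(points), tuple(region))


def estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Delegates to the Umeyama solver; requires at least 2 non-coincident
    correspondences.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise ValueError("need >= 2 matching (x, y) correspondences")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValueError("coincident points: similarity transform is degenerate")
    if hasattr(_SkSimilarity, "from_estimate"):
        tf = _SkSimilarity.from_estimate(src, dst)
        if not tf:
            raise ValueError("similarity estimation failed (rank-deficient input)")
    else:  # scikit-image < 0.26
        tf = _SkSimilarity()
        if not tf.estimate(src, dst):
            raise ValueError("similarity estimation failed (rank-deficient input)")
    if not np.all(np.isfinite(tf.params)):
        raise ValueError("similarity estimation failed (non-finite parameters)")
    return SimilarityTransform(
        scale=float(tf.scale),
        rotation=float(tf.rotation),
        tx=float(tf.translation[0]),
        ty=float(tf.translation[1]),
    )


def apply_transform(t: SimilarityTransform, rect: RoiRect) -> RoiRect:
    """Map a rect through a similarity transform, re-axis-aligning it.

    The result is the integer bounding box of the four mapped corners.
    """
    mapped = t.apply(rect.corners())
    x0, y0 = mapped.min(axis=0)
    x1, y1 = mapped.max(axis=0)
    return RoiRect(
        rect.name,
        _round_half_away(x0),
        _round_half_away(y0),
        _round_half_away(x1),
        _round_half_away(y1),
    )


# ---------------------------------------------------------------------------
# Sparse pyramidal Lucas-Kanade optical flow
# ---------------------------------------------------------------------------

#: Signature of a flow engine: (prev_gray, next_gray, points, window) ->
#: (new_points, status) where status[k] is False for points whose flow
#: solve failed.
FlowEngine = Callable[[np.ndarray, np.ndarray, np.ndarray, int], tuple[np.ndarray, np.ndarray]]


def _to_gray(frame: np.ndarray) -> np.ndarray:
    a = np.asarray(frame, dtype=np.float64)
    if a.ndim == 3:
        a = a.mean(axis=2)
    return a


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        blurred = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(blurred[::2, ::2])
    return pyr


def _sample_windows(img: np.ndarray, centers: np.ndarray,
                    offsets: np.ndarray) -> np.ndarray:
    """Bilinear-sample (n, m) window values around n center points."""
    # coords: (2, n*m) as (rows, cols)
    rows = centers[:, 1:2] + offsets[None, :, 1]
    cols = centers[:, 0:1] + offsets[None, :, 0]
    coords = np.stack([rows.ravel(), cols.ravel()])
    vals = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return vals.reshape(centers.shape[0], offsets.shape[0])


def pyramidal_lucas_kanade(
    prev: np.ndarray,
    next_: np.ndarray,
    points: np.ndarray,
    window: int,
    levels: int = 3,
    max_iter: int = 8,
    eps: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Track sparse points with iterative coarse-to-fine Lucas-Kanade flow.

    A Gaussian image pyramid with ``levels`` octaves is built for both
    frames; at each level every point's displacement is refined by Newton
    iterations on the window around it (all points solved as one batched
    2x2 system), the coarse estimate seeding the next finer level.
    Points whose normal matrix is near-singular (textureless windows)
    are flagged failed.
    """
    prev_g = _to_gray(prev)
    next_g = _to_gray(next_)
    if prev_g.shape != next_g.shape:
        raise ValueError("frames must share dimensions")
    if window < 3:
        raise ValueError("window must be >= 3 px")
    pts = np.asarray(points, dtype=np.float64)
    half = max(1, int(window) // 2)
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    offsets = np.stack([dx.ravel(), dy.ravel()], axis=1).astype(np.float64)

    pyr_prev = _pyramid(prev_g, levels)
    pyr_next = _pyramid(next_g, levels)

    n = pts.shape[0]
    d = np.zeros((n, 2))
    solved = np.zeros(n, dtype=bool)
    for lev in range(levels - 1, -1, -1):
        scale = 2.0**lev
        centers = pts / scale
        img0 = pyr_prev[lev]
        gy, gx = np.gradient(img0)
        i0 = _sample_windows(img0, centers, offsets)
        jx = _sample_windows(gx, centers, offsets)
        jy = _sample_windows(gy, centers, offsets)
        # batched 2x2 normal matrices
        a = (jx * jx).sum(axis=1)
        b = (jx * jy).sum(axis=1)
        c = (jy * jy).sum(axis=1)
        det = a * c - b * b
        ok = det > 1e-6 * np.maximum(a + c, 1e-12) ** 2
        solved |= ok
        d *= 2.0 if lev < levels - 1 else 1.0
        active = ok.copy()
        for _ in range(max_iter):
            if not np.any(active):
                break
            i1 = _sample_windows(pyr_next[lev], centers[active] + d[active],
                                 offsets)
            diff = i0[active] - i1
            b1 = (jx[active] * diff).sum(axis=1)
            b2 = (jy[active] * diff).sum(axis=1)
            det_a = det[active]
            step_x = (c[active] * b1 - b[active] * b2) / det_a
            step_y = (a[active] * b2 - b[active] * b1) / det_a
            d[active, 0] += step_x
            d[active, 1] += step_y
            still = np.hypot(step_x, step_y) >= eps
            idx = np.flatnonzero(active)
            active[idx[~still]] = False
    d[~solved] = 0.0
    return pts + d, solved


def track_points(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points: PointGrid,
    window: int,
    engine: FlowEngine | None = None,
) -> tuple[PointGrid, bool]:
    """Advance the point grid by one frame; flag when re-detection is due.

    The re-detection flag is raised when any point's displacement exceeds
    10 px — the caller must then rebuild ROIs and the grid on the current
    frame. Points whose flow solve fails keep their previous position.
    """
    engine = engine or pyramidal_lucas_kanade
    new_pts, status = engine(prev_frame, next_frame, points.points, window)
    if not np.all(status):
        log.warning("optical flow failed for %d point(s); carried over",
                    int((~status).sum()))
        new_pts = np.where(status[:, None], new_pts, points.points)
    disp = np.hypot(*(new_pts - points.points).T)
    redetect = bool(np.any(disp > REDETECT_PX))
    return PointGrid(new_pts, points.region), redetect


def lk_window_for_face(face: FaceBox) -> int:
    """Tracker window size: the detected face size divided by 10."""
    return max(3, _round_half_away(max(face.w, face.h) / 10.0))


@dataclass
class TrackingResult:
    """Output of :func:`track_video`: trajectories plus per-frame ROIs."""

    trajectories: TrajectoryBank
    rois_per_frame: list[dict[str, RoiRect]]
    reset_frames: list[int]


def track_video(
    frames: Sequence[np.ndarray],
    face_boxes: dict[int, FaceBox] | Callable[[int, np.ndarray], FaceBox],
    fps: float,
    engine: FlowEngine | None = None,
) -> TrackingResult:
    """Track the facial grid and ROIs across a whole clip.

    ``face_boxes`` supplies a detection for a given frame index — either a
    mapping (e.g. loaded from a sidecar CSV) or a callable wrapping a
    detector. Detection is consulted only on frame 0 and after each
    re-detection trigger; between triggers the similarity transform fitted
    to the tracked points carries the ROIs.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")

    def detect(i: int) -> FaceBox:
        if callable(face_boxes):
            return face_boxes(i, frames[i])
        try:
            return face_boxes[i]
        except KeyError:
            raise ValueError(f"no face box available for frame {i}") from None

    face = detect(0)
    window = lk_window_for_face(face)
    rois = {r.name: r for r in compute_rois(face)}
    grid = make_point_grid(rois["forehead"], rois["nose"])

    n = len(frames)
    xs = np.empty((80, n))
    ys = np.empty((80, n))
    xs[:, 0], ys[:, 0] = grid.points[:, 0], grid.points[:, 1]
    rois_per_frame = [dict(rois)]
    resets: list[int] = []

    for i in range(1, n):
        new_grid, redetect = track_points(
            frames[i - 1], frames[i], grid, window, engine=engine
        )
        if redetect:
            log.info("re-detection triggered at frame %d", i)
            resets.append(i)
            face = detect(i)
            window = lk_window_for_face(face)
            rois = {r.name: r for r in compute_rois(face)}
            grid = make_point_grid(rois["forehead"], rois["nose"])
        else:
            tf = estimate_similarity(grid.points, new_grid.points)
            rois = {name: apply_transform(tf, r) for name, r in rois.items()}
            grid = new_grid
        xs[:, i], ys[:, i] = grid.points[:, 0], grid.points[:, 1]
        rois_per_frame.append(dict(rois))

    bank = TrajectoryBank(
        xs, ys, fps, region=grid.region, reset_frames=tuple(resets)
    )
    return TrackingResult(bank, rois_per_frame, resets)
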