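"""Plain-text serialization of every pipeline artifact.

All formats are CSV with JSON sidecars for scalar metadata (sampling
rate), so runs are inspectable and diffable:

* signals: ``t_seconds,value`` (+ ``<name>.json`` with ``fs``)
* RGB traces: ``frame,roi,r_mean,g_mean,b_mean``
* trajectories: ``point_id,region,x_0,y_0,x_1,y_1,...``
* face boxes: ``frame_index,x,y,w,h``
* HR series: ``t_seconds,hr_bpm,method``
* ground truth: ``t_seconds,hr_bpm``
* agreement metrics: JSON; Bland-Altman pairs: ``mean,diff``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import AgreementStats, HrSeries
from .geometry import FaceBox, TrajectoryBank
from .ppg import RgbTrace
from .signal_core import Signal1D
from .synth import GroundTruth


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_signal(sig: Signal1D, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"t_seconds": sig.times, "value": sig.samples}).to_csv(
        path, index=False
    )
    _sidecar(path).write_text(json.dumps({"fs": sig.fs}))


def read_signal(path: str | Path) -> Signal1D:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    return Signal1D(df["value"].to_numpy(), float(meta["fs"]))


def write_rgb_traces(traces: list[RgbTrace], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for t in traces:
        for i in range(len(t)):
            rows.append((i, t.roi, t.r[i], t.g[i], t.b[i]))
    pd.DataFrame(
        rows, columns=["frame", "roi", "r_mean", "g_mean", "b_mean"]
    ).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"fps": traces[0].fps}))


def read_rgb_traces(path: str | Path) -> list[RgbTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    fps = float(json.loads(_sidecar(path).read_text())["fps"])
    traces = []
    for roi, grp in df.groupby("roi", sort=False):
        grp = grp.sort_values("frame")
        traces.append(
            RgbTrace(
                str(roi),
                grp["r_mean"].to_numpy(),
                grp["g_mean"].to_numpy(),
                grp["b_mean"].to_numpy(),
                fps=fps,
            )
        )
    return traces


def write_trajectories(traj: TrajectoryBank, path: str | Path) -> None:
    path = Path(path)
    data: dict[str, object] = {
        "point_id": np.arange(traj.n_points),
        "region": list(traj.region) or [""] * traj.n_points,
    }
    for f in range(traj.n_frames):
        data[f"x_{f}"] = traj.xs[:, f]
        data[f"y_{f}"] = traj.ys[:, f]
    pd.DataFrame(data).to_csv(path, index=False)
    _sidecar(path).write_text(
        json.dumps({"fps": traj.fps, "reset_frames": list(traj.reset_frames)})
    )


def read_trajectories(path: str | Path) -> TrajectoryBank:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    n_frames = (len(df.columns) - 2) // 2
    xs = np.column_stack([df[f"x_{f}"] for f in range(n_frames)])
    ys = np.column_stack([df[f"y_{f}"] for f in range(n_frames)])
    return TrajectoryBank(
        xs,
        ys,
        float(meta["fps"]),
        region=tuple(df["region"]),
        reset_frames=tuple(meta.get("reset_frames", ())),
    )


def write_face_boxes(boxes: dict[int, FaceBox], path: str | Path) -> None:
    rows = [
        (i, b.x, b.y, b.w, b.h) for i, b in sorted(boxes.items())
    ]
    pd.DataFrame(rows, columns=["frame_index", "x", "y", "w", "h"]).to_csv(
        Path(path), index=False
    )


def read_face_boxes(path: str | Path) -> dict[int, FaceBox]:
    df = pd.read_csv(path)
    return {
        int(r.frame_index): FaceBox(r.x, r.y, r.w, r.h, int(r.frame_index))
        for r in df.itertuples()
    }


def write_hr_series(series: list[HrSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, b in zip(s.times, s.bpm):
            rows.append((t, b, s.method))
    pd.DataFrame(rows, columns=["t_seconds", "hr_bpm", "method"]).to_csv(
        Path(path), index=False
    )


def read_hr_series(path: str | Path) -> list[HrSeries]:
    df = pd.read_csv(path)
    out = []
    for method, grp in df.groupby("method", sort=False):
        grp = grp.sort_values("t_seconds")
        out.append(
            HrSeries(grp["t_seconds"].to_numpy(), grp["hr_bpm"].to_numpy(),
                     str(method))
        )
    return out


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    pd.DataFrame({"t_seconds": gt.times, "hr_bpm": gt.bpm}).to_csv(
        Path(path), index=False
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(df["t_seconds"].to_numpy(), df["hr_bpm"].to_numpy())


def write_metrics(stats: AgreementStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.as_dict(), indent=2))


def write_bland_altman(est: HrSeries, ref: HrSeries, path: str | Path) -> None:
    """Export (mean, difference) pairs for a Bland-Altman plot."""
    from .evaluate import _align

    e, r = _align(est, ref)
    pd.DataFrame({"mean": (e + r) / 2.0, "diff": e - r}).to_csv(
        Path(path), index=False
    )
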