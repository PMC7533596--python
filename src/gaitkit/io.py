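"""Reading and writing the pipeline's delimited-text formats.

Formats (all CSV with header):

* step annotations: ``mouse_id,group,side,step,frame,marker,x,y``
  (marker in {knee, ankle, metatarsus}; x, y in pixels or mm);
* calibration: 4 rows of ``src_x,src_y,dst_x,dst_y`` (pixels -> mm);
* group table: ``mouse_id,group``;
* open-field tracks: ``mouse_id,group,frame,x_cm,y_cm``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import Homography, PointCorrespondence, apply_homography, estimate_homography
from .gait import MARKERS, StepTrace
from .openfield import ArenaGeometry, CentroidTrack

ANNOTATION_COLUMNS = ["mouse_id", "group", "side", "step", "frame", "marker", "x", "y"]
TRACK_COLUMNS = ["mouse_id", "group", "frame", "x_cm", "y_cm"]
CALIBRATION_COLUMNS = ["src_x", "src_y", "dst_x", "dst_y"]


def read_step_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_calibration(path) -> list[PointCorrespondence]:
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) != 4:
        raise ValueError(f"{path}: calibration needs exactly 4 rows, got {len(df)}")
    return [
        PointCorrespondence(
            source=np.array([r.src_x, r.src_y]),
            target=np.array([r.dst_x, r.dst_y]),
        )
        for r in df.itertuples()
    ]


def load_homography(path) -> Homography:
    return estimate_homography(read_calibration(path))


def read_group_table(path) -> dict[str, str]:
    df = pd.read_csv(path)
    for c in ("mouse_id", "group"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    dup = df["mouse_id"][df["mouse_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate mouse ids {sorted(set(dup))}")
    return dict(zip(df["mouse_id"].astype(str), df["group"].astype(str)))


def step_traces_from_frame(
    df: pd.DataFrame,
    *,
    fps: float = 240.0,
    homography: Homography | None = None,
) -> list[StepTrace]:
    """Build StepTrace objects from a long-format annotation table.

    If a homography is given, coordinates are assumed to be pixels and are
    rectified to mm; otherwise they are taken as mm already.
    """
    traces = []
    for (mouse, group, side, step), sub in df.groupby(
        ["mouse_id", "group", "side", "step"], sort=True
    ):
        wide = sub.pivot_table(
            index="frame", columns="marker", values=["x", "y"], aggfunc="first"
        ).sort_index()
        for m in MARKERS:
            if ("x", m) not in wide.columns or wide[("x", m)].isna().any():
                raise ValueError(
                    f"{mouse} {side} step {step}: marker {m!r} missing on some frames"
                )
        frames = wide.index.to_numpy()
        arrays = {}
        for m in MARKERS:
            xy = np.column_stack([wide[("x", m)].to_numpy(), wide[("y", m)].to_numpy()])
            if homography is not None:
                xy = apply_homography(homography, xy)
            arrays[m] = xy
        traces.append(StepTrace(
            mouse_id=str(mouse), group=str(group), side=str(side),
            step_index=int(step), fps=fps, frames=frames,
            knee=arrays["knee"], ankle=arrays["ankle"],
            metatarsus=arrays["metatarsus"],
        ))
    return traces


def read_centroid_tracks(
    path, *, fps: float = 30.0, arena: ArenaGeometry | None = None,
    groups: Mapping[str, str] | None = None,
) -> list[CentroidTrack]:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return centroid_tracks_from_frame(df, fps=fps, arena=arena, groups=groups)


def centroid_tracks_from_frame(
    df: pd.DataFrame, *, fps: float = 30.0, arena: ArenaGeometry | None = None,
    groups: Mapping[str, str] | None = None,
) -> list[CentroidTrack]:
    arena = arena or ArenaGeometry()
    tracks = []
    for mouse, sub in df.groupby("mouse_id", sort=True):
        sub = sub.sort_values("frame")
        group = str(sub["group"].iloc[0])
        if groups is not None:
            group = groups.get(str(mouse), group)
        tracks.append(CentroidTrack(
            mouse_id=str(mouse), group=group, fps=fps,
            points=sub[["x_cm", "y_cm"]].to_numpy(dtype=float), arena=arena,
        ))
    return tracks


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
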