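"""Marker-trajectory data model and per-step gait kinematics.

One *step* (stride cycle) of one hindlimb is a :class:`StepTrace`: the
(x, y) positions of the knee, ankle and metatarsus markers on every video
frame between the manually annotated start and end instants, at a known
frame rate (240 fps for the tunnel-walk recordings).

Step length and speed follow the horizontal (x) coordinate of the
metatarsus: length is the net |dx| between the step boundaries, duration
is the frame span divided by fps, and speed is their ratio.  Left/right
step pairs are classified into four types:

* **A** -- left and right agree in both duration and length (within tolerance);
* **B** -- both strides are short relative to a baseline length;
* **C** -- the left stride is longer than the right;
* **D** -- the right stride is longer than the left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKERS",
    "GROUPS",
    "MarkerFrame",
    "StepTrace",
    "StepKinematics",
    "StepClass",
    "step_duration",
    "step_kinematics",
    "classify_step_pair",
    "pair_steps",
    "step_type_distribution",
]

MARKERS = ("knee", "ankle", "metatarsus")
GROUPS = ("control", "CI", "HI", "HIEV")
STEP_CLASSES = ("A", "B", "C", "D")

#: expected steps per mouse per hindlimb; outside this we warn, never fail
EXPECTED_STEP_RANGE = (5, 7)

#: plausible vertical band for markers above the belt, mm
Y_BAND_MM = (0.0, 60.0)

Side = Literal["left", "right"]


@dataclass(frozen=True)
class MarkerFrame:
    """Marker positions on a single frame (x along travel, y up; mm)."""

    frame: int
    knee: np.ndarray
    ankle: np.ndarray
    metatarsus: np.ndarray


@dataclass
class StepTrace:
    """All marker samples of one hindlimb during one step.

    Coordinates are stored as ``(n, 2)`` arrays per marker, aligned with
    ``frames`` (strictly increasing integer frame indices).
    """

    mouse_id: str
    group: str
    side: Side
    step_index: int
    fps: float
    frames: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    metatarsus: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in MARKERS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.frames), 2):
                raise ValueError(
                    f"{name} must have shape ({len(self.frames)}, 2), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} coordinates must be finite")
            setattr(self, name, arr)
        if len(self.frames) < 2:
            raise ValueError("a step needs at least 2 frames")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.step_index < 1:
            raise ValueError("step_index starts at 1")

    def marker(self, name: str) -> np.ndarray:
        if name not in MARKERS:
            raise KeyError(f"unknown marker {name!r}; expected one of {MARKERS}")
        return getattr(self, name)

    def iter_frames(self) -> Iterator[MarkerFrame]:
        for i, f in enumerate(self.frames):
            yield MarkerFrame(
                int(f), self.knee[i], self.ankle[i], self.metatarsus[i]
            )

    def validate_y_band(self) -> None:
        """Warn if marker heights leave the plausible band above the belt."""
        lo, hi = Y_BAND_MM
        for name in MARKERS:
            y = self.marker(name)[:, 1]
            if y.min() < lo or y.max() > hi:
                warnings.warn(
                    f"{self.mouse_id} {self.side} step {self.step_index}: "
                    f"{name} y outside [{lo}, {hi}] mm",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class StepKinematics:
    """Duration (s), stride length (mm) and speed (mm/s) of one step."""

    duration: float
    stride_length: float
    speed: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.stride_length < 0:
            raise ValueError("stride_length must be non-negative")


@dataclass(frozen=True)
class StepClass:
    label: Literal["A", "B", "C", "D"]

    def __post_init__(self) -> None:
        if self.label not in STEP_CLASSES:
            raise ValueError(f"label must be one of {STEP_CLASSES}")


def step_duration(step: StepTrace) -> float:
    """Step duration in seconds: frame span over fps.

    The annotated boundaries are instants, so the denominator is the span
    between first and last frame, not the frame count.
    """
    return float(step.frames[-1] - step.frames[0]) / step.fps


def step_kinematics(step: StepTrace) -> StepKinematics:
    """Length and speed of a step from the metatarsus x coordinate."""
    duration = step_duration(step)
    if duration <= 0:
        raise ValueError("zero-duration step")
    x = step.metatarsus[:, 0]
    stride = abs(float(x[-1] - x[0]))
    return StepKinematics(duration=duration, stride_length=stride, speed=stride / duration)


def classify_step_pair(
    left: StepKinematics,
    right: StepKinematics,
    baseline_length: float,
    time_tol: float = 0.15,
    length_tol: float = 0.15,
) -> StepClass:
    """Classify a left/right step pair into Type A, B, C or D.

    Decision order:

    1. both stride lengths below ``(1 - length_tol) * baseline_length`` -> **B**
       (both strides shortened);
    2. else, lengths within ``length_tol`` of each other *and* durations
       within ``time_tol`` of each other (relative to the larger) -> **A**;
    3. else **C** if the left stride is longer, **D** otherwise.

    The ordering makes the classes exhaustive and mutually exclusive.
    """
    if time_tol <= 0 or length_tol <= 0:
        raise ValueError("tolerances must be positive")
    if baseline_length <= 0:
        raise ValueError("baseline_length must be positive")

    short_cut = (1.0 - length_tol) * baseline_length
    if left.stride_length < short_cut and right.stride_length < short_cut:
        return StepClass("B")
    max_len = max(left.stride_length, right.stride_length)
    max_dur = max(left.duration, right.duration)
    len_ok = abs(left.stride_length - right.stride_length) <= length_tol * max_len
    dur_ok = abs(left.duration - right.duration) <= time_tol * max_dur
    if len_ok and dur_ok:
        return StepClass("A")
    if left.stride_length != right.stride_length:
        return StepClass("C" if left.stride_length > right.stride_length else "D")
    # exactly equal lengths but unequal timing: break the tie on duration so
    # relabelling the limbs still swaps C and D
    return StepClass("C" if left.duration > right.duration else "D")


def pair_steps(
    left_steps: Sequence[StepTrace], right_steps: Sequence[StepTrace]
) -> list[tuple[StepTrace, StepTrace]]:
    """Pair left and right steps of one mouse by temporal frame-range overlap.

    Each left step is matched to the unmatched right step whose frame range
    overlaps it the most; steps with no overlap stay unpaired (they are still
    used for speed analysis, just not for classification).
    """
    pairs: list[tuple[StepTrace, StepTrace]] = []
    used: set[int] = set()
    for ls in sorted(left_steps, key=lambda s: s.frames[0]):
        best_j, best_ov = -1, 0
        for j, rs in enumerate(right_steps):
            if j in used:
                continue
            ov = min(ls.frames[-1], rs.frames[-1]) - max(ls.frames[0], rs.frames[0])
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0:
            used.add(best_j)
            pairs.append((ls, right_steps[best_j]))
    return pairs


def step_type_distribution(
    labels: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-group proportions over step types A-D.

    Parameters
    ----------
    labels
        Either a mapping ``group -> sequence of labels`` or a DataFrame with
        ``group`` and ``label`` columns.

    Returns
    -------
    DataFrame indexed by group with one column per type; rows sum to 1.
    """
    if isinstance(labels, pd.DataFrame):
        grouped = {g: list(sub["label"]) for g, sub in labels.groupby("group", sort=True)}
    else:
        grouped = {g: list(v) for g, v in labels.items()}
    rows = {}
    for group in sorted(grouped):
        labs = grouped[group]
        if len(labs) == 0:
            raise ValueError(f"group {group!r} has no classified step pairs")
        bad = set(labs) - set(STEP_CLASSES)
        if bad:
            raise ValueError(f"unknown step labels {sorted(bad)}")
        n = len(labs)
        rows[group] = {c: labs.count(c) / n for c in STEP_CLASSES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STEP_CLASSES))


def check_step_counts(steps: Sequence[StepTrace]) -> list[str]:
    """Return warnings for mice/sides outside the expected 5-7 step range."""
    lo, hi = EXPECTED_STEP_RANGE
    counts: dict[tuple[str, str], int] = {}
    for s in steps:
        counts[(s.mouse_id, s.side)] = counts.get((s.mouse_id, s.side), 0) + 1
    out = []
    for (mouse, side), n in sorted(counts.items()):
        if not lo <= n <= hi:
            out.append(
                f"{mouse} {side}: {n} steps (expected {lo}-{hi} per hindlimb)"
            )
    return out
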