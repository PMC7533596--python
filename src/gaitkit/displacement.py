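"""Step-cycle normalization and the pairwise curve-distance statistic D.

Each marker's displacement during one step is resampled onto a common
percent-of-cycle axis (100 samples) with a cubic spline, so steps of
different durations become comparable point-for-point.  Two normalized
curves are then compared with the mean squared pointwise difference over
both axes,

    D = (1/200) * [ sum_i (x1_i - x2_i)^2 + sum_i (y1_i - y2_i)^2 ],

with i running over the 100 cycle samples (200 squared terms in total;
units mm^2).  D is symmetric, non-negative, zero iff the curves coincide
at every sample, and invariant to a common translation of both curves.

For group comparison, every step curve of a subject mouse is compared with
every step curve of every mouse in a reference (control) group; the
smallest and largest distances found are the subject's D_min and D_max.
Within the control group itself, same-mouse comparisons are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .gait import MARKERS, StepTrace

__all__ = [
    "N_CYCLE_SAMPLES",
    "NormalizedCurve",
    "PairwiseDistance",
    "SubjectDistanceSummary",
    "normalize_curve",
    "curves_from_step",
    "curve_distance",
    "pairwise_distances",
    "subject_min_max",
    "group_distance_summary",
]

N_CYCLE_SAMPLES = 100

DVariant = Literal["mean_both", "x_scaled_only"]


@dataclass(frozen=True)
class NormalizedCurve:
    """A marker's displacement over one step, resampled to 100 cycle points."""

    marker: str
    side: str
    mouse_id: str
    step_index: int
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CYCLE_SAMPLES,):
                raise ValueError(
                    f"{name} must have exactly {N_CYCLE_SAMPLES} samples, "
                    f"got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")

    @property
    def provenance(self) -> tuple[str, int]:
        return (self.mouse_id, self.step_index)


@dataclass(frozen=True)
class PairwiseDistance:
    """The D statistic between two curves, with provenance of both."""

    D: float
    curve_a: tuple[str, int]
    curve_b: tuple[str, int]


@dataclass(frozen=True)
class SubjectDistanceSummary:
    """Per-mouse extremes of D against a reference group."""

    mouse_id: str
    marker: str
    side: str
    D_min: float
    D_max: float
    argmin: tuple[tuple[str, int], tuple[str, int]]
    argmax: tuple[tuple[str, int], tuple[str, int]]


def normalize_curve(
    frames: np.ndarray,
    xy: np.ndarray,
    *,
    marker: str,
    side: str,
    mouse_id: str = "",
    step_index: int = 1,
    n: int = N_CYCLE_SAMPLES,
) -> NormalizedCurve:
    """Resample one marker track onto ``n`` evenly spaced percent-cycle points.

    Frame indices are mapped affinely onto [0, 1]; x(t) and y(t) are
    interpolated with a cubic spline (not-a-knot end conditions, so
    polynomials up to cubic are reproduced exactly) and evaluated at ``n``
    evenly spaced parameters including both endpoints.  The first and last
    output samples are pinned to the raw endpoint values.

    Raises
    ------
    ValueError
        If fewer than 4 frames are given (cubic spline needs 4 knots) or
        frame indices are not strictly increasing.
    """
    t = np.asarray(frames, dtype=float)
    pts = np.asarray(xy, dtype=float)
    if t.ndim != 1 or len(t) < 4:
        raise ValueError("need at least 4 frames for cubic-spline normalization")
    d = np.diff(t)
    if np.any(d == 0):
        raise ValueError("duplicate frame indices")
    if np.any(d < 0):
        raise ValueError("frame indices must be strictly increasing")
    if pts.shape != (len(t), 2):
        raise ValueError(f"xy must have shape ({len(t)}, 2)")
    u = (t - t[0]) / (t[-1] - t[0])
    grid = np.linspace(0.0, 1.0, n)
    out = CubicSpline(u, pts, axis=0)(grid)
    out[0] = pts[0]
    out[-1] = pts[-1]
    return NormalizedCurve(
        marker=marker, side=side, mouse_id=mouse_id, step_index=step_index,
        x=out[:, 0], y=out[:, 1],
    )


def curves_from_step(
    step: StepTrace, *, rezero: bool = True, markers: Sequence[str] = MARKERS
) -> dict[str, NormalizedCurve]:
    """Normalized curves of a step's markers.

    With ``rezero`` (default), the metatarsus x position on the first frame
    of the step is subtracted from every marker's x, so curves describe
    displacement within the step rather than absolute position along the
    tunnel.  Without it D would mostly measure where in the tunnel the step
    happened, not its shape.
    """
    x0 = step.metatarsus[0, 0] if rezero else 0.0
    out = {}
    for m in markers:
        xy = step.marker(m).copy()
        xy[:, 0] -= x0
        out[m] = normalize_curve(
            step.frames, xy, marker=m, side=step.side,
            mouse_id=step.mouse_id, step_index=step.step_index,
        )
    return out


def curve_distance(
    a: NormalizedCurve, b: NormalizedCurve, *, variant: DVariant = "mean_both"
) -> PairwiseDistance:
    """The distance D between two normalized curves of the same marker/side.

    ``variant`` controls where the 1/200 factor applies.  The default
    ``"mean_both"`` scales the sum of both axis sums (the mean of all 200
    squared differences).  ``"x_scaled_only"`` applies 1/200 to the x sum
    only and adds the raw y sum -- kept for sensitivity checks.
    """
    if a.marker != b.marker:
        raise ValueError(f"marker mismatch: {a.marker} vs {b.marker}")
    if a.side != b.side:
        raise ValueError(f"side mismatch: {a.side} vs {b.side}")
    sx = float(np.sum((a.x - b.x) ** 2))
    sy = float(np.sum((a.y - b.y) ** 2))
    if variant == "mean_both":
        d = (sx + sy) / (2 * N_CYCLE_SAMPLES)
    elif variant == "x_scaled_only":
        d = sx / (2 * N_CYCLE_SAMPLES) + sy
    else:
        raise ValueError(f"unknown D variant {variant!r}")
    return PairwiseDistance(D=d, curve_a=a.provenance, curve_b=b.provenance)


def pairwise_distances(
    steps_a: Sequence[NormalizedCurve],
    steps_b: Sequence[NormalizedCurve],
    *,
    variant: DVariant = "mean_both",
) -> list[PairwiseDistance]:
    """All |steps_a| x |steps_b| distances, ordered by (step_a, step_b)."""
    if len(steps_a) == 0 or len(steps_b) == 0:
        raise ValueError("both curve sets must be non-empty")
    sa = sorted(steps_a, key=lambda c: c.provenance)
    sb = sorted(steps_b, key=lambda c: c.provenance)
    return [curve_distance(a, b, variant=variant) for a in sa for b in sb]


def subject_min_max(
    subject_id: str,
    curves_by_mouse: Mapping[str, Sequence[NormalizedCurve]],
    reference_ids: Iterable[str],
    *,
    exclude_self: bool = True,
    variant: DVariant = "mean_both",
) -> SubjectDistanceSummary:
    """D_min/D_max of one mouse's steps against a reference group's steps.

    Every step curve of the subject is compared with every step curve of
    every reference mouse; with ``exclude_self`` (always on for
    within-control summaries) comparisons against the subject's own steps
    are dropped.  Ties break toward the lexicographically smallest
    ``((mouse, step), (mouse, step))`` pair, which the iteration order
    guarantees.
    """
    subject_curves = sorted(curves_by_mouse[subject_id], key=lambda c: c.provenance)
    if not subject_curves:
        raise ValueError(f"subject {subject_id!r} has no curves")
    marker = subject_curves[0].marker
    side = subject_curves[0].side

    best_min: PairwiseDistance | None = None
    best_max: PairwiseDistance | None = None
    for ref_id in sorted(set(reference_ids)):
        if exclude_self and ref_id == subject_id:
            continue
        for a in subject_curves:
            for b in sorted(curves_by_mouse[ref_id], key=lambda c: c.provenance):
                pd_ = curve_distance(a, b, variant=variant)
                if best_min is None or pd_.D < best_min.D:
                    best_min = pd_
                if best_max is None or pd_.D > best_max.D:
                    best_max = pd_
    if best_min is None or best_max is None:
        raise ValueError(
            f"no comparison pairs for subject {subject_id!r} "
            "(empty reference after self-exclusion?)"
        )
    return SubjectDistanceSummary(
        mouse_id=subject_id, marker=marker, side=side,
        D_min=best_min.D, D_max=best_max.D,
        argmin=(best_min.curve_a, best_min.curve_b),
        argmax=(best_max.curve_a, best_max.curve_b),
    )


def group_distance_summary(
    curves: Sequence[NormalizedCurve],
    groups: Mapping[str, str],
    reference_group: str = "control",
    *,
    step_filter: str = "all",
    variant: DVariant = "mean_both",
) -> pd.DataFrame:
    """Per-mouse D_min/D_max for every group against the reference group.

    Reference-group mice are summarized within-group with self-exclusion;
    every other mouse is compared against all reference mice.  ``curves``
    must all share one marker and side (run once per marker/side).

    Returns a DataFrame with one row per mouse:
    ``mouse_id, group, marker, side, step_filter, D_min, D_max, argmin, argmax``.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves given")
    marker = curves[0].marker
    side = curves[0].side
    if any(c.marker != marker or c.side != side for c in curves):
        raise ValueError("all curves must share one marker and side")

    by_mouse: dict[str, list[NormalizedCurve]] = {}
    for c in curves:
        by_mouse.setdefault(c.mouse_id, []).append(c)
    unknown = sorted(set(by_mouse) - set(groups))
    if unknown:
        raise ValueError(f"mice missing from group table: {unknown}")
    ref_ids = sorted(m for m in by_mouse if groups[m] == reference_group)
    if len(ref_ids) < 2:
        raise ValueError(
            f"reference group {reference_group!r} needs >= 2 mice with curves"
        )

    rows = []
    for mouse in sorted(by_mouse):
        summ = subject_min_max(
            mouse, by_mouse, ref_ids,
            exclude_self=groups[mouse] == reference_group,
            variant=variant,
        )
        rows.append({
            "mouse_id": mouse,
            "group": groups[mouse],
            "marker": marker,
            "side": side,
            "step_filter": step_filter,
            "D_min": summ.D_min,
            "D_max": summ.D_max,
            "argmin": _fmt_pair(summ.argmin),
            "argmax": _fmt_pair(summ.argmax),
        })
    return pd.DataFrame(rows)


def _fmt_pair(pair: tuple[tuple[str, int], tuple[str, int]]) -> str:
    (ma, sa), (mb, sb) = pair
    return f"D_{ma}s{sa}_{mb}s{sb}"
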