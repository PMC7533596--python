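"""Open-field locomotion metrics: distance, moving speed and thigmotaxis.

The arena is a rectangular 45 x 32 cm box divided into a 4 x 4 grid of
16 quadrants (11.25 x 8 cm each); the 12 quadrants touching a wall form
the periphery and the inner 2 x 2 block the center.  Time in the
periphery quantifies thigmotaxis (wall hugging).  Locomotion speed is
total path length divided by *moving* time: frames where the animal is
still (sustained sub-threshold speed) are excluded from the denominator
but their (negligible) path contribution stays in the total distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ArenaGeometry",
    "CentroidTrack",
    "OpenFieldMetrics",
    "classify_zone",
    "total_distance",
    "still_mask",
    "moving_speed",
    "periphery_time",
    "compute_metrics",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Rectangular arena partitioned into a 4 x 4 quadrant grid (cm)."""

    width: float = 45.0
    depth: float = 32.0
    nx: int = 4
    ny: int = 4
    boundary_tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3 x 3 to have a center block")

    @property
    def quadrant_size(self) -> tuple[float, float]:
        return (self.width / self.nx, self.height_of_cell())

    def height_of_cell(self) -> float:
        return self.depth / self.ny

    @property
    def n_periphery(self) -> int:
        return self.nx * self.ny - (self.nx - 2) * (self.ny - 2)

    def quadrant_index(self, point: np.ndarray) -> tuple[int, int]:
        """Column/row of the quadrant containing ``point`` (half-open cells)."""
        x, y = float(point[0]), float(point[1])
        ix = min(int(x // (self.width / self.nx)), self.nx - 1)
        iy = min(int(y // (self.depth / self.ny)), self.ny - 1)
        return max(ix, 0), max(iy, 0)


@dataclass
class CentroidTrack:
    """Centroid positions of one mouse in the open field (cm, 30 fps)."""

    mouse_id: str
    group: str
    fps: float
    points: np.ndarray
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        tol = self.arena.boundary_tolerance
        lo = np.array([0.0, 0.0])
        hi = np.array([self.arena.width, self.arena.depth])
        if np.any(pts < lo - tol) or np.any(pts > hi + tol):
            raise ValueError(
                f"track {self.mouse_id}: points outside arena beyond "
                f"{tol} cm tolerance"
            )
        if np.any(pts < lo) or np.any(pts > hi):
            warnings.warn(
                f"track {self.mouse_id}: points within {tol} cm outside the "
                "arena were clamped to the walls",
                stacklevel=2,
            )
            pts = np.clip(pts, lo, hi)
        self.points = pts

    @property
    def duration(self) -> float:
        """Track duration in seconds (frame count over fps)."""
        return len(self.points) / self.fps


@dataclass(frozen=True)
class OpenFieldMetrics:
    total_distance: float  # cm
    moving_time: float  # s
    speed: float  # cm/s, still time excluded
    periphery_time: float  # s
    still_time: float  # s
    duration: float  # s


def classify_zone(
    point: np.ndarray, arena: ArenaGeometry
) -> Literal["periphery", "center"]:
    """Zone of a point: center iff its quadrant is in the inner block.

    Quadrant cells are half-open, so points exactly on the center-block
    boundary fall in the periphery (wall-adjacent bias keeps the rule
    deterministic).
    """
    x, y = float(point[0]), float(point[1])
    tol = arena.boundary_tolerance
    if not (-tol <= x <= arena.width + tol and -tol <= y <= arena.depth + tol):
        raise ValueError(f"point {(x, y)} outside arena beyond tolerance")
    ix, iy = arena.quadrant_index(np.clip([x, y], [0, 0], [arena.width, arena.depth]))
    inner_x = 1 <= ix <= arena.nx - 2
    inner_y = 1 <= iy <= arena.ny - 2
    return "center" if (inner_x and inner_y) else "periphery"


def total_distance(track: CentroidTrack) -> float:
    """Total path length: sum of Euclidean inter-frame displacements (cm)."""
    if len(track.points) < 2:
        warnings.warn("single-point track: total distance is 0", stacklevel=2)
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(track.points, axis=0), axis=1)))


def still_mask(
    track: CentroidTrack,
    still_speed_threshold: float = 0.5,
    still_min_duration: float = 0.5,
) -> np.ndarray:
    """Boolean mask of frames the animal is still.

    Frame speeds are backward differences (frame i carries the displacement
    from frame i-1; frame 0 copies frame 1).  Runs of sub-threshold frames
    lasting at least ``still_min_duration`` seconds are marked still;
    shorter dips count as moving.
    """
    if still_speed_threshold <= 0:
        raise ValueError("still_speed_threshold must be positive")
    n = len(track.points)
    if n < 2:
        return np.zeros(n, dtype=bool)
    speeds = np.empty(n)
    speeds[1:] = np.linalg.norm(np.diff(track.points, axis=0), axis=1) * track.fps
    speeds[0] = speeds[1]
    slow = speeds < still_speed_threshold
    min_frames = max(int(round(still_min_duration * track.fps)), 1)

    mask = np.zeros(n, dtype=bool)
    # mark maximal runs of slow frames that last long enough
    edges = np.flatnonzero(np.diff(np.concatenate(([0], slow.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_frames:
            mask[start:stop] = True
    return mask


def moving_speed(
    track: CentroidTrack,
    still_speed_threshold: float = 0.5,
    still_min_duration: float = 0.5,
) -> OpenFieldMetrics:
    """Locomotion metrics with still time excluded from the speed denominator."""
    dist = total_distance(track)
    still = still_mask(track, still_speed_threshold, still_min_duration)
    duration = track.duration
    still_time = float(still.sum()) / track.fps
    moving_time = duration - still_time
    if moving_time <= 0:
        raise ValueError(
            f"track {track.mouse_id}: animal never moved; speed undefined"
        )
    return OpenFieldMetrics(
        total_distance=dist,
        moving_time=moving_time,
        speed=dist / moving_time,
        periphery_time=periphery_time(track),
        still_time=still_time,
        duration=duration,
    )


def periphery_time(track: CentroidTrack) -> float:
    """Seconds spent in the 12 wall-adjacent quadrants."""
    arena = track.arena
    w_cell = arena.width / arena.nx
    d_cell = arena.depth / arena.ny
    ix = np.minimum((track.points[:, 0] // w_cell).astype(int), arena.nx - 1)
    iy = np.minimum((track.points[:, 1] // d_cell).astype(int), arena.ny - 1)
    center = (ix >= 1) & (ix <= arena.nx - 2) & (iy >= 1) & (iy <= arena.ny - 2)
    return float((~center).sum()) / track.fps


def compute_metrics(
    track: CentroidTrack,
    still_speed_threshold: float = 0.5,
    still_min_duration: float = 0.5,
) -> OpenFieldMetrics:
    """All open-field metrics for one track."""
    return moving_speed(track, still_speed_threshold, still_min_duration)
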