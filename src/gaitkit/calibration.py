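"""Planar homography calibration for gait video.

Tunnel-walk recordings are filmed through a transparent wall, so raw pixel
coordinates carry lens/perspective distortion.  A single planar homography
per camera removes it and simultaneously converts pixels to millimetres on
the rectified tunnel-wall plane: the four calibration targets are given in
mm, so no separate scale step exists.

The homography is determined exactly from four point correspondences
(a projective map of the plane has 8 degrees of freedom; four points in
general position pin them all down).  We solve the homogeneous 8x9 direct
linear transform (DLT) system via its SVD null space -- an exact solve,
not a least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PointCorrespondence",
    "Homography",
    "DegenerateConfigurationError",
    "estimate_homography",
    "apply_homography",
]

#: triangle area below this fraction of the bounding-box area counts as collinear
COLLINEARITY_REL_TOL = 1e-9


class DegenerateConfigurationError(ValueError):
    """Raised when calibration points cannot determine a homography."""


@dataclass(frozen=True)
class PointCorrespondence:
    """One calibration pair: image point (pixels) -> rectified point (mm)."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float).reshape(2)
        dst = np.asarray(self.target, dtype=float).reshape(2)
        if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
            raise ValueError("calibration points must be finite")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", dst)


@dataclass(frozen=True)
class Homography:
    """A 3x3 projective map, normalized so the bottom-right entry is 1 when nonzero."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography entries must be finite")
        if abs(np.linalg.det(m)) < 1e-12 * max(np.abs(m).max(), 1.0) ** 3:
            raise ValueError("homography must be invertible")
        if abs(m[2, 2]) > 1e-12 * np.abs(m).max():
            m = m / m[2, 2]
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.matrix @ other.matrix)


def _any_three_collinear(points: np.ndarray) -> bool:
    """True if any 3 of the 4 points are collinear relative to their extent."""
    span = points.max(axis=0) - points.min(axis=0)
    bbox_area = max(span[0] * span[1], np.max(span) ** 2, 1e-300)
    idx = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for i, j, k in idx:
        a, b, c = points[i], points[j], points[k]
        u, v = b - a, c - a
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        if area <= COLLINEARITY_REL_TOL * bbox_area:
            return True
    return False


def estimate_homography(
    correspondences: Sequence[PointCorrespondence],
) -> Homography:
    """Estimate the planar homography from exactly four correspondences.

    Builds the standard DLT system (two rows per point) and takes the
    one-dimensional null space of the resulting 8x9 matrix.  With four
    points in general position the solution is exact: every source maps
    onto its target to machine precision.

    Raises
    ------
    ValueError
        If the number of correspondences is not exactly 4.
    DegenerateConfigurationError
        If any three source or three target points are collinear.
    """
    correspondences = list(correspondences)
    if len(correspondences) != 4:
        raise ValueError(
            f"exactly 4 correspondences are required, got {len(correspondences)}"
        )
    src = np.array([c.source for c in correspondences])
    dst = np.array([c.target for c in correspondences])
    if _any_three_collinear(src):
        raise DegenerateConfigurationError("three source points are collinear")
    if _any_three_collinear(dst):
        raise DegenerateConfigurationError("three target points are collinear")

    rows = []
    for (x, y), (u, v) in zip(src, dst):
        rows.append([-x, -y, -1.0, 0.0, 0.0, 0.0, u * x, u * y, u])
        rows.append([0.0, 0.0, 0.0, -x, -y, -1.0, v * x, v * y, v])
    a = np.array(rows)
    # null vector = right singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(a)
    h = vt[-1].reshape(3, 3)
    try:
        return Homography(h)
    except ValueError as exc:  # pragma: no cover - guarded by collinearity test
        raise DegenerateConfigurationError(str(exc)) from exc


def apply_homography(
    h: Homography, points: Iterable[Sequence[float]] | np.ndarray
) -> np.ndarray:
    """Map points through ``h`` with homogeneous division.

    Parameters
    ----------
    h : Homography
    points : array-like, shape (n, 2) or (2,)

    Returns
    -------
    ndarray with the same leading shape, in target units (mm).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    single = np.asarray(points).ndim == 1
    if pts.shape[1] != 2:
        raise ValueError("points must be 2-vectors")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = hom[:, 2]
    scale = max(np.abs(hom[:, :2]).max(initial=0.0), 1.0)
    if np.any(np.abs(w) < 1e-12 * scale):
        raise ValueError("point maps to the line at infinity (homogeneous w ~ 0)")
    out = hom[:, :2] / w[:, None]
    return out[0] if single else out
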