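"""Primitive planar geometry for traced spindle structures.

Everything downstream (strain maps, curvature profiles, spindle metrics)
reduces to a handful of polyline operations: arc-length measurement and
resampling, signed curvature from a circumscribed circle through three
points, and least-squares rigid (rotation + translation) registration of
matched point sets.  All coordinates are in micrometres, in mathematical
convention (y increases upward); conversion from image convention happens
once, at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "as_polyline",
    "polyline_length",
    "cumulative_arclength",
    "resample_arclength",
    "point_at_arclength",
    "circumcircle_signed_curvature",
    "RigidTransform2D",
    "rigid_align",
]


def as_polyline(points: np.ndarray) -> np.ndarray:
    """Validate and return an (n, 2) float array of polyline vertices.

    Requires n >= 2, finite coordinates, and no two *consecutive* points
    identical (zero-length segments make arc-length parameterization
    ill-defined).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"polyline must be an (n, 2) array, got shape {p.shape}")
    if p.shape[0] < 2:
        raise ValueError("polyline needs at least 2 points")
    if not np.all(np.isfinite(p)):
        raise ValueError("polyline contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ValueError("polyline has coincident consecutive points")
    return p


def polyline_length(points: np.ndarray) -> float:
    """Total arc length (um): sum of segment lengths."""
    p = as_polyline(points)
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of every vertex, starting at 0."""
    p = as_polyline(points)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_arclength(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` vertices at equal arc-length spacing.

    The first and last output points equal the input endpoints bit-exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    p = as_polyline(points)
    s = cumulative_arclength(p)
    total = s[-1]
    if total <= 0.0:
        raise ValueError("cannot resample a zero-length polyline")
    target = np.linspace(0.0, total, n_points)
    out = np.column_stack(
        [np.interp(target, s, p[:, 0]), np.interp(target, s, p[:, 1])]
    )
    out[0] = p[0]
    out[-1] = p[-1]
    return out


def point_at_arclength(points: np.ndarray, s_query) -> np.ndarray:
    """Interpolate point(s) at given arc-length position(s) along a polyline."""
    p = as_polyline(points)
    s = cumulative_arclength(p)
    sq = np.atleast_1d(np.asarray(s_query, dtype=float))
    if np.any(sq < -1e-9) or np.any(sq > s[-1] + 1e-9):
        raise ValueError("arc-length query outside [0, length]")
    sq = np.clip(sq, 0.0, s[-1])
    out = np.column_stack([np.interp(sq, s, p[:, 0]), np.interp(sq, s, p[:, 1])])
    return out[0] if np.isscalar(s_query) or np.asarray(s_query).ndim == 0 else out


def circumcircle_signed_curvature(p1, p2, p3, normal_ref) -> float:
    """Signed curvature (1/um) from the circle circumscribing three points.

    Magnitude is the inverse circumradius, ``kappa = 4*A / (a*b*c)`` with A
    the triangle area and a, b, c the side lengths; exactly collinear points
    give 0.  The sign is positive when the middle point bows toward
    ``normal_ref`` (i.e. the deviation of p2 from the p1-p3 chord midpoint
    has positive dot product with the reference normal), which pins the bend
    at the microneedle to positive and the chromosome-proximal reverse bend
    to negative once the reference is fixed per manipulation.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise ValueError("circumcircle requires three distinct points")
    cross = (p2[0] - p1[0]) * (p3[1] - p2[1]) - (p2[1] - p1[1]) * (p3[0] - p2[0])
    area2 = abs(cross)  # = 2 * triangle area
    if area2 == 0.0:
        return 0.0
    kappa = 2.0 * area2 / (a * b * c)
    bow = p2 - 0.5 * (p1 + p3)
    n = np.asarray(normal_ref, dtype=float)
    dot = float(bow @ n)
    if dot != 0.0:
        sign = np.sign(dot)
    else:
        # bow exactly perpendicular to the reference: fall back on the turn
        # direction (left turn positive) so the result stays deterministic
        sign = np.sign(cross)
    return float(sign * kappa)


@dataclass(frozen=True)
class RigidTransform2D:
    """Proper rigid motion of the plane: rotation (degrees, CCW) then translation."""

    rotation_deg: float
    translation: tuple[float, float]

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + np.asarray(self.translation)
        return out[0] if single else out

    def inverse(self) -> "RigidTransform2D":
        Rinv = self.matrix.T
        t = -Rinv @ np.asarray(self.translation)
        return RigidTransform2D(-self.rotation_deg, (float(t[0]), float(t[1])))


def rigid_align(
    moving: np.ndarray,
    fixed: np.ndarray,
    anchor_mask: np.ndarray | None = None,
) -> tuple[RigidTransform2D, np.ndarray]:
    """Least-squares rigid registration of index-matched point sets.

    Solves for the rotation + translation (no scaling, reflection forbidden)
    minimizing the summed squared residual over anchor pairs, via the
    cross-covariance/SVD (Kabsch) solution, and applies it to *all* moving
    points.  Used to remove whole-spindle rotation and translation between
    frames so that only internal deformation remains.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 2:
        raise ValueError("moving and fixed must be matching (n, 2) arrays")
    if anchor_mask is None:
        anchor_mask = np.ones(len(mov), dtype=bool)
    anchor_mask = np.asarray(anchor_mask, dtype=bool)
    if anchor_mask.shape != (len(mov),):
        raise ValueError("anchor_mask length must match the point sets")
    m = mov[anchor_mask]
    f = fix[anchor_mask]
    if len(m) < 2:
        raise ValueError("rigid alignment needs at least 2 anchor pairs")
    cm = m.mean(axis=0)
    cf = f.mean(axis=0)
    if np.allclose(m, m[0]) :
        raise ValueError("all anchor points coincide; rotation is undefined")
    H = (m - cm).T @ (f - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cf - R @ cm
    angle = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    tf = RigidTransform2D(angle, (float(t[0]), float(t[1])))
    return tf, tf.apply(mov)
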