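"""Strain maps and the spatial decay of deformation.

A strain map links each of the ``resample_points`` equally spaced
coordinates stored along every structure in the undeformed frame to the
same-index coordinate in the deformed frame, after removing whole-spindle
rigid motion.  The per-pair displacement magnitude D, plotted against the
pair's distance d from the microneedle tip, quantifies how far a local pull
propagates; its spatial profile is summarized by a two-parameter
exponential fit D = A * exp(-lambda * d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import RunConfig, DEFAULT_CONFIG
from .geometry import polyline_length, resample_arclength, rigid_align, RigidTransform2D
from .scene import SpindleFrame

__all__ = [
    "StrainMap",
    "DecayFit",
    "build_strain_map",
    "deformation_vs_distance",
    "fit_exponential_decay",
]


@dataclass
class StrainMap:
    """Matched undeformed/deformed point pairs after rigid correction.

    ``pairs`` columns: structure_id, point_index, x0, y0 (undeformed),
    x1, y1 (deformed, rigid-corrected), D (displacement magnitude, um),
    d (distance from the needle tip, um; NaN when no needle was traced).
    """

    pairs: pd.DataFrame
    transform: RigidTransform2D
    needle: np.ndarray | None
    cell_id: str = ""

    @property
    def D(self) -> np.ndarray:
        return self.pairs["D"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.pairs["d"].to_numpy()

    def half_spindle(self, frame0: SpindleFrame) -> "StrainMap":
        """Restrict the map to the manipulated (needle-side) half-spindle.

        Deformation decays are quantified within the half-spindle that was
        pulled; the opposite half responds through sister coupling and
        whole-spindle geometry, not through the local crosslink network.
        A structure belongs to the needle's half when its undeformed
        centroid lies on the needle-proximal-pole side of the equator.
        """
        if self.needle is None:
            return self
        p1, p2 = frame0.require_poles()
        center = 0.5 * (p1 + p2)
        axis = p2 - p1
        near_pole_sign = np.sign(float((np.asarray(self.needle) - center) @ axis))
        keep_ids = []
        for sid, grp in self.pairs.groupby("structure_id", sort=False):
            centroid = grp[["x0", "y0"]].to_numpy().mean(axis=0)
            side = float((centroid - center) @ axis)
            if np.sign(side) == near_pole_sign or sid in ("pole1", "pole2"):
                if sid.startswith("pole") and np.sign(side) != near_pole_sign:
                    continue
                keep_ids.append(sid)
        sub = self.pairs[self.pairs["structure_id"].isin(keep_ids)].reset_index(drop=True)
        return StrainMap(pairs=sub, transform=self.transform, needle=self.needle,
                         cell_id=self.cell_id)


@dataclass
class DecayFit:
    """Exponential decay fit D = A * exp(-lambda * d)."""

    amplitude: float
    decay_constant: float
    residual_norm: float
    n_points: int


def build_strain_map(
    frame0: SpindleFrame,
    frame1: SpindleFrame,
    needle_pos: np.ndarray | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> StrainMap:
    """Match frame0 (undeformed) to frame1 (deformed) point-by-point.

    Both frames are rigid-aligned first, using as anchors the pole
    centroids plus every matched fiber point farther than
    ``rigid_exclusion_radius_um`` from the needle tip: the deformation is
    local, so distal structure approximates a rigid reference.  Each fiber
    is resampled to ``resample_points`` equally spaced coordinates in both
    frames and pair i connects index i to index i.  Structures present in
    only one frame are excluded with a warning, as are fibers whose length
    changed by more than 10% (which violates the linear-mapping premise).
    """
    if needle_pos is None:
        needle_pos = frame1.needle
    common = [sid for sid in frame0.fibers if sid in frame1.fibers]
    only = set(frame0.fibers) ^ set(frame1.fibers)
    if only:
        warnings.warn(f"structures present in only one frame, excluded: {sorted(only)}")
    if not common and frame0.pole1 is None:
        raise ValueError("no common structures between the two frames")

    rows_id: list[tuple[str, int]] = []
    fixed_pts: list[np.ndarray] = []
    moving_pts: list[np.ndarray] = []
    anchor: list[bool] = []

    for name, p0, p1 in (
        ("pole1", frame0.pole1, frame1.pole1),
        ("pole2", frame0.pole2, frame1.pole2),
    ):
        if p0 is not None and p1 is not None:
            rows_id.append((name, 0))
            fixed_pts.append(np.asarray(p0, dtype=float))
            moving_pts.append(np.asarray(p1, dtype=float))
            anchor.append(True)

    for sid in common:
        f0, f1 = frame0.fibers[sid], frame1.fibers[sid]
        L0, L1 = polyline_length(f0.points), polyline_length(f1.points)
        if abs(L1 - L0) > 0.10 * L0:
            warnings.warn(
                f"fiber {sid!r} length changed by more than 10% "
                f"({L0:.2f} -> {L1:.2f} um); linear point mapping is suspect"
            )
        r0 = resample_arclength(f0.points, config.resample_points)
        r1 = resample_arclength(f1.points, config.resample_points)
        for i in range(config.resample_points):
            rows_id.append((sid, i))
            fixed_pts.append(r0[i])
            moving_pts.append(r1[i])
            if needle_pos is None:
                anchor.append(True)
            else:
                # symmetric in the two frames, so that swapping the roles of
                # undeformed and deformed frames yields the inverse transform
                far0 = float(np.linalg.norm(r0[i] - needle_pos))
                far1 = float(np.linalg.norm(r1[i] - needle_pos))
                anchor.append(
                    min(far0, far1) > config.rigid_exclusion_radius_um
                )

    fixed = np.asarray(fixed_pts)
    moving = np.asarray(moving_pts)
    mask = np.asarray(anchor, dtype=bool)
    if mask.sum() < 2:  # fall back to all points rather than fail outright
        mask = np.ones(len(fixed), dtype=bool)
    tf, aligned = rigid_align(moving, fixed, mask)
    needle_aligned = tf.apply(needle_pos) if needle_pos is not None else None

    D = np.linalg.norm(aligned - fixed, axis=1)
    if needle_aligned is not None:
        d = np.linalg.norm(aligned - needle_aligned, axis=1)
    else:
        d = np.full(len(D), np.nan)
    pairs = pd.DataFrame(
        {
            "structure_id": [sid for sid, _ in rows_id],
            "point_index": [i for _, i in rows_id],
            "x0": fixed[:, 0],
            "y0": fixed[:, 1],
            "x1": aligned[:, 0],
            "y1": aligned[:, 1],
            "D": D,
            "d": d,
        }
    )
    return StrainMap(pairs=pairs, transform=tf, needle=needle_aligned)


def deformation_vs_distance(maps, bin_width: float = 1.0) -> pd.DataFrame:
    """Bin displacement magnitude by distance from the needle.

    Returns a table of (d_bin center, mean D, SEM, n); empty bins are
    omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(maps, StrainMap):
        maps = [maps]
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one strain map")
    d = np.concatenate([m.d for m in maps])
    D = np.concatenate([m.D for m in maps])
    ok = np.isfinite(d)
    d, D = d[ok], D[ok]
    if len(d) == 0:
        raise ValueError("no needle distances available (no needle traced?)")
    idx = np.floor(d / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        vals = D[idx == b]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "d_center": (b + 0.5) * bin_width,
                "mean_D": float(vals.mean()),
                "sem_D": sem,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def fit_exponential_decay(d, D) -> DecayFit:
    """Nonlinear least squares of D = A * exp(-lambda * d), A, lambda >= 0."""
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    if d.shape != D.shape or d.ndim != 1:
        raise ValueError("d and D must be 1-D arrays of equal length")
    if len(d) < 3:
        raise ValueError("need at least 3 points for the decay fit")
    if np.all(D == 0):
        raise ValueError("degenerate: all deformations are zero")

    A0 = float(D.max())
    pos = D > 0
    if pos.sum() >= 2 and np.ptp(d[pos]) > 0:
        slope = np.polyfit(d[pos], np.log(D[pos]), 1)[0]
        lam0 = max(-slope, 0.0)
    else:
        lam0 = 0.1

    def model(x, A, lam):
        return A * np.exp(-lam * x)

    try:
        popt, _ = curve_fit(
            model,
            d,
            D,
            p0=[A0, lam0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(
            f"exponential decay fit did not converge (p0=A{A0:.3g}, lam{lam0:.3g}): {err}"
        ) from err
    resid = D - model(d, *popt)
    return DecayFit(
        amplitude=float(popt[0]),
        decay_constant=float(popt[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=int(len(d)),
    )
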