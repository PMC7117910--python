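"""Scalar spindle geometry and intensity metrics.

Inter-kinetochore distance (between sister fiber plus-ends), pole-pole
distance (between pole centroids), angles of fiber plus-end regions to the
pole-pole axis and between sisters, intensity-ratio profiles along the
pole-pole axis with a half-max enrichment span, and paired correlation
(Pearson + Spearman + least-squares line).

Angle measurements use a least-squares line through the plus-end-proximal
``region_um`` of fiber points rather than an endpoint chord, to damp
tracing noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig, DEFAULT_CONFIG
from .geometry import cumulative_arclength, resample_arclength
from .scene import SpindleFrame

__all__ = [
    "interkinetochore_distance",
    "pole_pole_distance",
    "sister_angle_to_axis",
    "inter_sister_angle",
    "metrics_record",
    "intensity_ratio_profile",
    "enrichment_span",
    "paired_correlation",
    "CorrelationResult",
]


def interkinetochore_distance(frame: SpindleFrame, pair_id: str) -> float:
    """Euclidean distance between sister fiber plus-ends (um)."""
    fa, fb = frame.sister_fibers(pair_id)
    return float(np.linalg.norm(fa.plus_end - fb.plus_end))


def pole_pole_distance(frame: SpindleFrame) -> float:
    """Euclidean distance between the two pole centroids (um)."""
    p1, p2 = frame.require_poles()
    return float(np.linalg.norm(p1 - p2))


def _plus_end_direction(points: np.ndarray, region_um: float) -> np.ndarray:
    """Unit direction of the least-squares line through the plus-end region.

    Oriented away from the plus-end (toward the fiber interior/pole).
    The line is the first principal axis of the region points, so steep or
    vertical regions are handled identically to shallow ones.
    """
    s = cumulative_arclength(points)
    sel = points[s <= region_um + 1e-12]
    if len(sel) < 2:
        raise ValueError("plus-end region shorter than 2 points; increase region_um")
    centered = sel - sel.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    # orient from the plus-end toward the far end of the region
    if d @ (sel[-1] - sel[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def sister_angle_to_axis(
    frame: SpindleFrame,
    fiber_id: str,
    region_um: float = 3.0,
    config: RunConfig = DEFAULT_CONFIG,
) -> float:
    """Angle (degrees, folded to [0, 90]) between a fiber's plus-end region
    and the pole-pole axis."""
    p1, p2 = frame.require_poles()
    axis = p2 - p1
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("pole centroids coincide; axis undefined")
    axis = axis / nrm
    fiber = frame.fibers[fiber_id]
    pts = resample_arclength(fiber.points, config.resample_points)
    d = _plus_end_direction(pts, region_um)
    cosang = np.clip(abs(float(d @ axis)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def inter_sister_angle(
    frame: SpindleFrame,
    pair_id: str,
    region_um: float = 3.0,
    config: RunConfig = DEFAULT_CONFIG,
) -> float:
    """Angle (degrees, in [0, 180]) between sister plus-end-region directions.

    Each direction points outward from the shared chromosome toward its own
    pole, so collinear sisters pointing at opposite poles give 180 deg and
    parallel same-direction regions give 0.  The exact value 180 is
    returned as such; callers binning into [0, 180) should treat it as the
    top edge.
    """
    fa, fb = frame.sister_fibers(pair_id)
    da = _plus_end_direction(resample_arclength(fa.points, config.resample_points), region_um)
    db = _plus_end_direction(resample_arclength(fb.points, config.resample_points), region_um)
    cosang = np.clip(float(da @ db), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def metrics_record(
    frame: SpindleFrame,
    pair_id: str,
    region_um: float = 3.0,
    config: RunConfig = DEFAULT_CONFIG,
) -> dict:
    """All per-frame scalar metrics for one sister pair."""
    fa, fb = frame.sister_fibers(pair_id)
    from .geometry import polyline_length

    return {
        "t": frame.time_s,
        "interkt_um": interkinetochore_distance(frame, pair_id),
        "pole_pole_um": pole_pole_distance(frame),
        "sister_angle_deg": sister_angle_to_axis(frame, fb.structure_id, region_um, config),
        "inter_sister_angle_deg": inter_sister_angle(frame, pair_id, region_um, config),
        "kfiber_length_um": polyline_length(fa.points),
    }


# ---------------------------------------------------------------------------
# Intensity profiles


def intensity_ratio_profile(numerator, denominator, axis_length_um: float) -> pd.DataFrame:
    """Pointwise ratio of two linescans along the pole-pole axis.

    Returns a table of normalized axis position u in [0, 1], position in
    um, and the ratio.  The denominator must be strictly positive.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("linescans must be 1-D arrays of equal length")
    if np.any(den <= 0):
        raise ValueError("denominator linescan must be strictly positive")
    u = np.linspace(0.0, 1.0, len(num))
    return pd.DataFrame({"u": u, "position_um": u * axis_length_um, "ratio": num / den})


def enrichment_span(
    profile: pd.DataFrame,
    axis_length_um: float,
    flank_fraction: float = 0.2,
) -> float:
    """Width (um) of the central region enriched above half-maximum.

    Baseline is the mean ratio over the outer ``flank_fraction`` of the
    axis on each side; the peak is the profile maximum.  The span is the
    width of the contiguous region around the peak where the ratio exceeds
    baseline + (peak - baseline)/2, with sub-sample edges found by linear
    interpolation.  A flat profile (no peak above baseline) has span 0.
    """
    u = profile["u"].to_numpy()
    r = profile["ratio"].to_numpy()
    n = len(r)
    k = max(1, int(round(flank_fraction * n)))
    baseline = float(np.concatenate([r[:k], r[-k:]]).mean())
    i_pk = int(np.argmax(r))
    peak = float(r[i_pk])
    if peak <= baseline:
        return 0.0
    level = baseline + 0.5 * (peak - baseline)
    # walk outward from the peak to the crossings
    left = u[0]
    for i in range(i_pk, 0, -1):
        if r[i - 1] <= level:
            frac = (r[i] - level) / (r[i] - r[i - 1])
            left = u[i] - frac * (u[i] - u[i - 1])
            break
    right = u[-1]
    for i in range(i_pk, n - 1):
        if r[i + 1] <= level:
            frac = (r[i] - level) / (r[i] - r[i + 1])
            right = u[i] + frac * (u[i + 1] - u[i])
            break
    return float((right - left) * axis_length_um)


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def paired_correlation(x, y) -> CorrelationResult:
    """Pearson and Spearman correlation plus the least-squares line.

    The Spearman p-value is exact (full permutation null) for n <= 8,
    where the t-approximation is unreliable; the approximation is used for
    larger samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    spearman_p = float(sr.pvalue)
    if len(x) <= 8:
        from itertools import permutations

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = total = 0
        for perm in permutations(range(len(x))):
            if abs(np.corrcoef(rx, ry[list(perm)])[0, 1]) >= rho_obs - 1e-12:
                count += 1
            total += 1
        spearman_p = count / total
    lin = sps.linregress(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=spearman_p,
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        r_squared=float(lin.rvalue**2),
        n=len(x),
    )
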