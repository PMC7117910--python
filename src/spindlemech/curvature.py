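"""Signed curvature profiles along manipulated k-fibers.

Curvature at arc position s is the inverse radius of the circle through
the three fiber points spanning the measurement window w (at s - w/2, s,
s + w/2; w = 1 um by default), signed so the bend at the microneedle is
positive and the chromosome-proximal reverse bend negative.  The window
is the only smoother: it sets the length scale on which curvature is
measured, and the outer chord of the triplet bounds |kappa| by 2/w.

From each profile we locate the global extrema (positive peak near the
needle, negative trough), classify troughs below the detection threshold
as chromosome-proximal or pole-proximal, time the disappearance of the
trough during manipulate-and-hold experiments, and match microneedle
positions between experimental groups before comparing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import RunConfig, DEFAULT_CONFIG
from .geometry import (
    as_polyline,
    cumulative_arclength,
    point_at_arclength,
    resample_arclength,
    circumcircle_signed_curvature,
)
from .stats import mann_whitney_u

__all__ = [
    "CurvatureProfile",
    "CurvatureExtrema",
    "HoldResult",
    "MatchResult",
    "compute_curvature_profile",
    "locate_extrema",
    "classify_negative_curvature",
    "hold_lifetime",
    "match_needle_positions",
]


@dataclass
class CurvatureProfile:
    """Signed curvature sampled along one fiber.

    ``s`` is arc length from the plus-end (um), ``u = s / length`` the
    normalized position; curvature is defined only for
    s in [window, length - window].
    """

    s: np.ndarray
    u: np.ndarray
    kappa: np.ndarray
    window: float
    length: float
    s_needle: float | None = None
    time_s: float | None = None

    @property
    def u_needle(self) -> float | None:
        return None if self.s_needle is None else self.s_needle / self.length


@dataclass
class CurvatureExtrema:
    """Global curvature extrema of one profile and their positions."""

    s_max: float
    kappa_max: float
    s_min: float
    kappa_min: float
    length: float
    s_needle: float | None = None

    @property
    def min_from_plus_end(self) -> float:
        return self.s_min

    @property
    def max_from_plus_end(self) -> float:
        return self.s_max

    @property
    def min_from_needle(self) -> float | None:
        return None if self.s_needle is None else abs(self.s_min - self.s_needle)

    @property
    def max_from_needle(self) -> float | None:
        return None if self.s_needle is None else abs(self.s_max - self.s_needle)

    @property
    def u_needle(self) -> float | None:
        return None if self.s_needle is None else self.s_needle / self.length


@dataclass
class HoldResult:
    """Trough curvature versus time held, and the detected lifetime."""

    times_s: np.ndarray  # time since hold start
    kappa_min: np.ndarray
    lifetime_s: float | None
    censored: bool
    window: tuple[float, float]


def _default_normal_ref(fiber: np.ndarray, needle: np.ndarray | None) -> np.ndarray:
    """Sign reference: direction in which the fiber is displaced at the needle.

    Taken as the perpendicular deviation, at the needle-proximal point, of
    the fiber from its end-to-end chord.  This makes the bend at the needle
    positive by construction.  Falls back to the leftward chord normal for
    a needle-free or perfectly straight fiber.
    """
    chord = fiber[-1] - fiber[0]
    nrm = np.linalg.norm(chord)
    that = chord / nrm
    left = np.array([-that[1], that[0]])
    if needle is None:
        return left
    d2 = np.linalg.norm(fiber - np.asarray(needle, dtype=float), axis=1)
    p = fiber[int(np.argmin(d2))]
    dev = p - fiber[0]
    dev = dev - (dev @ that) * that
    if np.linalg.norm(dev) < 1e-9:
        return left
    return dev / np.linalg.norm(dev)


def compute_curvature_profile(
    fiber: np.ndarray,
    needle: np.ndarray | None = None,
    config: RunConfig = DEFAULT_CONFIG,
    normal_ref: np.ndarray | None = None,
    time_s: float | None = None,
) -> CurvatureProfile:
    """Signed curvature at every resampled position s in [w, L - w].

    The fiber (plus-end first) is resampled to ``config.resample_points``
    equally spaced coordinates; at each stored position the circle through
    the interpolated points at s - w/2, s, s + w/2 (a triplet spanning the
    window w) gives the curvature magnitude, with the manipulation-fixed
    sign reference (``normal_ref``, derived from the needle-proximal bow
    direction when not supplied).  The profile is trimmed a full window
    from either end, where the triplet would leave the fiber.
    """
    w = config.curvature_window_um
    h = w / 2.0
    fiber = as_polyline(fiber)
    r = resample_arclength(fiber, config.resample_points)
    s_all = cumulative_arclength(r)
    L = float(s_all[-1])
    if L <= 2 * w:
        raise ValueError(f"fiber too short for window: length {L:.2f} <= 2*{w}")
    if normal_ref is None:
        normal_ref = _default_normal_ref(r, needle)
    normal_ref = np.asarray(normal_ref, dtype=float)
    keep = (s_all >= w - 1e-12) & (s_all <= L - w + 1e-12)
    s = s_all[keep]
    p_minus = point_at_arclength(r, np.clip(s - h, 0.0, L))
    p_mid = point_at_arclength(r, s)
    p_plus = point_at_arclength(r, np.clip(s + h, 0.0, L))
    kappa = np.array(
        [
            circumcircle_signed_curvature(a, b, c, normal_ref)
            for a, b, c in zip(p_minus, p_mid, p_plus)
        ]
    )
    s_needle = None
    if needle is not None:
        d2 = np.linalg.norm(r - np.asarray(needle, dtype=float), axis=1)
        s_needle = float(s_all[int(np.argmin(d2))])
    return CurvatureProfile(
        s=s, u=s / L, kappa=kappa, window=w, length=L, s_needle=s_needle, time_s=time_s
    )


def locate_extrema(
    profile: CurvatureProfile,
    region: tuple[float, float] | None = None,
) -> CurvatureExtrema:
    """Global maximum and minimum of kappa(s); ties break toward the plus-end.

    ``np.argmax``/``argmin`` return the first occurrence and s increases
    from the plus-end, so ties resolve plus-end-proximal deterministically.
    A flat zero profile yields both extrema 0 at the plus-proximal end of
    the defined range.  ``region`` optionally restricts the search to an
    arc-length interval (e.g. the chromosome side of the needle).
    """
    s, kappa = profile.s, profile.kappa
    if region is not None:
        sel = (s >= region[0]) & (s <= region[1])
        if not np.any(sel):
            raise ValueError("no profile samples inside the requested region")
        s, kappa = s[sel], kappa[sel]
    i_max = int(np.argmax(kappa))
    i_min = int(np.argmin(kappa))
    return CurvatureExtrema(
        s_max=float(s[i_max]),
        kappa_max=float(kappa[i_max]),
        s_min=float(s[i_min]),
        kappa_min=float(kappa[i_min]),
        length=profile.length,
        s_needle=profile.s_needle,
    )


def classify_negative_curvature(
    ex: CurvatureExtrema,
    length: float | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Classify the negative trough: chromosome_proximal, pole_proximal, none.

    A trough counts only if kappa_min is below ``negative_threshold``;
    its position decides the class: within ``proximal_fraction * L`` of the
    plus-end -> chromosome_proximal; within the same fraction of the pole
    end -> pole_proximal; mid-fiber troughs are not classified (none).
    """
    L = float(length if length is not None else ex.length)
    if ex.kappa_min >= config.negative_threshold:
        return "none"
    if ex.s_min <= config.proximal_fraction * L:
        return "chromosome_proximal"
    if ex.s_min >= (1.0 - config.proximal_fraction) * L:
        return "pole_proximal"
    return "none"


def hold_lifetime(
    profiles: list[CurvatureProfile],
    hold_start: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> HoldResult:
    """Time for the chromosome-proximal negative curvature to disappear.

    The tracking window is fixed from the last pre-hold profile: the
    position of its most negative curvature within the chromosome-proximal
    region, padded by ``track_halfwidth_um``.  In every held frame the
    minimum curvature inside that window is recorded; the lifetime T is the
    first time since hold start at which the minimum is at or above the
    detection threshold and stays there for every later frame
    (single-frame dips back below the threshold are ignored as noise).
    If the trough never disappears the result is censored at the last
    frame.
    """
    profiles = sorted(profiles, key=lambda p: (p.time_s if p.time_s is not None else 0.0))
    times = np.array([p.time_s for p in profiles], dtype=float)
    if np.any(np.isnan(times)):
        raise ValueError("all profiles need a frame time for lifetime detection")
    if np.any(np.diff(times) <= 0):
        raise ValueError("profile times must be strictly increasing")
    pre = [p for p in profiles if p.time_s < hold_start]
    post = [p for p in profiles if p.time_s >= hold_start]
    if not pre:
        raise ValueError("no pre-hold frame to fix the tracking window")
    if len(post) < 2:
        raise ValueError("need at least 2 frames after hold start")

    ref = pre[-1]
    prox = ref.s <= config.proximal_fraction * ref.length
    if not np.any(prox):
        raise ValueError("no chromosome-proximal samples in the reference profile")
    k_prox = np.where(prox, ref.kappa, np.inf)
    i0 = int(np.argmin(k_prox))
    if ref.kappa[i0] >= config.negative_threshold:
        raise ValueError("nothing to track: no pre-hold negative curvature")
    s0 = float(ref.s[i0])
    lo = max(ref.s[0], s0 - config.track_halfwidth_um)
    hi = min(ref.s[-1], s0 + config.track_halfwidth_um)

    t_rel, kmins = [], []
    for p in post:
        sel = (p.s >= lo) & (p.s <= hi)
        if not np.any(sel):
            sel = slice(None)
        t_rel.append(p.time_s - hold_start)
        kmins.append(float(np.min(p.kappa[sel])))
    t_rel = np.array(t_rel)
    kmins = np.array(kmins)

    above = kmins >= config.negative_threshold
    # forgive single-frame flickers back below threshold
    for j in range(1, len(above) - 1):
        if not above[j] and above[j - 1] and above[j + 1]:
            above[j] = True
    lifetime: float | None = None
    for i in range(len(above)):
        if above[i:].all():
            lifetime = float(t_rel[i])
            break
    return HoldResult(
        times_s=t_rel,
        kappa_min=kmins,
        lifetime_s=lifetime,
        censored=lifetime is None,
        window=(lo, hi),
    )


@dataclass
class MatchResult:
    """Minimal down-sampling of two groups to overlapping needle positions."""

    keep_a: np.ndarray
    keep_b: np.ndarray
    p_value: float
    u_range: tuple[float, float]


def match_needle_positions(u_a, u_b) -> MatchResult:
    """Trim both groups to the intersection of their needle-position ranges.

    Removes the fewest records such that both groups' normalized needle
    positions span the same interval, then reports the two-sided
    Mann-Whitney p-value on the retained positions (a warning is issued if
    the distributions still differ at p <= 0.05).
    """
    u_a = np.asarray(u_a, dtype=float)
    u_b = np.asarray(u_b, dtype=float)
    if len(u_a) == 0 or len(u_b) == 0:
        raise ValueError("both groups must be non-empty")
    lo = max(u_a.min(), u_b.min())
    hi = min(u_a.max(), u_b.max())
    if lo > hi:
        raise ValueError("no overlap between the needle-position ranges")
    keep_a = (u_a >= lo) & (u_a <= hi)
    keep_b = (u_b >= lo) & (u_b <= hi)
    res = mann_whitney_u(u_a[keep_a], u_b[keep_b])
    if res.p_value <= 0.05:
        warnings.warn(
            f"needle-position distributions still differ after trimming "
            f"(p = {res.p_value:.3g})"
        )
    return MatchResult(keep_a=keep_a, keep_b=keep_b, p_value=res.p_value, u_range=(lo, hi))
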