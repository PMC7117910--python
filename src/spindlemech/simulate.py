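"""Synthetic microneedle-manipulation experiments on an elastic-rod spindle.

The manipulated k-fiber is a discrete inextensible elastic rod: bending
energy penalizes deviation from the rest (intrinsic) shape, each node is
tethered to its rest position by a crosslink spring representing anchorage
to the background non-kinetochore-microtubule network, the pole end is
hinged (position fixed, free to pivot), and the plus-end is tethered to
the kinetochore by a spring.  The crosslink stiffness profile realizes the
two anchorage hypotheses: uniform along the fiber (model 1) versus a
chromosome-proximal enhancement over the first few micrometres from the
plus-end (model 2).  Holding the needle lets the enhancement decay
exponentially with the crosslink turnover lifetime tau.

A full scene embeds the rod in a bipolar spindle with sister and neighbor
fibers, applies the needle ramp protocols used experimentally
(~1.8 um over ~12 s, ~2.5 um over ~60 s, or ramp-and-hold), adds
whole-spindle rigid jitter between frames and smooth correlated tracing
noise, and emits trace tables in the same dialect the I/O layer reads.
All randomness flows from one recorded seed; reruns are bit-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import cumulative_arclength, resample_arclength
from .scene import FiberTrace, SpindleFrame, ManipulationSeries

__all__ = [
    "RodModel",
    "Protocol",
    "SceneParams",
    "GroundTruth",
    "make_rod",
    "degrade_reinforcement",
    "simulate_rod_equilibrium",
    "generate_manipulation_series",
    "series_to_trace_table",
    "render_frame",
    "needle_step_program",
]

# Default mechanical parameters (see docs/methods.md for the calibration
# rationale).  Only shape-level quantities are meaningful; absolute forces
# are not calibrated.
DEFAULT_B = 500.0          # pN*um^2 bending stiffness of the rod
DEFAULT_KC_UNIFORM = 75.0  # pN/um^2 uniform anchorage density (model 1)
DEFAULT_KC_BASE = 18.0     # pN/um^2 background anchorage density (model 2)
DEFAULT_K_ENH = 300.0      # pN/um^2 chromosome-proximal enhancement (model 2)
DEFAULT_S_ENH = 3.0        # um extent of the enhancement from the plus-end
DEFAULT_K_KT = 50.0        # pN/um plus-end tether to the kinetochore
DEFAULT_STRETCH_K = 5.0e4  # pN inextensibility penalty stiffness


@dataclass
class RodModel:
    """Discretized elastic k-fiber with a spatial crosslink-stiffness profile.

    ``rest`` is the intrinsic shape, plus-end first.  ``kc_base`` and
    ``k_enh`` are stiffness *densities* (pN/um per um of fiber); the
    enhancement acts over arc positions [0, s_enh] from the plus-end.
    Model 1 <=> k_enh == 0; model 2 <=> k_enh > 0.
    """

    rest: np.ndarray
    bending_B: float = DEFAULT_B
    kc_base: float = DEFAULT_KC_BASE
    k_enh: float = DEFAULT_K_ENH
    s_enh: float = DEFAULT_S_ENH
    k_kt: float = DEFAULT_K_KT
    kt_pos: np.ndarray | None = None
    stretch_k: float = DEFAULT_STRETCH_K
    # crosslinks resist lateral separation strongly and axial sliding with
    # half that stiffness (crosslinker friction); the axial component also
    # removes the zero-cost mode of sliding the rod bodily along its own
    # axis
    axial_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.rest = np.asarray(self.rest, dtype=float)
        if self.rest.ndim != 2 or self.rest.shape[1] != 2 or len(self.rest) < 50:
            raise ValueError("rod needs an (n>=50, 2) rest shape")
        for name in ("bending_B", "kc_base", "k_enh", "k_kt", "stretch_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kt_pos is None:
            self.kt_pos = self.rest[0].copy()
        else:
            self.kt_pos = np.asarray(self.kt_pos, dtype=float)

    @property
    def n(self) -> int:
        return len(self.rest)

    @property
    def s(self) -> np.ndarray:
        return cumulative_arclength(self.rest)

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def seg_rest(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.rest, axis=0), axis=1)

    @property
    def node_weights(self) -> np.ndarray:
        """Arc-length weight of each node (trapezoidal)."""
        seg = self.seg_rest
        w = np.zeros(self.n)
        w[:-1] += seg / 2
        w[1:] += seg / 2
        return w

    @property
    def kc_nodes(self) -> np.ndarray:
        """Crosslink spring constant per node (pN/um)."""
        dens = np.full(self.n, self.kc_base)
        dens[self.s <= self.s_enh + 1e-12] += self.k_enh
        return dens * self.node_weights

    @property
    def rest_angles(self) -> np.ndarray:
        e = np.diff(self.rest, axis=0)
        return _turn_angles(e)

    @property
    def rest_normals(self) -> np.ndarray:
        """Unit normal to the rest tangent at every node.

        Crosslink springs act along these normals only: the background
        network resists lateral separation of the fiber but not sliding
        along its own axis.
        """
        t = np.zeros_like(self.rest)
        t[1:-1] = self.rest[2:] - self.rest[:-2]
        t[0] = self.rest[1] - self.rest[0]
        t[-1] = self.rest[-1] - self.rest[-2]
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return np.column_stack([-t[:, 1], t[:, 0]])


def make_rod(
    length: float = 10.0,
    n_nodes: int = 51,
    model: int = 2,
    bending_B: float = DEFAULT_B,
    kc_base: float | None = None,
    k_enh: float | None = None,
    s_enh: float = DEFAULT_S_ENH,
    k_kt: float = DEFAULT_K_KT,
    sagitta: float = 0.0,
    start: tuple[float, float] = (0.0, 0.0),
    direction_deg: float = 0.0,
) -> RodModel:
    """Build a straight or shallow-arc rod of the requested anchorage model."""
    if model not in (1, 2):
        raise ValueError("model must be 1 (uniform) or 2 (chromosome-proximal)")
    if kc_base is None:
        kc_base = DEFAULT_KC_UNIFORM if model == 1 else DEFAULT_KC_BASE
    if k_enh is None:
        k_enh = 0.0 if model == 1 else DEFAULT_K_ENH
    if model == 1 and k_enh != 0.0:
        raise ValueError("model 1 is uniform anchorage (k_enh must be 0)")
    t = np.linspace(0.0, 1.0, n_nodes)
    th = math.radians(direction_deg)
    axis = np.array([math.cos(th), math.sin(th)])
    perp = np.array([-axis[1], axis[0]])
    pts = (
        np.asarray(start, dtype=float)
        + np.outer(t * length, axis)
        + np.outer(sagitta * np.sin(np.pi * t), perp)
    )
    pts = resample_arclength(pts, n_nodes)
    return RodModel(
        rest=pts,
        bending_B=bending_B,
        kc_base=kc_base,
        k_enh=k_enh,
        s_enh=s_enh,
        k_kt=k_kt,
    )


def degrade_reinforcement(model: RodModel, t_since_hold: float, tau: float) -> RodModel:
    """Crosslink turnover: scale the enhancement by exp(-t/tau).

    The background anchorage is unchanged; as t -> inf the rod tends to
    model 1.
    """
    if tau <= 0:
        raise ValueError("turnover lifetime tau must be > 0")
    if t_since_hold < 0:
        raise ValueError("time since hold start must be >= 0")
    return replace(model, k_enh=model.k_enh * math.exp(-t_since_hold / tau))


# ---------------------------------------------------------------------------
# Energy and equilibrium


def _turn_angles(e: np.ndarray) -> np.ndarray:
    """Signed turning angle at each interior joint of a segment chain."""
    e1, e2 = e[:-1], e[1:]
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    dot = (e1 * e2).sum(axis=1)
    return np.arctan2(cross, dot)


def rod_energy_gradient(x: np.ndarray, model: RodModel) -> tuple[float, np.ndarray]:
    """Total elastic energy (pN*um) and its gradient (pN) at configuration x.

    E = sum (B/ds) (1 - cos(theta_i - theta_i0))        bending vs intrinsic shape
      + sum ks/(2 ds_i) (|e_i| - ds_i)^2                 inextensibility penalty
      + sum kc_i/2 (n_i0 . (x_i - x_i0))^2               lateral crosslinks to rest
      + k_kt/2 |x_plus - x_kt|^2                         kinetochore tether
    """
    x = x.reshape(-1, 2)
    g = np.zeros_like(x)
    e = np.diff(x, axis=0)
    seg = np.linalg.norm(e, axis=1)
    rest_seg = model.seg_rest
    ds = float(rest_seg.mean())

    # bending (intrinsic turning angles from the rest shape)
    theta = _turn_angles(e)
    dtheta = theta - model.rest_angles
    coef = model.bending_B / ds
    E = coef * float((1.0 - np.cos(dtheta)).sum())
    tension = coef * np.sin(dtheta)  # dE/dtheta per joint
    e1, e2 = e[:-1], e[1:]
    denom = (seg[:-1] * seg[1:]) ** 2  # |e1|^2 |e2|^2 = c^2 + d^2
    c = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    d = (e1 * e2).sum(axis=1)
    perp_e2 = np.column_stack([e2[:, 1], -e2[:, 0]])   # d(cross)/d(e1)
    perp_e1 = np.column_stack([-e1[:, 1], e1[:, 0]])   # d(cross)/d(e2)
    dth_de1 = (d[:, None] * perp_e2 - c[:, None] * e2) / denom[:, None]
    dth_de2 = (d[:, None] * perp_e1 - c[:, None] * e1) / denom[:, None]
    g[:-2] -= tension[:, None] * dth_de1
    g[1:-1] += tension[:, None] * (dth_de1 - dth_de2)
    g[2:] += tension[:, None] * dth_de2

    # stretching penalty
    dev = seg - rest_seg
    E += float((model.stretch_k / (2.0 * rest_seg) * dev**2).sum())
    tgt = (model.stretch_k / rest_seg) * dev
    unit = e / seg[:, None]
    gs = tgt[:, None] * unit
    g[1:] += gs
    g[:-1] -= gs

    # crosslinks: anisotropic springs to the rest position — stiff against
    # lateral separation, weak against axial sliding
    kc = model.kc_nodes
    disp = x - model.rest
    nrm = model.rest_normals
    dlat = (disp * nrm).sum(axis=1)
    tng = np.column_stack([nrm[:, 1], -nrm[:, 0]])
    dax = (disp * tng).sum(axis=1)
    af = model.axial_fraction
    E += 0.5 * float((kc * (dlat**2 + af * dax**2)).sum())
    g += (kc * dlat)[:, None] * nrm + (kc * af * dax)[:, None] * tng

    # kinetochore tether at the plus-end
    dkt = x[0] - model.kt_pos
    E += 0.5 * model.k_kt * float(dkt @ dkt)
    g[0] += model.k_kt * dkt

    return E, g


def _damped_newton(fun, grad_only, v0, grad_tol, maxiter=60):
    """Damped Newton on the reduced coordinates.

    The Hessian couples each node only to its two neighbors on either side
    (half-bandwidth 5 in flattened coordinates), so the exact Hessian is
    assembled from 11 colored forward differences of the analytic gradient
    and factorized densely (the systems are ~100 x 100).  Levenberg damping
    plus backtracking guards the early steps.
    """
    v = v0.copy()
    E, g = fun(v)
    ndof = len(v)
    half_bw = 5
    stride = 2 * half_bw + 1
    mu = 0.0
    for _ in range(maxiter):
        gnorm = float(np.abs(g).max())
        if gnorm <= grad_tol:
            return v, gnorm
        eps = 1e-7 * max(1.0, float(np.abs(v).max()))
        H = np.zeros((ndof, ndof))
        for color in range(stride):
            cols = np.arange(color, ndof, stride)
            pert = np.zeros(ndof)
            pert[cols] = eps
            gp = grad_only(v + pert)
            dg = (gp - g) / eps
            for j in cols:
                lo, hi = max(0, j - half_bw), min(ndof, j + half_bw + 1)
                H[lo:hi, j] = dg[lo:hi]
        H = 0.5 * (H + H.T)
        step_ok = False
        for _try in range(8):
            try:
                delta = np.linalg.solve(
                    H + mu * np.eye(ndof) if mu else H, -g)
            except np.linalg.LinAlgError:
                mu = max(10 * mu, 1e-3)
                continue
            alpha = 1.0
            for _ls in range(6):
                E_new, g_new = fun(v + alpha * delta)
                if E_new <= E + 1e-12 * abs(E) + 1e-15:
                    v = v + alpha * delta
                    E, g = E_new, g_new
                    step_ok = True
                    break
                alpha *= 0.5
            if step_ok:
                mu *= 0.1
                break
            mu = max(10 * mu, 1e-3)
        if not step_ok:
            break
    return v, float(np.abs(g).max())


def simulate_rod_equilibrium(
    model: RodModel,
    needle_displacement: np.ndarray | None = None,
    s_needle: float | None = None,
    x0: np.ndarray | None = None,
    extra_fixed: dict[int, np.ndarray] | None = None,
    pin_plus_end: bool = False,
    free_pole_axial: bool = False,
    pole_axial_k: float = 20.0,
    grad_tol: float = 1.0e-4,
    maxiter: int = 20000,
) -> np.ndarray:
    """Minimum-energy configuration under a point constraint at the needle.

    The pole end (last node) is hinged: position fixed, free to pivot.  If a
    needle displacement is given, the ~1 um of fiber around arc position
    ``s_needle`` (the extent of the needle tip) is driven to its rest
    position plus the displacement *along the pull direction only*, by a
    stiff penalty: the needle acts as a frictionless peg of finite width,
    so the fiber is free to slide across it laterally, which is what keeps
    an inextensible rod geometrically feasible under micron-scale pulls.  Additional hard constraints can be passed via ``extra_fixed``
    (node index -> position) or ``pin_plus_end`` (both ends pinned, the
    three-point-bending configuration).  With ``free_pole_axial`` the pole
    end is instead held laterally but mounted on an axial spring
    (``pole_axial_k``), so chord shortening of the bowed fiber draws the
    pole inward — the spindle-shortening response.  Raises if the gradient
    norm on the free nodes does not drop below ``grad_tol`` (pN).
    """
    n = model.n
    fixed: dict[int, np.ndarray] = {}
    if not free_pole_axial:
        fixed[n - 1] = model.rest[-1].copy()
    if pin_plus_end:
        fixed[0] = model.rest[0].copy()
    pole_t = model.rest[-1] - model.rest[-2]
    pole_t = pole_t / np.linalg.norm(pole_t)
    pole_n = np.array([-pole_t[1], pole_t[0]])
    if extra_fixed:
        for idx, pos in extra_fixed.items():
            fixed[int(idx)] = np.asarray(pos, dtype=float)

    needle_nodes = None
    pull_dir = None
    pull_target = 0.0
    k_needle = 1.0e4        # pN/um, stiff one-dimensional peg constraint
    tip_width = 1.0         # um of fiber in contact with the (~1 um) tip
    if needle_displacement is not None:
        disp = np.asarray(needle_displacement, dtype=float)
        mag = float(np.linalg.norm(disp))
        if s_needle is None:
            s_needle = model.length / 2.0
        nodes = np.nonzero(np.abs(model.s - s_needle) <= tip_width / 2.0)[0]
        nodes = np.array([j for j in nodes if j not in fixed])
        if mag > 0 and len(nodes):
            needle_nodes = nodes
            pull_dir = disp / mag
            node0 = int(np.argmin(np.abs(model.s - s_needle)))
            pull_target = float((model.rest[node0] + disp) @ pull_dir)


    start = model.rest.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    for idx, pos in fixed.items():
        start[idx] = pos
    free = np.array([i for i in range(n) if i not in fixed])

    def pack(xfull):
        return xfull[free].ravel()

    def unpack(v):
        xfull = start.copy()
        xfull[free] = v.reshape(-1, 2)
        return xfull

    def fun(v):
        x = unpack(v)
        E, g = rod_energy_gradient(x, model)
        if needle_nodes is not None:
            kn = k_needle / len(needle_nodes)
            dev = x[needle_nodes] @ pull_dir - pull_target
            E += 0.5 * kn * float((dev**2).sum())
            g[needle_nodes] += kn * dev[:, None] * pull_dir
        if free_pole_axial:
            dp = x[n - 1] - model.rest[-1]
            lat = float(dp @ pole_n)
            ax = float(dp @ pole_t)
            E += 0.5 * 1.0e4 * lat**2 + 0.5 * pole_axial_k * ax**2
            g[n - 1] += 1.0e4 * lat * pole_n + pole_axial_k * ax * pole_t
        return E, g[free].ravel()

    def grad_only(v):
        return fun(v)[1]

    # short quasi-Newton leg to approach the basin, then damped Newton with
    # the exact (banded) Hessian assembled by colored finite differences of
    # the analytic gradient — the stiff stretching penalty makes the energy
    # too ill-conditioned for first-order methods to finish efficiently
    res = minimize(
        fun,
        pack(start),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 150, "maxfun": 2000,
                 "ftol": 1e-16, "gtol": 0.5 * grad_tol},
    )
    v = res.x
    gnorm = float(np.abs(res.jac).max()) if len(free) else 0.0
    if gnorm > grad_tol and len(free):
        v, gnorm = _damped_newton(fun, grad_only, v, grad_tol)
    x = unpack(v)
    if gnorm > grad_tol:
        E, _ = rod_energy_gradient(x, model)
        raise RuntimeError(
            f"rod equilibrium did not converge: |grad|_inf = {gnorm:.3e} pN "
            f"(> {grad_tol:.1e}), E = {E:.6g} pN*um"
        )
    seg = np.linalg.norm(np.diff(x, axis=0), axis=1)
    strain = np.abs(seg / model.seg_rest - 1.0).max()
    if strain > 0.005:
        warnings.warn(f"segment strain {strain:.2%} exceeds 0.5%; stiffen stretch_k")
    return x


# ---------------------------------------------------------------------------
# Protocols and scenes


@dataclass(frozen=True)
class Protocol:
    """Needle motion program: linear ramp, optional stationary hold."""

    kind: str  # pull12 | pull60 | pull_hold | none
    pull_um: float
    pull_s: float
    hold_s: float = 0.0
    u_needle: float = 0.5
    direction: tuple[float, float] = (0.0, 1.0)
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("pull12", "pull60", "pull_hold", "none"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind != "none":
            if self.pull_um <= 0 or self.pull_s <= 0:
                raise ValueError("pull distance and duration must be > 0")
            if self.frame_interval_s > self.pull_s:
                raise ValueError("frame interval exceeds the pull duration")
        if self.kind == "pull_hold" and self.hold_s <= 0:
            raise ValueError("pull_hold needs hold duration > 0")
        if not (0.0 < self.u_needle < 1.0):
            raise ValueError("u_needle must be inside (0, 1)")

    @property
    def total_s(self) -> float:
        return self.pull_s + self.hold_s

    def displacement_at(self, t: float) -> float:
        if self.kind == "none":
            return 0.0
        return self.pull_um * min(max(t, 0.0) / self.pull_s, 1.0)

    # the two manipulation datasets emulated throughout: a fast short pull
    # and a slower, larger one, plus the ramp-and-hold variant
    @classmethod
    def pull12(cls, u_needle: float = 0.5) -> "Protocol":
        return cls("pull12", 1.8, 12.0, 0.0, u_needle, frame_interval_s=1.0)

    @classmethod
    def pull60(cls, u_needle: float = 0.5) -> "Protocol":
        return cls("pull60", 2.5, 60.0, 0.0, u_needle, frame_interval_s=5.0)

    @classmethod
    def pull_hold(cls, hold_s: float = 60.0, u_needle: float = 0.5) -> "Protocol":
        return cls("pull_hold", 2.5, 60.0, hold_s, u_needle, frame_interval_s=3.0)

    @classmethod
    def unmanipulated(cls, duration_s: float = 12.0, interval_s: float = 1.0) -> "Protocol":
        return cls("none", 0.0, duration_s, 0.0, frame_interval_s=interval_s)


@dataclass
class SceneParams:
    """Bipolar spindle scene and noise model.

    Geometry: poles on the x axis, sister kinetochore pairs straddling the
    equator, the manipulated fiber being the outermost of ``fibers_per_half``
    on the +y side.  ``network_crosslinking`` > 1 emulates a globally
    stiffened network (rigor-crosslinked kinesin-5): inter-fiber coupling
    rises relative to each fiber's own anchorage, so deformation is
    transmitted further across the spindle half.  Tracing noise is smooth along each fiber (correlation length
    ``noise_corr_um``), emulating semi-automatic tracing error rather than
    white pixel noise.
    """

    spindle_length_um: float = 16.0
    fibers_per_half: int = 4
    interkt_um: float = 2.35
    outer_offset_um: float = 3.5
    fiber_spacing_um: float = 1.4
    sagitta_um: float = 0.4
    sister_coupling: bool = True
    sister_decay_um: float = 2.0
    bending_B: float = DEFAULT_B
    kc_base: float = DEFAULT_KC_BASE
    k_enh: float = DEFAULT_K_ENH
    s_enh_um: float = DEFAULT_S_ENH
    k_kt: float = DEFAULT_K_KT
    pole_axial_k: float = 600.0
    network_crosslinking: float = 1.0
    k_neighbor: float = 88.0
    k_anchor: float = 75.0
    jitter_rot_deg: float = 0.5
    jitter_trans_um: float = 0.2
    noise_sigma_um: float = 0.075
    noise_corr_um: float = 3.0
    tau_s: float = 20.0
    n_nodes: int = 51
    resample_points: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_um < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.tau_s <= 0:
            raise ValueError("turnover lifetime must be > 0")
        if self.fibers_per_half < 1:
            raise ValueError("need at least one fiber per half")

    @classmethod
    def wildtype(cls, **kw) -> "SceneParams":
        return cls(**kw)

    @classmethod
    def fcpt(cls, **kw) -> "SceneParams":
        kw.setdefault("network_crosslinking", 2.0)
        return cls(**kw)

    @classmethod
    def prc1_rnai(cls, **kw) -> "SceneParams":
        kw.setdefault("k_enh", 0.0)
        kw.setdefault("sister_coupling", False)
        kw.setdefault("interkt_um", 1.86)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that an experimenter would not."""

    seed: int
    s_needle_um: float
    needle_path: np.ndarray          # (n_frames, 2), before jitter/noise
    needle_displacement_um: np.ndarray
    kc_profile: np.ndarray           # per-node crosslink stiffness at t = 0
    k_enh_series: np.ndarray         # enhancement density per frame
    tau_s: float
    transmission: float              # per-neighbor displacement attenuation
    rest_fibers: dict[str, np.ndarray] = field(default_factory=dict)
    jitter: list[tuple[float, np.ndarray]] = field(default_factory=list)


def _arc_polyline(p_from, p_to, sagitta: float, n: int, bulge_sign: float) -> np.ndarray:
    """Shallow circular-ish arc between two points, plus-end first."""
    p_from = np.asarray(p_from, dtype=float)
    p_to = np.asarray(p_to, dtype=float)
    t = np.linspace(0.0, 1.0, n)
    chord = p_to - p_from
    perp = np.array([-chord[1], chord[0]])
    perp = perp / np.linalg.norm(perp)
    pts = p_from + np.outer(t, chord) + np.outer(bulge_sign * sagitta * np.sin(np.pi * t), perp)
    return resample_arclength(pts, n)


def _region_rotation(rest: np.ndarray, deformed: np.ndarray, region_um: float) -> float:
    """Signed rotation (radians) of the plus-end region between two shapes."""
    def direction(pts):
        s = cumulative_arclength(pts)
        sel = pts[s <= region_um + 1e-12]
        d = sel[-1] - sel[0]
        return d / np.linalg.norm(d)

    d0, d1 = direction(rest), direction(deformed)
    return float(math.atan2(d0[0] * d1[1] - d0[1] * d1[0], d0 @ d1))


def _smooth_noise(rng, s: np.ndarray, sigma: float, corr: float) -> np.ndarray:
    """Smooth 2D Gaussian noise field along arc positions s (RBF kernel)."""
    if sigma == 0.0:
        return np.zeros((len(s), 2))
    d = s[:, None] - s[None, :]
    K = sigma**2 * np.exp(-0.5 * (d / corr) ** 2) + 1e-12 * np.eye(len(s))
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal((len(s), 2))


def generate_manipulation_series(
    scene: SceneParams,
    protocol: Protocol,
    cell_id: str = "cell0",
    condition: str | None = None,
) -> tuple[ManipulationSeries, GroundTruth]:
    """Simulate one manipulation experiment frame by frame.

    Per frame: the needle ramps linearly toward the pull distance; the
    manipulated rod is re-equilibrated (enhancement decaying during a
    hold); neighbor fibers on the same side follow with the transmission
    attenuation; the sister either rigidly tracks the manipulated plus-end
    (coupled) or stays put; whole-spindle rigid jitter and smooth tracing
    noise are applied last.
    """
    rng = np.random.default_rng(scene.seed)
    c = scene.network_crosslinking
    Ls = scene.spindle_length_um
    pole1 = np.array([0.0, 0.0])
    pole2 = np.array([Ls, 0.0])
    xc = Ls / 2.0

    # rest geometry: pair j at decreasing lateral offset, pair 0 manipulated
    rest_a: dict[str, np.ndarray] = {}
    rest_b: dict[str, np.ndarray] = {}
    for j in range(scene.fibers_per_half):
        y = scene.outer_offset_um - j * scene.fiber_spacing_um
        kt_a = np.array([xc - scene.interkt_um / 2.0, y])
        kt_b = np.array([xc + scene.interkt_um / 2.0, y])
        bulge = 1.0 if y >= 0 else -1.0
        rest_a[f"pair{j}.a"] = _arc_polyline(kt_a, pole1, scene.sagitta_um, scene.n_nodes, bulge)
        rest_b[f"pair{j}.b"] = _arc_polyline(kt_b, pole2, scene.sagitta_um, scene.n_nodes, bulge)

    manip_id = "pair0.a"
    # without sister coupling the chromosome stretches instead of holding
    # the plus-end, so the kinetochore tether is an order of magnitude softer
    rod = RodModel(
        rest=rest_a[manip_id],
        bending_B=scene.bending_B,
        kc_base=scene.kc_base,
        k_enh=scene.k_enh,
        s_enh=scene.s_enh_um,
        k_kt=scene.k_kt if scene.sister_coupling else scene.k_kt / 10.0,
    )
    s_needle = protocol.u_needle * rod.length
    needle_node = int(np.argmin(np.abs(rod.s - s_needle)))
    needle_rest = rod.rest[needle_node].copy()
    direction = np.asarray(protocol.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    # a rigor-crosslinked network moves more collectively: inter-fiber
    # coupling scales up with c while each fiber's effective anchorage to
    # an (increasingly mobile) reference scales down
    transmission = (scene.k_neighbor * c) / (scene.k_neighbor * c + scene.k_anchor / c)
    n_frames = int(np.floor(protocol.total_s / protocol.frame_interval_s)) + 1
    times = np.arange(n_frames) * protocol.frame_interval_s

    # cache one resampling grid + noise factor per structure
    rs = scene.resample_points
    frac = np.linspace(0.0, 1.0, rs)

    frames: list[SpindleFrame] = []
    gt = GroundTruth(
        seed=scene.seed,
        s_needle_um=s_needle,
        needle_path=np.zeros((n_frames, 2)),
        needle_displacement_um=np.zeros(n_frames),
        kc_profile=rod.kc_nodes.copy(),
        k_enh_series=np.zeros(n_frames),
        tau_s=scene.tau_s,
        transmission=transmission,
        rest_fibers={**{k: v.copy() for k, v in rest_a.items()},
                     **{k: v.copy() for k, v in rest_b.items()}},
    )

    x_prev = rod.rest.copy()
    for fi, t in enumerate(times):
        delta = protocol.displacement_at(t)
        t_hold = max(0.0, t - protocol.pull_s) if protocol.kind == "pull_hold" else 0.0
        rod_t = degrade_reinforcement(rod, t_hold, scene.tau_s) if t_hold > 0 else rod
        gt.k_enh_series[fi] = rod_t.k_enh

        if protocol.kind == "none" or delta == 0.0:
            x_manip = rod.rest.copy()
        else:
            x_manip = simulate_rod_equilibrium(
                rod_t, delta * direction, s_needle=s_needle, x0=x_prev,
                free_pole_axial=True, pole_axial_k=scene.pole_axial_k,
            )
            x_prev = x_manip
        needle_tip = needle_rest + delta * direction
        gt.needle_path[fi] = needle_tip
        gt.needle_displacement_um[fi] = delta

        # displacement field of the manipulated fiber at fractional positions
        man_rest_rs = resample_arclength(rod.rest, rs)
        man_def_rs = resample_arclength(x_manip, rs)
        u_field = man_def_rs - man_rest_rs

        fibers: dict[str, FiberTrace] = {}
        fibers[manip_id] = FiberTrace(manip_id, man_def_rs, role="kfiber",
                                      sister_id="pair0.b")

        # neighbors on the manipulated side: attenuated copy of the field
        for j in range(1, scene.fibers_per_half):
            sid = f"pair{j}.a"
            base = resample_arclength(rest_a[sid], rs)
            fibers[sid] = FiberTrace(sid, base + (transmission**j) * u_field,
                                     role="kfiber", sister_id=f"pair{j}.b")

        # sister side: when coupled, the kinetochore junction moves as a
        # rigid unit — the sister's plus-end translates with the
        # manipulated plus-end *and* co-rotates with its plus-end region
        # (preserving the inter-sister angle), the response decaying along
        # the sister as its own chromosome-proximal reinforcement takes up
        # the load.  Uncoupled sisters are static (the stretched chromosome
        # absorbs the displacement).
        plus_disp = x_manip[0] - rod.rest[0]
        pole2_t = pole2.copy()
        sister_shapes: dict[str, np.ndarray] = {
            sid: resample_arclength(p, rs) for sid, p in rest_b.items()
        }
        if scene.sister_coupling and protocol.kind != "none" and delta > 0:
            phi = _region_rotation(rod.rest, x_manip, region_um=3.0)
            base = sister_shapes["pair0.b"]
            s_arc = cumulative_arclength(base)
            wgt = np.exp(-s_arc / scene.sister_decay_um)
            rel = base - base[0]
            rot = np.column_stack([-rel[:, 1], rel[:, 0]]) * phi  # small-angle
            sister_shapes["pair0.b"] = base + wgt[:, None] * (plus_disp + rot)
        for sid, shape in sister_shapes.items():
            pair = sid[:-2]
            fibers[sid] = FiberTrace(sid, shape, role="sister_kfiber",
                                     sister_id=pair + ".a")

        # whole-spindle rigid jitter, about the spindle center
        rot = rng.normal(0.0, scene.jitter_rot_deg)
        trans = rng.normal(0.0, scene.jitter_trans_um, 2)
        th = math.radians(rot)
        Rj = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        center = np.array([xc, 0.0])

        def jit(pts):
            return (np.atleast_2d(pts) - center) @ Rj.T + center + trans

        gt.jitter.append((rot, trans.copy()))

        for tr in fibers.values():
            s_arc = cumulative_arclength(tr.points)
            noise = _smooth_noise(rng, s_arc, scene.noise_sigma_um, scene.noise_corr_um)
            tr.points = jit(tr.points) + noise
        # pole1 is the manipulated rod's (axially sprung) pole end
        p1 = jit(x_manip[-1])[0] + rng.normal(0.0, scene.noise_sigma_um, 2)
        p2 = jit(pole2_t)[0] + rng.normal(0.0, scene.noise_sigma_um, 2)
        ndl = jit(needle_tip)[0] + rng.normal(0.0, scene.noise_sigma_um, 2)

        kt_pairs = {f"pair{j}": (f"pair{j}.a", f"pair{j}.b")
                    for j in range(scene.fibers_per_half)}
        frames.append(
            SpindleFrame(
                pole1=p1, pole2=p2, fibers=fibers, kt_pairs=kt_pairs,
                needle=ndl, time_s=float(t),
            )
        )

    series = ManipulationSeries(
        frames=frames,
        manipulated_fiber=manip_id,
        pull_end_s=None if protocol.kind == "none" else protocol.pull_s,
        hold_start_s=protocol.pull_s if protocol.kind == "pull_hold" else None,
        condition=condition or ("WT" if scene.k_enh > 0 else "PRC1_RNAi"),
        cell_id=cell_id,
    )
    return series, gt


def series_to_trace_table(series: ManipulationSeries) -> pd.DataFrame:
    """Flatten a series into the trace-table dialect (um, math convention)."""
    rows = []
    for fi, frame in enumerate(series.frames):
        def emit(sid, role, pts):
            pts = np.atleast_2d(pts)
            for pi, (x, y) in enumerate(pts):
                rows.append(
                    {
                        "cell_id": series.cell_id,
                        "condition": series.condition,
                        "frame_index": fi,
                        "time_s": frame.time_s,
                        "structure_id": sid,
                        "role": role,
                        "point_index": pi,
                        "x_um": x,
                        "y_um": y,
                    }
                )

        if frame.pole1 is not None:
            emit("pole1", "pole", frame.pole1)
        if frame.pole2 is not None:
            emit("pole2", "pole", frame.pole2)
        for sid, tr in frame.fibers.items():
            emit(sid, tr.role, tr.points)
        for pair, (a, b) in frame.kt_pairs.items():
            emit(f"{pair}.kt_a", "kinetochore", frame.fibers[a].plus_end)
            emit(f"{pair}.kt_b", "kinetochore", frame.fibers[b].plus_end)
        if frame.needle is not None:
            emit("needle", "needle", frame.needle)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering and needle step programs


def render_frame(
    frame: SpindleFrame,
    pixel_size: float = 0.105,
    psf_sigma: float = 0.2,
    fov_um: tuple[float, float] = (20.0, 12.0),
    origin_um: tuple[float, float] = (-2.0, -6.0),
) -> np.ndarray:
    """Gaussian-convolved line rendering of the scene (fixture use only).

    Fibers are splatted as dense chains of Gaussian kernels (intensity per
    unit length, so total intensity is conserved under sub-pixel shifts);
    poles are brighter isotropic blobs.  Raises if any structure falls
    outside the field of view.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    w_px = int(round(fov_um[0] / pixel_size))
    h_px = int(round(fov_um[1] / pixel_size))
    img = np.zeros((h_px, w_px))
    ox, oy = origin_um

    def splat(points: np.ndarray, amplitude: float) -> None:
        pts = np.atleast_2d(points)
        px = (pts[:, 0] - ox) / pixel_size
        py = (pts[:, 1] - oy) / pixel_size
        if px.min() < 0 or py.min() < 0 or px.max() >= w_px or py.max() >= h_px:
            raise ValueError("field of view too small for the scene")
        sig = psf_sigma / pixel_size
        rad = int(np.ceil(4 * sig))
        for cx, cy in zip(px, py):
            x0, x1 = int(cx) - rad, int(cx) + rad + 1
            y0, y1 = int(cy) - rad, int(cy) + rad + 1
            xs = np.arange(max(x0, 0), min(x1, w_px))
            ys = np.arange(max(y0, 0), min(y1, h_px))
            if len(xs) == 0 or len(ys) == 0:
                continue
            gx = np.exp(-0.5 * ((xs - cx) / sig) ** 2)
            gy = np.exp(-0.5 * ((ys - cy) / sig) ** 2)
            img[np.ix_(ys, xs)] += amplitude * np.outer(gy, gx)

    step = pixel_size / 4.0
    for tr in frame.fibers.values():
        L = cumulative_arclength(tr.points)[-1]
        n = max(int(np.ceil(L / step)), 2)
        dense = resample_arclength(tr.points, n)
        splat(dense, amplitude=L / n)  # per-point weight = covered length
    for pole in (frame.pole1, frame.pole2):
        if pole is not None:
            splat(pole, amplitude=5.0)
    return img


def needle_step_program(
    angle_deg: float,
    distance_um: float,
    duration_s: float,
    step_um: float = 0.0625,
) -> pd.DataFrame:
    """Stepper-motor instruction list for a smooth linear needle ramp.

    Steps of ``step_um`` along the requested angle, one dwell between
    steps, so the total displacement lands within one step of the request.
    """
    if distance_um <= 0 or duration_s <= 0:
        raise ValueError("distance and duration must be > 0")
    if distance_um < step_um:
        warnings.warn("requested distance below the minimum step; single-step program")
        n = 1
        mag = distance_um
    else:
        n = int(round(distance_um / step_um))
        mag = step_um
    th = math.radians(angle_deg)
    dwell = duration_s / n
    return pd.DataFrame(
        {
            "dx_um": np.full(n, mag * math.cos(th)),
            "dy_um": np.full(n, mag * math.sin(th)),
            "dwell_s": np.full(n, dwell),
        }
    )
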