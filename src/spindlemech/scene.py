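"""In-memory scene containers: traced structures, frames, time courses.

A :class:`SpindleFrame` holds everything traced in one movie frame — pole
centroids, kinetochore pairs, fiber polylines with sister linkage, and the
microneedle tip.  A :class:`ManipulationSeries` is the ordered time course
of one manipulation, with protocol phase markers (ramp end / hold start).

Fiber polylines are stored plus-end first: index 0 is the chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import as_polyline

__all__ = ["FiberTrace", "SpindleFrame", "ManipulationSeries"]

ROLES = ("kfiber", "sister_kfiber", "pole", "kinetochore", "needle")


@dataclass
class FiberTrace:
    """Ordered 2D polyline (um) for one fiber in one frame.

    ``points[0]`` is the plus-end (chromosome end).  ``sister_id`` names the
    fiber attached to the same chromosome from the opposite pole, if traced.
    """

    structure_id: str
    points: np.ndarray
    role: str = "kfiber"
    sister_id: str | None = None

    def __post_init__(self) -> None:
        self.points = as_polyline(self.points)
        if self.role not in ("kfiber", "sister_kfiber"):
            raise ValueError(f"not a fiber role: {self.role}")

    @property
    def plus_end(self) -> np.ndarray:
        return self.points[0]


@dataclass
class SpindleFrame:
    """One traced frame: poles, fibers, kinetochore pairs, needle tip."""

    pole1: np.ndarray | None
    pole2: np.ndarray | None
    fibers: dict[str, FiberTrace] = field(default_factory=dict)
    kt_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    needle: np.ndarray | None = None
    time_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pole1", "pole2", "needle"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        for pair_id, (a, b) in self.kt_pairs.items():
            for fid in (a, b):
                if fid not in self.fibers:
                    raise ValueError(f"kt pair {pair_id!r} references unknown fiber {fid!r}")

    def require_poles(self) -> tuple[np.ndarray, np.ndarray]:
        if self.pole1 is None or self.pole2 is None:
            raise ValueError("both spindle poles are required for this metric")
        return self.pole1, self.pole2

    def sister_fibers(self, pair_id: str) -> tuple[FiberTrace, FiberTrace]:
        if pair_id not in self.kt_pairs:
            raise ValueError(f"unknown kinetochore pair {pair_id!r}")
        a, b = self.kt_pairs[pair_id]
        return self.fibers[a], self.fibers[b]


@dataclass
class ManipulationSeries:
    """Ordered time course of one manipulation experiment."""

    frames: list[SpindleFrame]
    manipulated_fiber: str
    pull_end_s: float | None = None
    hold_start_s: float | None = None
    condition: str = "WT"
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        times = [f.time_s for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])
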