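"""Run configuration: every analysis parameter, with units and defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters shared across the pipeline.

    curvature_window_um
        Arc-length spacing between the three points of each circumscribed
        circle fit; sets the length scale on which curvature is measured.
    negative_threshold
        Signed curvature (1/um) below which a reverse bend counts as a
        detectable negative-curvature event.
    proximal_fraction
        Fraction of the fiber length from the plus-end (and symmetrically
        from the pole end) defining the "proximal to chromosome" / "proximal
        to pole" classification windows.
    resample_points
        Number of equally spaced coordinates stored along each fiber.
    rigid_exclusion_radius_um
        Points within this distance of the microneedle tip are excluded from
        the rigid-alignment anchors (the deformation is local, so distal
        structure approximates a rigid reference).
    region_um
        Extent of the plus-end-proximal region used for line-fit angle
        measurements.
    bin_width_um
        Bin width for deformation-versus-distance summaries.
    track_halfwidth_um
        Half-width of the arc-length window, centred on the pre-hold
        curvature minimum, in which the minimum is tracked during a
        manipulate-and-hold experiment.
    pixel_size_um
        Camera pixel size; applied once when trace tables arrive in pixel
        units.
    seed
        Seed recorded in every output manifest; all randomness flows from it.
    """

    curvature_window_um: float = 1.0
    negative_threshold: float = -0.1
    proximal_fraction: float = 0.4
    resample_points: int = 100
    rigid_exclusion_radius_um: float = 5.0
    region_um: float = 3.0
    bin_width_um: float = 1.0
    track_halfwidth_um: float = 1.5
    pixel_size_um: float = 0.105
    seed: int = 0

    def __post_init__(self) -> None:
        if self.curvature_window_um <= 0:
            raise ValueError("curvature_window_um must be > 0")
        if not (0.0 < self.proximal_fraction <= 0.5):
            raise ValueError("proximal_fraction must be in (0, 0.5]")
        if self.resample_points < 3:
            raise ValueError("resample_points must be >= 3")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


DEFAULT_CONFIG = RunConfig()
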