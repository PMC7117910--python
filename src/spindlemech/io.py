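"""Reading and writing tabular inputs and outputs.

Trace tables are comma-delimited text with one traced point per row
(columns: cell_id, condition, frame_index, time_s, structure_id, role,
point_index, x_um, y_um — or x_px/y_px for pixel-unit traces).  Input
coordinates use image convention (y increases downward) and are converted
once, here, to the mathematical convention (y up) used by all geometry;
writing converts back, so a read/write round trip is the identity.

Deposited source-data spreadsheets (one workbook per figure) are read into
a :class:`SourceDataBundle` keyed by panel; sheets are matched to panels by
a documented keyword dialect, since the workbooks themselves carry the only
authoritative layout.

Sister linkage convention in trace tables: fibers attached to the same
chromosome share a structure_id prefix before the final ``.a`` / ``.b``
suffix (e.g. ``pair0.a`` is a ``kfiber`` and ``pair0.b`` its
``sister_kfiber``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .scene import FiberTrace, SpindleFrame

__all__ = [
    "TraceTable",
    "read_trace_table",
    "write_trace_table",
    "SourceDataBundle",
    "read_source_bundle",
    "write_report",
    "PANELS",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "cell_id",
    "condition",
    "frame_index",
    "time_s",
    "structure_id",
    "role",
    "point_index",
]
ROLE_VALUES = {"kfiber", "sister_kfiber", "pole", "kinetochore", "needle"}
CONDITIONS = {"WT", "FCPT", "PRC1_RNAi", "control"}


@dataclass
class TraceTable:
    """Validated table of traced points, coordinates in um, math convention."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS + ["x_um", "y_um"] if c not in df.columns]
        if missing:
            raise ValueError(f"trace table missing required column(s): {missing}")
        if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy())):
            raise ValueError("trace table contains non-finite coordinates")
        bad_roles = set(df["role"]) - ROLE_VALUES
        if bad_roles:
            raise ValueError(f"unknown role value(s): {sorted(bad_roles)}")
        for (cell, frame, sid), grp in df.groupby(
            ["cell_id", "frame_index", "structure_id"], sort=False
        ):
            idx = grp["point_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(
                    f"point_index not consecutive from 0 for "
                    f"(cell={cell!r}, frame={frame}, structure={sid!r})"
                )

    def cells(self) -> list[str]:
        return list(dict.fromkeys(self.df["cell_id"]))

    def to_frames(self, cell_id: str) -> list[SpindleFrame]:
        """Assemble per-frame scenes for one cell, sister-linked by id suffix."""
        sub = self.df[self.df["cell_id"] == cell_id]
        if sub.empty:
            raise ValueError(f"no records for cell {cell_id!r}")
        frames = []
        for fidx, grp in sub.groupby("frame_index", sort=True):
            poles: dict[str, np.ndarray] = {}
            fibers: dict[str, FiberTrace] = {}
            needle = None
            for sid, g in grp.groupby("structure_id", sort=False):
                g = g.sort_values("point_index")
                pts = g[["x_um", "y_um"]].to_numpy()
                role = g["role"].iloc[0]
                if role == "pole":
                    poles[sid] = pts.mean(axis=0)
                elif role == "needle":
                    needle = pts[0]
                elif role in ("kfiber", "sister_kfiber"):
                    fibers[sid] = FiberTrace(sid, pts, role=role)
            kt_pairs = {}
            for sid in fibers:
                if sid.endswith(".a") and sid[:-2] + ".b" in fibers:
                    pair = sid[:-2]
                    kt_pairs[pair] = (sid, pair + ".b")
                    fibers[sid].sister_id = pair + ".b"
                    fibers[pair + ".b"].sister_id = sid
            pole_ids = sorted(poles)
            frames.append(
                SpindleFrame(
                    pole1=poles[pole_ids[0]] if len(pole_ids) > 0 else None,
                    pole2=poles[pole_ids[1]] if len(pole_ids) > 1 else None,
                    fibers=fibers,
                    kt_pairs=kt_pairs,
                    needle=needle,
                    time_s=float(grp["time_s"].iloc[0]),
                )
            )
        return frames


def read_trace_table(path_or_buffer, config: RunConfig = DEFAULT_CONFIG) -> TraceTable:
    """Read a trace CSV, validate it, and convert to um / math convention.

    Pixel-unit inputs (columns ``x_px``/``y_px``) are scaled by
    ``config.pixel_size_um``; um inputs are never rescaled (unit conversion
    is idempotent).
    """
    df = pd.read_csv(path_or_buffer)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing required column(s): {missing}")
    if {"x_um", "y_um"}.issubset(df.columns):
        pass
    elif {"x_px", "y_px"}.issubset(df.columns):
        df["x_um"] = df["x_px"] * config.pixel_size_um
        df["y_um"] = df["y_px"] * config.pixel_size_um
        df = df.drop(columns=["x_px", "y_px"])
    else:
        raise ValueError(
            "trace table missing required column(s): ['x_um', 'y_um'] (or x_px/y_px)"
        )
    df = df.copy()
    df["y_um"] = -df["y_um"]  # image convention (y down) -> math convention (y up)
    return TraceTable(df)


def write_trace_table(table: TraceTable, path) -> None:
    """Write a trace table back to CSV in image convention."""
    out = table.df.copy()
    out["y_um"] = -out["y_um"]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Deposited source-data spreadsheets

PANELS = (
    "deformation_vs_distance",
    "curvature_profiles",
    "hold_minima",
    "metrics",
    "needle_displacement",
    "cell_heights",
    "intensity_ratio",
)

# keyword dialect: first keyword found in a (lowercased) sheet name wins
_SHEET_DIALECT = [
    ("deformation", "deformation_vs_distance"),
    ("curvature", "curvature_profiles"),
    ("hold", "hold_minima"),
    ("displacement", "needle_displacement"),
    ("height", "cell_heights"),
    ("ratio", "intensity_ratio"),
    ("intensity", "intensity_ratio"),
    ("metric", "metrics"),
    ("inter-kinetochore", "metrics"),
    ("kinetochore", "metrics"),
    ("pole", "metrics"),
    ("angle", "metrics"),
]

_PANEL_UNITS = {
    "deformation_vs_distance": {"distance": "um", "deformation": "um"},
    "curvature_profiles": {"position": "normalized", "curvature": "1/um"},
    "hold_minima": {"time": "s", "curvature": "1/um"},
    "metrics": {"distance": "um", "angle": "deg"},
    "needle_displacement": {"time": "s", "displacement": "um"},
    "cell_heights": {"height": "um"},
    "intensity_ratio": {"position": "normalized", "ratio": "dimensionless"},
}


@dataclass
class SourceDataBundle:
    """Named tables keyed by figure panel; absent panels are explicit."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    units: dict[str, dict[str, str]] = field(default_factory=dict)

    def has(self, panel: str) -> bool:
        self._check_panel(panel)
        return panel in self.tables

    def get(self, panel: str) -> pd.DataFrame:
        self._check_panel(panel)
        if panel not in self.tables:
            raise KeyError(f"panel {panel!r} is absent from this bundle")
        return self.tables[panel]

    def absent(self) -> list[str]:
        return [p for p in PANELS if p not in self.tables]

    @staticmethod
    def _check_panel(panel: str) -> None:
        if panel not in PANELS:
            raise KeyError(f"unknown panel {panel!r}; expected one of {PANELS}")


def _classify_sheet(name: str) -> str | None:
    low = name.lower()
    for key, panel in _SHEET_DIALECT:
        if key in low:
            return panel
    return None


def read_source_bundle(paths) -> SourceDataBundle:
    """Read one or more source-data workbooks (.xlsx) or panel CSVs.

    Sheets whose names match no dialect keyword are skipped with a warning;
    duplicated sheet names across the bundle are an error; an empty file is
    an error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    bundle = SourceDataBundle()
    seen_sheets: dict[str, str] = {}
    duplicates: list[str] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix.lower() in (".xlsx", ".xls"):
            sheets = pd.read_excel(path, sheet_name=None)
        else:
            sheets = {path.stem: pd.read_csv(path)}
        if not sheets or all(df.empty for df in sheets.values()):
            raise ValueError(f"source-data file {path} is empty")
        for sheet_name, df in sheets.items():
            if sheet_name in seen_sheets:
                duplicates.append(sheet_name)
                continue
            seen_sheets[sheet_name] = str(path)
            panel = _classify_sheet(sheet_name)
            if panel is None:
                warnings.warn(f"unrecognized sheet {sheet_name!r} in {path}; skipped")
                log.warning("skipping unrecognized sheet %r in %s", sheet_name, path)
                continue
            if panel in bundle.tables:
                bundle.tables[panel] = pd.concat(
                    [bundle.tables[panel], df], ignore_index=True
                )
            else:
                bundle.tables[panel] = df
                bundle.units[panel] = dict(_PANEL_UNITS[panel])
    if duplicates:
        raise ValueError(f"duplicated sheet name(s) across bundle: {sorted(set(duplicates))}")
    return bundle


# ---------------------------------------------------------------------------
# Results


def write_report(results: dict[str, pd.DataFrame], out_dir, config: RunConfig,
                 extra_manifest: dict | None = None) -> dict:
    """Write one TSV per result table plus a machine-readable run manifest.

    The manifest records the full effective configuration (no silent
    defaults), the seed, and library versions; it contains no timestamp so
    a rerun with the same seed regenerates the report bit-identically.
    """
    if not results:
        raise ValueError("results are empty; nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import scipy

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "spindlemech": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "tables": sorted(results),
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
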