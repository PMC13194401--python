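"""Plate I/O: image stacks, plate layouts, measurement tables.

Image stacks are multi-page TIFFs, one file per channel, all channels sharing
one (z, y, x) grid. Voxel indices are 0-based (z, y, x); physical positions
are voxel index x spacing, i.e. voxel centres on a regular grid anchored at
the first voxel centre.

Layouts are CSV tables mapping wells to sample / condition / dose / replicate
group / control flag; edge flags are derived from plate geometry (outermost
ring of the plate, rows A and P and columns 1 and 24 on a 384-well plate).
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = ("nuclei", "actin", "tracker")

#: Canonical column order for per-well measurement tables.
WELL_COLUMNS = [
    "well_id",
    "object_count",
    "total_volume_mm3",
    "mean_object_volume_um3",
    "median_object_volume_um3",
    "nucleus_count",
    "single_cell_count",
    "tracker_cell_count",
    "infiltrated_count",
    "infiltration_fraction",
    "qc_flags",
]

#: Canonical column order for normalized (percent-of-control) summary tables.
NORMALIZED_COLUMNS = [
    "sample_id",
    "condition",
    "dose",
    "readout",
    "poc_summary",
    "poc_sd",
    "n_replicates",
    "low_n",
    "reduction_percent",
    "response_category",
]


class FormatError(ValueError):
    """Input files are structurally inconsistent (e.g. channel shape mismatch)."""


class LayoutError(ValueError):
    """Plate layout violates its invariants."""


@dataclass
class ImageStack:
    """A calibrated multi-channel 3D well image.

    voxels : (channel, z, y, x) non-negative intensities.
    channel_roles : channel index -> role in ``CHANNEL_ROLES``.
    """

    voxels: np.ndarray
    channel_roles: dict[int, str]
    voxel_size_xy: float
    z_step: float
    well_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise FormatError(
                f"expected (channel, z, y, x) voxels, got shape {self.voxels.shape}"
            )
        if self.voxel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        for idx, role in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not 0 <= idx < self.voxels.shape[0]:
                raise ValueError(f"channel index {idx} out of range")
        nz = self.voxels.shape[1]
        if not 20 <= nz <= 80:
            warnings.warn(
                f"{nz} z-sections is outside the typical 20-80 acquisition range",
                stacklevel=2,
            )
        if not 20.0 <= self.z_step <= 50.0:
            warnings.warn(
                f"z-step {self.z_step} um is outside the typical 20-50 um range",
                stacklevel=2,
            )

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def roles(self) -> set[str]:
        return set(self.channel_roles.values())

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles.values()

    def channel(self, role: str) -> np.ndarray:
        for idx, r in self.channel_roles.items():
            if r == role:
                return self.voxels[idx]
        raise KeyError(f"stack {self.well_id!r} has no {role!r} channel")


def read_stack(
    paths: Mapping[str, str | Path],
    voxel_size_xy: float,
    z_step: float,
    well_id: str = "",
) -> ImageStack:
    """Read one multi-page TIFF per channel role into an :class:`ImageStack`.

    ``paths`` maps channel role ("nuclei", "actin", optionally "tracker") to a
    file. All channels must share one (z, y, x) shape.
    """
    if not paths:
        raise ValueError("no channel files given")
    arrays: list[np.ndarray] = []
    roles: dict[int, str] = {}
    for i, role in enumerate(r for r in CHANNEL_ROLES if r in paths):
        p = Path(paths[role])
        if not p.exists():
            raise FileNotFoundError(p)
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise FormatError(f"{p}: expected a z-stack, got shape {arr.shape}")
        arrays.append(arr)
        roles[i] = role
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise FormatError(f"channel shapes differ: {sorted(shapes)}")
    voxels = np.stack(arrays, axis=0)
    return ImageStack(voxels, roles, voxel_size_xy, z_step, well_id=well_id)


def write_stack(stack: ImageStack, directory: str | Path) -> dict[str, Path]:
    """Write one uint16 multi-page TIFF per channel; returns role -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for idx, role in stack.channel_roles.items():
        arr = np.clip(np.round(stack.voxels[idx]), 0, 65535).astype(np.uint16)
        path = directory / f"{stack.well_id or 'well'}_{role}.tif"
        tifffile.imwrite(path, arr)
        out[role] = path
    return out


# ---------------------------------------------------------------------------
# plate layouts
# ---------------------------------------------------------------------------

_PLATE_DIMS = {384: (16, 24), 96: (8, 12), 1536: (32, 48)}

_WELL_RE = re.compile(r"^([A-Za-z]{1,2})(\d{1,2})$")


def well_row_col(well_id: str) -> tuple[int, int]:
    """'B07' -> (1, 6): 0-based (row, column)."""
    m = _WELL_RE.match(well_id.strip())
    if not m:
        raise LayoutError(f"malformed well id {well_id!r}")
    letters, digits = m.groups()
    row = 0
    for ch in letters.upper():
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(digits) - 1


def well_name(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def is_edge_well(well_id: str, plate_format: int = 384) -> bool:
    nrow, ncol = _PLATE_DIMS[plate_format]
    r, c = well_row_col(well_id)
    if not (0 <= r < nrow and 0 <= c < ncol):
        raise LayoutError(f"well {well_id!r} outside a {plate_format}-well plate")
    return r in (0, nrow - 1) or c in (0, ncol - 1)


LAYOUT_COLUMNS = [
    "well_id",
    "sample_id",
    "condition",
    "dose",
    "dose_units",
    "replicate_group",
    "is_control",
    "is_edge",
]

_DEFAULT_REPLICATES = {"reconstituted": 4, "evpt": 8}


@dataclass
class PlateLayout:
    """Well -> (sample, condition, dose, replicate group, flags) mapping."""

    frame: pd.DataFrame
    plate_format: int = 384
    assay_kind: str = "evpt"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("well_id", "sample_id", "condition", "replicate_group", "is_control"):
            if col not in df.columns:
                raise LayoutError(f"layout is missing required column {col!r}")
        if "dose" not in df.columns:
            df["dose"] = np.nan
        if "dose_units" not in df.columns:
            df["dose_units"] = ""
        df["well_id"] = df["well_id"].astype(str).str.strip().str.upper()
        dup = df["well_id"][df["well_id"].duplicated()]
        if len(dup):
            raise LayoutError(f"duplicate well ids: {sorted(set(dup))}")
        df["is_control"] = df["is_control"].astype(bool)
        df["is_edge"] = [
            is_edge_well(w, self.plate_format) for w in df["well_id"]
        ]
        # a replicate group must describe exactly one condition x dose
        for name, sub in df.groupby("replicate_group"):
            combos = sub[["condition", "dose"]].drop_duplicates()
            if len(combos) > 1:
                raise LayoutError(
                    f"replicate group {name!r} spans multiple condition/dose combinations"
                )
        for sample, sub in df.groupby("sample_id"):
            if not sub["is_control"].any():
                raise LayoutError(f"sample {sample!r} has no control wells")
        expected = _DEFAULT_REPLICATES.get(self.assay_kind)
        if expected is not None:
            counts = df.groupby("replicate_group")["well_id"].count()
            off = counts[counts != expected]
            if len(off):
                warnings.warn(
                    f"replicate groups with n != {expected} for {self.assay_kind} assay: "
                    f"{dict(off.head(10))}",
                    stacklevel=2,
                )
        self.frame = df[LAYOUT_COLUMNS].reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return list(self.frame["well_id"])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def control_wells(self, sample_id: str | None = None) -> list[str]:
        df = self.frame
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        return list(df.loc[df["is_control"], "well_id"])

    @classmethod
    def from_csv(
        cls, path: str | Path, plate_format: int = 384, assay_kind: str | None = None
    ) -> "PlateLayout":
        df = pd.read_csv(path)
        if assay_kind is None:
            assay_kind = (
                str(df["assay_kind"].iloc[0]) if "assay_kind" in df.columns else "evpt"
            )
        df = df.drop(columns=[c for c in ("assay_kind", "is_edge") if c in df.columns])
        return cls(df, plate_format=plate_format, assay_kind=assay_kind)

    def to_csv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df["assay_kind"] = self.assay_kind
        df.to_csv(path, index=False)


def read_layout(
    path: str | Path, plate_format: int = 384, assay_kind: str | None = None
) -> PlateLayout:
    """Read and validate a layout CSV; edge flags are recomputed from geometry."""
    return PlateLayout.from_csv(path, plate_format=plate_format, assay_kind=assay_kind)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def write_measurements(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement table as CSV with stable column order.

    An empty table is written as a header-only file with a warning, so a run
    that measured nothing still leaves a well-formed artifact.
    """
    path = Path(path)
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(frame)
    if frame.empty:
        warnings.warn(f"writing empty measurement table to {path}", stacklevel=2)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
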