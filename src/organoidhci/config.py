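"""Run configuration: calibration, segmentation, classification, QC and
normalization parameters, with TOML round-trip.

All physical parameters are in micrometres (µm) unless noted; volumes in µm³
except the control-window volume gate, which is stated in mm³ (1 mm³ = 1e9 µm³)
to match how such thresholds are quoted in screening practice.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class Calibration:
    """Physical voxel calibration of an image stack.

    voxel_size_xy
        Lateral sampling, µm per pixel. Low-magnification (4x) whole-well
        acquisition; default 3.4 µm.
    z_step
        Axial spacing between sections, µm. Whole-well gel imaging uses
        coarse steps (20-50 µm typical).
    """

    voxel_size_xy: float = 3.4
    z_step: float = 25.0

    def __post_init__(self) -> None:
        if self.voxel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError(
                f"calibration must be positive, got voxel_size_xy="
                f"{self.voxel_size_xy}, z_step={self.z_step}"
            )

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_xy * self.voxel_size_xy * self.z_step

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """(z, y, x) spacing in µm, matching the array axis order."""
        return (self.z_step, self.voxel_size_xy, self.voxel_size_xy)


@dataclass
class SegmentationConfig:
    """Thresholds of the classical 3D segmentation pipeline.

    Smoothing sigmas are physical (µm) and are divided by the per-axis
    spacing before filtering, so a 25-50 µm z-step never gets the lateral
    amount of smoothing.
    """

    smooth_sigma_um: float = 3.4  # ~1 voxel at the default lateral sampling
    threshold_method: str = "otsu"  # "otsu" | "mad"
    mad_k: float = 8.0  # threshold = median + k * robust sigma when method="mad"
    nucleus_min_separation_um: float = 10.0
    # tracker dye marks small immune cells (~8 um lymphocytes), so the
    # tracker detector resolves tighter packings than the nucleus detector
    tracker_min_separation_um: float = 8.0
    closing_radius_um: float = 7.0
    min_object_diameter_um: float = 15.0  # components below this equivalent diameter = debris


@dataclass
class ClassificationConfig:
    """Multicellular-object vs single-cell split."""

    single_cell_max_diameter_um: float = 30.0
    min_nuclei_multicellular: int = 2


@dataclass
class QCConfig:
    """Well- and plate-level quality gates."""

    min_control_objects: int = 50
    min_control_volume_mm3: float = 0.01
    # image-quality gate
    foreground_fraction_bounds: tuple[float, float] = (1e-4, 0.5)
    min_label_intensity_ratio: float = 2.0
    min_segmentation_coverage: float = 0.8
    # edge-effect verdict
    edge_p_threshold: float = 0.01
    edge_ratio_bounds: tuple[float, float] = (0.8, 1.25)
    # plate-level
    max_exclusion_fraction: float = 0.04
    # sample verdict fails when more than this fraction of control wells fail
    control_fail_fraction: float = 0.5


@dataclass
class NormalizationConfig:
    control_summary: str = "mean"  # "mean" | "median" across passing control wells
    # condition used as the 100% reference; None -> layout is_control flag
    reference_condition: str | None = None


@dataclass
class RunConfig:
    """Complete analysis configuration; serialized into every run directory."""

    calibration: Calibration = field(default_factory=Calibration)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "calibration": Calibration,
            "segmentation": SegmentationConfig,
            "classification": ClassificationConfig,
            "qc": QCConfig,
            "normalization": NormalizationConfig,
        }
        for name, klass in sections.items():
            if name in d:
                sub = dict(d[name])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[name] = klass(**sub)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(dumps_toml(self.to_dict()))


def _toml_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_toml(d: dict[str, Any], prefix: str = "") -> str:
    """Minimal TOML writer for nested dicts of scalars/sequences."""
    lines: list[str] = []
    tables: list[tuple[str, dict]] = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        elif v is None:
            continue
        else:
            lines.append(f"{k} = {_toml_scalar(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{prefix}{k}"
        out += f"\n\n[{name}]\n" + dumps_toml(v, prefix=name + ".")
    return out.strip() + "\n"
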