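"""Per-object morphometry and per-well readouts.

"Size" of a multicellular object is the cumulative segmented area through
the stack: volume = sum(per-slice area) x z-step, which for a voxel grid
equals voxel count x voxel volume. Keeping the per-slice areas makes the
area-based view of the same measurement available, and makes the 0.01 mm³
control-window threshold dimensionally meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import Calibration, RunConfig
from .io_plate import ImageStack, WELL_COLUMNS
from .segment3d import (
    LabelVolume,
    PointSet,
    classify_objects,
    detect_nuclei,
    detect_tracker_cells,
    segment_actin_objects,
)

UM3_PER_MM3 = 1e9


@dataclass
class ObjectMeasurement:
    """Morphometry of one multicellular object.

    ``volume_um3`` is exactly ``per_slice_areas_um2.sum() * z_step`` and the
    equivalent diameter is that of the sphere of equal volume.
    """

    object_id: int
    per_slice_areas_um2: np.ndarray
    volume_um3: float
    equivalent_diameter_um: float
    nucleus_count: int
    infiltrated_cell_count: int
    centroid_um: tuple[float, float, float]


def measure_objects(
    labels: LabelVolume,
    nuclei: PointSet,
    calibration: Calibration,
) -> list[ObjectMeasurement]:
    """Measure every labelled object; an empty labelling yields an empty list."""
    n = labels.n_objects
    if n == 0:
        return []
    lab = labels.labels
    nz = lab.shape[0]
    area_per_voxel = calibration.voxel_size_xy**2
    # one pass over the foreground voxels covers slice areas and centroids
    zi, yi, xi = np.nonzero(lab)
    vals = lab[zi, yi, xi]
    slice_counts = np.bincount((vals - 1) * nz + zi, minlength=n * nz).reshape(n, nz)
    slice_areas = slice_counts * area_per_voxel
    tot = np.bincount(vals, minlength=n + 1)[1:].astype(float)
    cz = np.bincount(vals, weights=zi, minlength=n + 1)[1:] / tot
    cy = np.bincount(vals, weights=yi, minlength=n + 1)[1:] / tot
    cx = np.bincount(vals, weights=xi, minlength=n + 1)[1:] / tot
    if len(nuclei):
        owner = lab[nuclei.voxels[:, 0], nuclei.voxels[:, 1], nuclei.voxels[:, 2]]
        nuc_counts = np.bincount(owner, minlength=n + 1)
    else:
        nuc_counts = np.zeros(n + 1, dtype=int)
    sz, sy, sx = calibration.spacing_zyx
    out = []
    for k in range(1, n + 1):
        areas = slice_areas[k - 1]
        volume = float(areas.sum() * calibration.z_step)
        out.append(
            ObjectMeasurement(
                object_id=k,
                per_slice_areas_um2=areas,
                volume_um3=volume,
                equivalent_diameter_um=float((6.0 * volume / np.pi) ** (1.0 / 3.0)),
                nucleus_count=int(nuc_counts[k]),
                infiltrated_cell_count=0,
                centroid_um=(cz[k - 1] * sz, cy[k - 1] * sy, cx[k - 1] * sx),
            )
        )
    return out


def objects_to_frame(objects: list[ObjectMeasurement], well_id: str = "") -> pd.DataFrame:
    rows = []
    for o in objects:
        d = asdict(o)
        d.pop("per_slice_areas_um2")
        cz, cy, cx = d.pop("centroid_um")
        d.update(centroid_z_um=cz, centroid_y_um=cy, centroid_x_um=cx)
        if well_id:
            d["well_id"] = well_id
        rows.append(d)
    cols = [
        "object_id",
        "volume_um3",
        "equivalent_diameter_um",
        "nucleus_count",
        "infiltrated_cell_count",
        "centroid_z_um",
        "centroid_y_um",
        "centroid_x_um",
    ]
    if well_id:
        cols = ["well_id"] + cols
    return pd.DataFrame(rows, columns=cols)


def count_infiltration(
    objects: LabelVolume, tracker: PointSet
) -> tuple[dict[int, int], int]:
    """Labeled cells located within a multicellular object.

    A tracker centroid is infiltrated iff its voxel belongs to an object's
    mask (centroid-in-mask rule). Returns (per-object counts, total).
    """
    per_object: dict[int, int] = {k: 0 for k in range(1, objects.n_objects + 1)}
    if len(tracker) == 0 or objects.n_objects == 0:
        return per_object, 0
    owner = objects.labels[
        tracker.voxels[:, 0], tracker.voxels[:, 1], tracker.voxels[:, 2]
    ]
    total = 0
    for k in owner[owner > 0]:
        per_object[int(k)] += 1
        total += 1
    return per_object, total


@dataclass
class WellMeasurement:
    """Per-well aggregate readouts (multicellular objects only, plus the
    single-cell and labeled-cell populations)."""

    well_id: str
    object_count: int = 0
    total_volume_mm3: float = 0.0
    mean_object_volume_um3: float = 0.0
    median_object_volume_um3: float = 0.0
    nucleus_count: int = 0
    single_cell_count: int = 0
    tracker_cell_count: int = 0
    infiltrated_count: int = 0
    infiltration_fraction: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.qc_flags


def wells_to_frame(wells: list[WellMeasurement]) -> pd.DataFrame:
    rows = []
    for w in wells:
        d = asdict(w)
        d["qc_flags"] = ";".join(w.qc_flags)
        rows.append(d)
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def measure_well(
    stack: ImageStack,
    config: RunConfig | None = None,
    return_intermediates: bool = False,
):
    """Run the full single-well pipeline: segment, classify, measure, count.

    Deterministic for a fixed configuration. A failure inside any stage marks
    the well ``analysis_failed`` instead of aborting, so one bad well never
    kills a plate.
    """
    config = config or RunConfig()
    calib = Calibration(stack.voxel_size_xy, stack.z_step)
    well = WellMeasurement(well_id=stack.well_id)
    intermediates: dict = {}
    try:
        nuclei = detect_nuclei(stack, config.segmentation)
        actin = segment_actin_objects(stack, config.segmentation)
        multi, singles = classify_objects(actin, nuclei, calib, config.classification)
        objects = measure_objects(multi, nuclei, calib)
        if stack.has_channel("tracker"):
            tracker = detect_tracker_cells(stack, config.segmentation)
        else:  # label-free assay: silently no labeled cells
            from .segment3d import PointSet as _PS

            tracker = _PS.empty("tracker_cell")
        per_object_inf, total_inf = count_infiltration(multi, tracker)
        for o in objects:
            o.infiltrated_cell_count = per_object_inf.get(o.object_id, 0)
        volumes = np.array([o.volume_um3 for o in objects])
        well.object_count = len(objects)
        well.total_volume_mm3 = float(volumes.sum() / UM3_PER_MM3)
        well.mean_object_volume_um3 = float(volumes.mean()) if len(volumes) else 0.0
        well.median_object_volume_um3 = float(np.median(volumes)) if len(volumes) else 0.0
        well.nucleus_count = len(nuclei)
        well.single_cell_count = len(singles)
        well.tracker_cell_count = len(tracker)
        well.infiltrated_count = total_inf
        well.infiltration_fraction = (
            total_inf / len(tracker) if len(tracker) else None
        )
        intermediates = {
            "nuclei": nuclei,
            "actin": actin,
            "multicellular": multi,
            "single_cells": singles,
            "tracker": tracker,
            "objects": objects,
        }
    except Exception as exc:  # noqa: BLE001 - a bad well must not abort the plate
        well.qc_flags.append("analysis_failed")
        intermediates = {"error": repr(exc)}
    if return_intermediates:
        return well, intermediates
    return well
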