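"""Classical 3D segmentation: nuclei/tracker spot detection, actin-defined
multicellular objects, and the multicellular-vs-single-cell split.

The object definition follows the assay's operational one: a multicellular
object is a connected actin-cytoskeleton structure containing at least two
nuclei; everything smaller, or with fewer nuclei, contributes to the
single-cell fraction. The pipeline is deliberately simple and fully
parameterized (smooth -> threshold -> close -> 26-connected components),
with per-axis smoothing scaled by the physical voxel spacing because the
20-50 µm z-steps of whole-well acquisition make isotropic filtering wrong.

Known limitation: touching tumoroids that merge after morphological closing
are reported as one object; no watershed splitting is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .config import Calibration, ClassificationConfig, SegmentationConfig
from .io_plate import ImageStack


@dataclass
class PointSet:
    """Detected point objects (nucleus or tracker-cell centroids)."""

    voxels: np.ndarray  # (n, 3) int voxel indices (z, y, x)
    coords_um: np.ndarray  # (n, 3) physical positions, µm
    kind: str  # "nucleus" | "tracker_cell"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        self.coords_um = np.asarray(self.coords_um, dtype=float).reshape(-1, 3)
        if len(self.voxels) != len(self.coords_um):
            raise ValueError("voxel and physical coordinates differ in length")

    def __len__(self) -> int:
        return len(self.voxels)

    @classmethod
    def empty(cls, kind: str) -> "PointSet":
        return cls(np.empty((0, 3), int), np.empty((0, 3)), kind)


@dataclass
class LabelVolume:
    """Labelled 3D segmentation: 0 = background, k > 0 = object k.

    Labels are consecutive positive integers 1..n_objects.
    """

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (z, y, x) grid")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _subsample(img: np.ndarray, target: int = 200_000) -> np.ndarray:
    """Strided subsample for robust background statistics on big volumes."""
    flat = img.ravel()
    step = max(1, flat.size // target)
    return flat[::step]


def _sigma_vox(sigma_um: float, calib: Calibration) -> tuple[float, float, float]:
    return (
        sigma_um / calib.z_step,
        sigma_um / calib.voxel_size_xy,
        sigma_um / calib.voxel_size_xy,
    )


def _threshold(img: np.ndarray, cfg: SegmentationConfig) -> float:
    if cfg.threshold_method == "otsu":
        finite = img[np.isfinite(img)]
        return float(threshold_otsu(finite)) if finite.size else np.inf
    if cfg.threshold_method == "mad":
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        return med + cfg.mad_k * sigma
    raise ValueError(f"unknown threshold method {cfg.threshold_method!r}")


def _separation_footprint(sep_um: float, calib: Calibration) -> np.ndarray:
    """Anisotropic neighbourhood whose half-extent is the minimum separation."""
    rz = max(0, int(round(sep_um / calib.z_step)))
    rxy = max(1, int(round(sep_um / calib.voxel_size_xy)))
    return np.ones((2 * rz + 1, 2 * rxy + 1, 2 * rxy + 1), dtype=bool)


def _detect_points(
    channel: np.ndarray,
    calib: Calibration,
    cfg: SegmentationConfig,
    min_separation_um: float,
    kind: str,
) -> PointSet:
    img = np.asarray(channel, dtype=np.float32)
    smoothed = ndimage.gaussian_filter(img, sigma=_sigma_vox(cfg.smooth_sigma_um, calib))
    sub = _subsample(smoothed)
    background = float(np.median(sub))
    corrected = smoothed - background
    # Otsu can land inside pure noise when no signal exists; never go below a
    # robust noise floor (mad_k sigmas of the smoothed background).
    noise_sigma = 1.4826 * float(np.median(np.abs(sub - background)))
    thr = max(_threshold(corrected, cfg), cfg.mad_k * noise_sigma)
    if not np.any(corrected > thr):
        return PointSet.empty(kind)
    peaks = peak_local_max(
        corrected,
        footprint=_separation_footprint(min_separation_um, calib),
        threshold_abs=thr,
        exclude_border=False,
    )
    coords = peaks.astype(float) * np.array(calib.spacing_zyx)
    return PointSet(peaks, coords, kind)


def detect_nuclei(
    stack: ImageStack,
    config: SegmentationConfig | None = None,
) -> PointSet:
    """One centroid per resolvable nucleus in the nuclei channel.

    Gaussian smoothing, median background subtraction, global threshold
    (Otsu by default), then local maxima with a minimum separation of one
    nucleus diameter. Two nuclei closer than the separation merge into one
    detection.
    """
    cfg = config or SegmentationConfig()
    calib = Calibration(stack.voxel_size_xy, stack.z_step)
    channel = stack.channel("nuclei")  # KeyError when the channel is absent
    return _detect_points(channel, calib, cfg, cfg.nucleus_min_separation_um, "nucleus")


def detect_tracker_cells(
    stack: ImageStack,
    config: SegmentationConfig | None = None,
) -> PointSet:
    """Tracker-labeled cell centroids; empty set with a warning when the
    assay is label-free (no tracker channel)."""
    cfg = config or SegmentationConfig()
    if not stack.has_channel("tracker"):
        warnings.warn(
            f"stack {stack.well_id!r} has no tracker channel; returning no labeled cells",
            stacklevel=2,
        )
        return PointSet.empty("tracker_cell")
    calib = Calibration(stack.voxel_size_xy, stack.z_step)
    return _detect_points(
        stack.channel("tracker"), calib, cfg, cfg.tracker_min_separation_um, "tracker_cell"
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_actin_objects(
    stack: ImageStack,
    config: SegmentationConfig | None = None,
) -> LabelVolume:
    """Segment actin-defined structures into 26-connected 3D components.

    smooth -> global threshold (Otsu) -> morphological closing -> per-slice
    hole filling -> connected components -> debris filter (components whose
    volume falls below that of a ``min_object_diameter_um`` sphere).
    An all-background image yields an empty labelling, not an error.
    """
    cfg = config or SegmentationConfig()
    calib = Calibration(stack.voxel_size_xy, stack.z_step)
    img = np.asarray(stack.channel("actin"), dtype=np.float32)
    smoothed = ndimage.gaussian_filter(img, sigma=_sigma_vox(cfg.smooth_sigma_um, calib))
    thr = _threshold(smoothed, cfg)
    mask = smoothed > thr
    # guard against Otsu splitting pure background noise: require real contrast
    if mask.any():
        sub = _subsample(smoothed)
        fg_med = float(np.median(smoothed[mask]))
        bg_med = float(np.median(sub))
        mad = 1.4826 * float(np.median(np.abs(sub - bg_med)))
        if fg_med - bg_med < 4.0 * max(mad, 1e-6):
            mask[:] = False
    if mask.any():
        rz = max(0, int(round(cfg.closing_radius_um / calib.z_step)))
        rxy = max(1, int(round(cfg.closing_radius_um / calib.voxel_size_xy)))
        zz, yy, xx = np.mgrid[-rz : rz + 1, -rxy : rxy + 1, -rxy : rxy + 1]
        structure = (
            (zz / max(rz, 1)) ** 2 + (yy / rxy) ** 2 + (xx / rxy) ** 2
        ) <= 1.0
        mask = ndimage.binary_closing(mask, structure=structure)
        for z in range(mask.shape[0]):
            mask[z] = ndimage.binary_fill_holes(mask[z])
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return LabelVolume(labels.astype(np.int32), {"channel": "actin", "threshold": thr})
    min_voxels = max(
        1,
        int(np.ceil((np.pi / 6.0) * cfg.min_object_diameter_um**3 / calib.voxel_volume_um3)),
    )
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts[1:] >= min_voxels) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return LabelVolume(
        remap[labels],
        {
            "channel": "actin",
            "threshold": float(thr),
            "min_voxels": min_voxels,
            "closing_radius_um": cfg.closing_radius_um,
        },
    )


def classify_objects(
    objects: LabelVolume,
    nuclei: PointSet,
    calibration: Calibration,
    config: ClassificationConfig | None = None,
) -> tuple[LabelVolume, PointSet]:
    """Split actin components into multicellular objects and single cells.

    A component is multicellular iff its equivalent diameter is at least
    ``single_cell_max_diameter_um`` AND it contains at least two nucleus
    centroids; otherwise its nuclei join the single-cell fraction, as do
    nuclei outside any actin component. Every nucleus is assigned exactly
    once, so |single cells| + sum(nuclei in multicellular) = |nuclei|.

    A component above the size cut with a single nucleus is still a single
    cell: the nuclei rule dominates.
    """
    cfg = config or ClassificationConfig()
    if cfg.single_cell_max_diameter_um <= 0:
        raise ValueError("single_cell_max_diameter_um must be positive")
    labels = objects.labels
    n = objects.n_objects
    if len(nuclei):
        owner = labels[nuclei.voxels[:, 0], nuclei.voxels[:, 1], nuclei.voxels[:, 2]]
    else:
        owner = np.empty(0, dtype=int)
    nuc_per_label = np.bincount(owner, minlength=n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    vol_um3 = counts[1:] * calibration.voxel_volume_um3
    eq_diam = (6.0 * vol_um3 / np.pi) ** (1.0 / 3.0)
    multicellular = (eq_diam >= cfg.single_cell_max_diameter_um) & (
        nuc_per_label[1:] >= cfg.min_nuclei_multicellular
    )
    keep = np.flatnonzero(multicellular) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    multi = LabelVolume(
        remap[labels],
        {**objects.provenance, "single_cell_max_diameter_um": cfg.single_cell_max_diameter_um},
    )
    is_single = ~np.isin(owner, keep) if len(nuclei) else np.empty(0, dtype=bool)
    singles = PointSet(nuclei.voxels[is_single], nuclei.coords_um[is_single], "nucleus")
    return multi, singles
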