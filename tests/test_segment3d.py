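"""Segmentation: detection recovery against ground truth, the object
definition (actin component + >=2 nuclei), and the nucleus partition."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from organoidhci.config import Calibration, ClassificationConfig, SegmentationConfig
from organoidhci.io_plate import ImageStack
from organoidhci.segment3d import (
    LabelVolume,
    PointSet,
    classify_objects,
    detect_nuclei,
    detect_tracker_cells,
    segment_actin_objects,
)
from organoidhci.synthetic_plate import (
    EffectModel,
    GeneratorParams,
    ImagingConfig,
    render_well,
    sample_scene,
)

from conftest import blank_stack

CALIB = Calibration(3.4, 25.0)


def sparse_cell_stack(n_cells: int, seed: int, tracker: bool = False):
    """Single cells only, well separated, low noise."""
    params = GeneratorParams(
        field_xy_um=900.0,
        field_z_um=500.0,
        count_range=(1, 1),
        single_cell_count_mean=float(n_cells),
        tracker_labeled=tracker,
        cell_diameter_um=12.0,
    )
    # remove the lone tumoroid so only free cells remain; keep the labeled
    # population by a direct E:T on the (pre-loss) resident estimate
    effect = EffectModel(
        object_loss_fraction=1.0,
        infiltration_rate=0.0,
        effector_target_ratio=1.0 if tracker else 0.0,
    )
    scene = sample_scene(params, effect, seed=seed)
    imaging = ImagingConfig(read_noise_sd=2.0)
    stack = render_well(scene, imaging, seed=seed + 1)
    return scene, stack


class TestDetectNuclei:
    def test_blank_image_yields_no_nuclei(self, noise_stack):
        assert len(detect_nuclei(noise_stack)) == 0

    def test_missing_nuclei_channel_is_an_error(self):
        stack = blank_stack(roles=("actin",))
        with pytest.raises(KeyError):
            detect_nuclei(stack)

    def test_recovers_well_separated_single_cells_within_5pct(self):
        scene, stack = sparse_cell_stack(n_cells=120, seed=31)
        n_true = len(scene.single_cells)
        detected = detect_nuclei(stack)
        assert abs(len(detected) - n_true) <= 0.05 * n_true

    def test_two_blobs_closer_than_min_separation_merge(self):
        shape = (20, 64, 64)
        img = np.full(shape, 100.0, np.float32)
        zz, yy, xx = np.mgrid[:20, :64, :64].astype(float)
        for cy in (30.0, 32.0):  # 2 px = 6.8 um apart, below 10 um separation
            img += 800 * np.exp(
                -(((zz - 10) * 25 / 6) ** 2 + ((yy - cy) * 3.4 / 4) ** 2 + ((xx - 32) * 3.4 / 4) ** 2)
                / 2
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = ImageStack(img[None], {0: "nuclei"}, 3.4, 25.0)
        assert len(detect_nuclei(stack)) == 1


class TestDetectTracker:
    def test_label_free_stack_warns_and_returns_empty(self, noise_stack):
        with pytest.warns(UserWarning, match="tracker"):
            pts = detect_tracker_cells(noise_stack)
        assert len(pts) == 0 and pts.kind == "tracker_cell"

    def test_recovers_labeled_cells_within_5pct(self):
        scene, stack = sparse_cell_stack(n_cells=20, seed=41, tracker=True)
        n_true = len(scene.labeled_cells)
        assert n_true > 20
        detected = detect_tracker_cells(stack)
        assert abs(len(detected) - n_true) <= max(0.05 * n_true, 2)

    def test_labeled_cell_inside_bright_actin_body_is_still_detected(self):
        shape = (20, 48, 48)
        rng = np.random.default_rng(0)
        actin = np.full(shape, 100.0) + rng.normal(0, 3, shape)
        trk = np.full(shape, 100.0) + rng.normal(0, 3, shape)
        zz, yy, xx = np.mgrid[:20, :48, :48].astype(float)
        body = (
            ((zz - 10) * 25) ** 2 + ((yy - 24) * 3.4) ** 2 + ((xx - 24) * 3.4) ** 2
        ) < 60.0**2
        actin[body] += 600.0
        trk += 800 * np.exp(
            -(((zz - 10) * 25 / 6) ** 2 + ((yy - 24) * 3.4 / 4) ** 2 + ((xx - 24) * 3.4 / 4) ** 2)
            / 2
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = ImageStack(
                np.stack([actin, trk]).astype(np.float32),
                {0: "actin", 1: "tracker"},
                3.4,
                25.0,
            )
        pts = detect_tracker_cells(stack)
        assert len(pts) == 1
        assert np.linalg.norm(pts.coords_um[0] - np.array([250.0, 81.6, 81.6])) < 30


class TestSegmentActin:
    def test_blank_image_yields_no_components(self, noise_stack):
        labels = segment_actin_objects(noise_stack)
        assert labels.n_objects == 0

    def test_recovers_tumoroids_one_to_one(self, small_scene, small_stack):
        labels = segment_actin_objects(small_stack)
        k_true = small_scene.tumoroid_count
        assert abs(labels.n_objects - k_true) <= max(1, round(0.05 * k_true))
        # 1:1 matching by centroid distance < one radius
        from scipy import ndimage

        centroids = np.array(
            ndimage.center_of_mass(
                np.ones_like(labels.labels), labels.labels, range(1, labels.n_objects + 1)
            )
        ) * np.array(CALIB.spacing_zyx)
        truth = small_scene.tumoroids[["z_um", "y_um", "x_um"]].to_numpy()
        radii = small_scene.tumoroids["diameter_um"].to_numpy() / 2
        d = cdist(truth, centroids)
        matches = (d < radii[:, None]).any(axis=1)
        assert matches.sum() >= k_true - 1

    def test_touching_tumoroids_merge_into_one_component(self):
        shape = (16, 80, 80)
        rng = np.random.default_rng(1)
        img = np.full(shape, 100.0) + rng.normal(0, 3, shape)
        zz, yy, xx = np.mgrid[:16, :80, :80].astype(float)
        for cy in (110.0, 170.0):  # 60 um apart, radii 30 um each: touching
            body = (
                ((zz - 8) * 25) ** 2 + (yy * 3.4 - cy) ** 2 + ((xx - 40) * 3.4) ** 2
            ) < 30.0**2
            img[body] += 600.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = ImageStack(img[None].astype(np.float32), {0: "actin"}, 3.4, 25.0)
        labels = segment_actin_objects(stack)
        assert labels.n_objects == 1

    def test_labels_are_consecutive_and_shape_matches(self, small_stack):
        labels = segment_actin_objects(small_stack)
        present = np.unique(labels.labels)
        assert present[0] == 0
        assert list(present[1:]) == list(range(1, labels.n_objects + 1))
        assert labels.shape == small_stack.shape_zyx

    def test_intensity_scaling_leaves_counts_unchanged(self, small_stack):
        labels = segment_actin_objects(small_stack)
        nuclei = detect_nuclei(small_stack)
        scaled = ImageStack(
            small_stack.voxels * 3.0,
            dict(small_stack.channel_roles),
            small_stack.voxel_size_xy,
            small_stack.z_step,
        )
        assert segment_actin_objects(scaled).n_objects == labels.n_objects
        assert len(detect_nuclei(scaled)) == len(nuclei)


def _synthetic_component(diam_um: float, n_nuclei: int, seed=0):
    """One actin sphere + n nuclei inside it, on a quiet background."""
    shape = (16, 64, 64)
    rng = np.random.default_rng(seed)
    center = np.array([8 * 25.0, 32 * 3.4, 32 * 3.4])
    actin = np.full(shape, 100.0) + rng.normal(0, 3, shape)
    nuc = np.full(shape, 100.0) + rng.normal(0, 3, shape)
    zz, yy, xx = np.mgrid[:16, :64, :64].astype(float)
    dist = np.sqrt(
        ((zz * 25) - center[0]) ** 2
        + ((yy * 3.4) - center[1]) ** 2
        + ((xx * 3.4) - center[2]) ** 2
    )
    actin[dist < diam_um / 2] += 600.0
    pts = []
    r = max(diam_um / 2 - 6, 1.0)
    for i in range(n_nuclei):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        pts.append(center + u * r * rng.random() ** (1 / 3))
    for p in pts:
        nuc += 900 * np.exp(
            -(
                ((zz * 25 - p[0]) / 6) ** 2
                + ((yy * 3.4 - p[1]) / 4) ** 2
                + ((xx * 3.4 - p[2]) / 4) ** 2
            )
            / 2
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ImageStack(
            np.stack([nuc, actin]).astype(np.float32), {0: "nuclei", 1: "actin"}, 3.4, 25.0
        )


class TestClassifyObjects:
    def test_large_component_with_many_nuclei_is_multicellular(self):
        stack = _synthetic_component(100.0, 40)
        labels = segment_actin_objects(stack)
        nuclei = detect_nuclei(stack)
        multi, singles = classify_objects(labels, nuclei, CALIB)
        assert multi.n_objects == 1

    def test_isolated_nucleus_with_small_shell_is_single_cell(self):
        stack = _synthetic_component(12.0, 1)
        labels = segment_actin_objects(stack)
        nuclei = detect_nuclei(stack)
        multi, singles = classify_objects(labels, nuclei, CALIB)
        assert multi.n_objects == 0
        assert len(singles) == len(nuclei) == 1

    def test_large_component_with_one_nucleus_is_single_cell(self):
        # the nuclei rule dominates the size rule
        stack = _synthetic_component(60.0, 1)
        labels = segment_actin_objects(stack)
        nuclei = detect_nuclei(stack)
        assert labels.n_objects == 1 and len(nuclei) == 1
        multi, singles = classify_objects(labels, nuclei, CALIB)
        assert multi.n_objects == 0
        assert len(singles) == 1

    def test_nucleus_partition_is_exact(self, small_stack):
        labels = segment_actin_objects(small_stack)
        nuclei = detect_nuclei(small_stack)
        multi, singles = classify_objects(labels, nuclei, CALIB)
        inside = 0
        if len(nuclei):
            owner = multi.labels[
                nuclei.voxels[:, 0], nuclei.voxels[:, 1], nuclei.voxels[:, 2]
            ]
            inside = int((owner > 0).sum())
        assert len(singles) + inside == len(nuclei)

    def test_nonpositive_size_cut_rejected(self, small_stack):
        labels = segment_actin_objects(small_stack)
        nuclei = detect_nuclei(small_stack)
        with pytest.raises(ValueError):
            classify_objects(
                labels, nuclei, CALIB, ClassificationConfig(single_cell_max_diameter_um=0)
            )
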