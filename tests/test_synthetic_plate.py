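"""Ground-truth generator: seeding windows, effect semantics, determinism,
and fidelity of the rendered digitization."""

import numpy as np
import pandas as pd
import pytest

from organoidhci.config import Calibration
from organoidhci.synthetic_plate import (
    EffectModel,
    GenerationError,
    GeneratorParams,
    ImagingConfig,
    design_plate,
    render_well,
    sample_scene,
    simulate_plate,
    well_seed,
)


def scenes_equal(a, b) -> bool:
    return (
        a.tumoroids.equals(b.tumoroids)
        and a.tumoroid_nuclei.equals(b.tumoroid_nuclei)
        and a.single_cells.equals(b.single_cells)
        and a.labeled_cells.equals(b.labeled_cells)
    )


class TestSampleScene:
    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_evpt_defaults_respect_seeding_window(self, seed):
        scene = sample_scene(GeneratorParams.evpt_defaults(), seed=seed)
        assert 50 <= scene.tumoroid_count <= 300
        d = scene.tumoroids["diameter_um"]
        assert (d > 50).all() and (d < 200).all()

    def test_null_effect_is_identity(self):
        base = sample_scene(seed=5)
        explicit = sample_scene(effect=EffectModel(volume_reduction_fraction=0.0), seed=5)
        assert scenes_equal(base, explicit)

    def test_volume_reduction_scales_total_volume_exactly(self, small_params):
        null = sample_scene(small_params, EffectModel.null(), seed=9)
        half = sample_scene(
            small_params, EffectModel(volume_reduction_fraction=0.5), seed=9
        )
        assert half.total_volume_um3 == pytest.approx(0.5 * null.total_volume_um3)

    @pytest.mark.parametrize("effect_field", ["volume_reduction_fraction", "object_loss_fraction"])
    def test_total_volume_monotone_in_effect(self, small_params, effect_field):
        totals = [
            sample_scene(
                small_params, EffectModel(**{effect_field: f}), seed=21
            ).total_volume_um3
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_object_loss_removes_a_bernoulli_subset(self, small_params):
        null = sample_scene(small_params, EffectModel.null(), seed=3)
        lost = sample_scene(small_params, EffectModel(object_loss_fraction=0.5), seed=3)
        assert lost.tumoroid_count <= null.tumoroid_count
        # surviving diameters are a subset of the null scene's
        assert set(np.round(lost.tumoroids["diameter_um"], 6)) <= set(
            np.round(null.tumoroids["diameter_um"], 6)
        )

    def test_infiltrated_cells_lie_inside_their_host(self):
        params = GeneratorParams.reconstituted_defaults()
        scene = sample_scene(params, EffectModel(infiltration_rate=0.4), seed=17)
        lab = scene.labeled_cells
        assert 0.2 < lab["infiltrated"].mean() < 0.6
        tum = scene.tumoroids.set_index("tumoroid_id")
        inside = lab[lab["infiltrated"]]
        for row in inside.sample(min(len(inside), 200), random_state=0).itertuples():
            host = tum.loc[int(row.host_tumoroid_id)]
            dist = np.sqrt(
                (row.z_um - host.z_um) ** 2
                + (row.y_um - host.y_um) ** 2
                + (row.x_um - host.x_um) ** 2
            )
            assert dist <= host.diameter_um / 2.0 + 1e-9

    def test_single_cell_growth_factor_increases_count(self, small_params):
        base = sample_scene(small_params, EffectModel.null(), seed=4)
        grown = sample_scene(
            small_params, EffectModel(single_cell_growth_factor=1.0), seed=4
        )
        assert len(grown.single_cells) == 2 * len(base.single_cells)
        # the base population is preserved, growth appends to it
        assert grown.single_cells.iloc[: len(base.single_cells)].equals(base.single_cells)

    def test_effect_model_validates_ranges(self):
        with pytest.raises(ValueError):
            EffectModel(volume_reduction_fraction=1.2)
        with pytest.raises(ValueError):
            EffectModel(single_cell_growth_factor=-0.1)

    def test_infeasible_packing_raises(self):
        params = GeneratorParams(
            field_xy_um=500.0,
            field_z_um=400.0,
            count_range=(80, 80),
            diameter_range_um=(150.0, 190.0),
            diameter_log_median_um=170.0,
            max_place_tries=20,
        )
        with pytest.raises(GenerationError):
            sample_scene(params, seed=0)


class TestRenderWell:
    def test_empty_scene_has_no_foreground(self, small_params, small_imaging):
        scene = sample_scene(
            GeneratorParams(
                field_xy_um=500.0,
                field_z_um=500.0,
                count_range=(1, 1),
                single_cell_count_mean=0.0,
            ),
            EffectModel(object_loss_fraction=1.0),
            seed=2,
        )
        assert scene.tumoroid_count == 0
        stack = render_well(scene, small_imaging, seed=3)
        img = stack.channel("actin")
        bg = np.median(img)
        sigma = 1.4826 * np.median(np.abs(img - bg))
        assert (img > bg + 5 * sigma).mean() < 1e-3

    def test_same_seed_renders_bit_identical_stacks(self, small_scene, small_imaging):
        a = render_well(small_scene, small_imaging, seed=8)
        b = render_well(small_scene, small_imaging, seed=8)
        assert np.array_equal(a.voxels, b.voxels)

    def test_digitized_sphere_volume_matches_analytic(self):
        params = GeneratorParams(
            field_xy_um=500.0,
            field_z_um=400.0,
            count_range=(1, 1),
            diameter_range_um=(99.0, 101.0),
            diameter_log_median_um=100.0,
            diameter_log_sigma=0.05,
            single_cell_count_mean=0.0,
        )
        scene = sample_scene(params, seed=6)
        (d,) = scene.tumoroids["diameter_um"]
        stack = render_well(scene, ImagingConfig(), seed=7)
        img = stack.channel("actin")
        bg = np.median(img)
        sigma = 1.4826 * np.median(np.abs(img - bg))
        bright = img > bg + 5 * sigma
        voxel_vol = 3.4 * 3.4 * 25.0
        measured = bright.sum() * voxel_vol
        analytic = np.pi / 6.0 * d**3
        assert measured == pytest.approx(analytic, rel=0.15)

    def test_tracker_channel_present_only_for_labeled_scenes(self, small_scene, small_imaging):
        stack = render_well(small_scene, small_imaging, seed=1)
        assert not stack.has_channel("tracker")  # evpt scenes are label-free
        recon = sample_scene(
            GeneratorParams.reconstituted_defaults(), EffectModel(), seed=1
        )
        stack2 = render_well(recon, ImagingConfig.survey(), seed=1)
        assert stack2.has_channel("tracker")


class TestSimulatePlate:
    def test_sixteen_well_run_writes_stacks_and_truth(self, tmp_path):
        layout, effects = design_plate(
            {"treated": EffectModel(volume_reduction_fraction=0.5)},
            n_replicates=8,
            assay_kind="evpt",
        )
        assert len(layout.wells) == 16
        params = GeneratorParams(
            field_xy_um=600.0, field_z_um=400.0, count_range=(5, 10),
            diameter_range_um=(50.0, 120.0), diameter_log_median_um=75.0,
            single_cell_count_mean=10.0,
        )
        out = simulate_plate(
            layout, effects, 42, params=params,
            imaging=ImagingConfig.survey(), outdir=tmp_path / "run",
        )
        assert len(out) == 16
        tifs = sorted((tmp_path / "run" / "wells").glob("*.tif"))
        assert len(tifs) == 32  # nuclei + actin per well, label-free
        truth = pd.read_csv(tmp_path / "run" / "truth_tumoroids.csv")
        assert set(truth["well_id"]) == set(layout.wells)
        assert (tmp_path / "run" / "params.toml").exists()

    def test_same_master_seed_reproduces_the_run(self, tmp_path):
        layout, effects = design_plate({}, n_replicates=4, assay_kind="evpt")
        params = GeneratorParams(
            field_xy_um=500.0, field_z_um=400.0, count_range=(3, 6),
            diameter_range_um=(50.0, 100.0), diameter_log_median_um=70.0,
            single_cell_count_mean=5.0,
        )
        runs = []
        for sub in ("a", "b"):
            out = simulate_plate(
                layout, effects, 9, params=params, imaging=ImagingConfig.survey()
            )
            runs.append(out)
        for wid in layout.wells:
            assert np.array_equal(runs[0][wid][0].voxels, runs[1][wid][0].voxels)
            assert runs[0][wid][1].tumoroids.equals(runs[1][wid][1].tumoroids)

    def test_missing_effect_for_condition_raises(self):
        layout, effects = design_plate({}, n_replicates=4)
        layout.frame.loc[0, "condition"] = "mystery"
        with pytest.raises(KeyError, match="mystery"):
            simulate_plate(layout, effects, 0)

    def test_well_seeds_are_stable_and_distinct(self):
        s1 = well_seed(5, "B07", "scene")
        assert s1 == well_seed(5, "B07", "scene")
        assert s1 != well_seed(5, "B08", "scene")
        assert s1 != well_seed(5, "B07", "render")
        assert 0 <= s1 < 2**31
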