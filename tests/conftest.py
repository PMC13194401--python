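"""Shared fixtures: small synthetic wells with known ground truth.

Everything is generated at test time; fixtures use small fields so the
default (fine) calibration stays cheap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from organoidhci.config import Calibration, RunConfig
from organoidhci.synthetic_plate import (
    EffectModel,
    GeneratorParams,
    ImagingConfig,
    render_well,
    sample_scene,
)


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """A desk-sized field with a handful of well-separated tumoroids."""
    return GeneratorParams(
        assay_kind="evpt",
        field_xy_um=800.0,
        field_z_um=500.0,
        count_range=(8, 8),
        diameter_range_um=(50.0, 120.0),
        diameter_log_median_um=80.0,
        diameter_log_sigma=0.25,
        min_gap_um=40.0,
        single_cell_count_mean=40.0,
    )


@pytest.fixture(scope="session")
def small_imaging() -> ImagingConfig:
    return ImagingConfig(calibration=Calibration(voxel_size_xy=3.4, z_step=25.0))


@pytest.fixture(scope="session")
def small_scene(small_params):
    return sample_scene(small_params, EffectModel.null(), seed=11)


@pytest.fixture(scope="session")
def small_stack(small_scene, small_imaging):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return render_well(small_scene, small_imaging, seed=12)


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def blank_stack(shape=(20, 96, 96), roles=("nuclei", "actin"), seed=0, background=100.0):
    """Noise-only stack: constant background + Poisson + read noise."""
    from organoidhci.io_plate import ImageStack

    rng = np.random.default_rng(seed)
    vox = np.stack(
        [
            np.clip(
                rng.poisson(background, size=shape) + rng.normal(0, 5, size=shape), 0, None
            ).astype(np.float32)
            for _ in roles
        ]
    )
    return ImageStack(vox, dict(enumerate(roles)), 3.4, 25.0, well_id="blank")


@pytest.fixture()
def noise_stack():
    return blank_stack()
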