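"""Synthetic 3D well generator with exact ground truth.

Emulates the content of a gel-embedded co-culture well as imaged by
low-magnification whole-well confocal stacks: 50-300 tumoroids (spheres,
log-normal diameters truncated to the seeding window), a population of free
single cells, and optionally tracker-labeled immune cells some of which sit
inside tumoroids ("infiltrated"). Treatment effects are expressed directly on
the ground truth — volume reduction, object loss, infiltration increase,
single-cell proliferation — so every downstream measurement can be scored
against a known answer.

Two parameter presets mirror the two assay formats:

* ``evpt`` — heterogeneous fresh-tissue clusters: per-well tumoroid count
  uniform on [50, 300], diameters truncated to (50, 200) µm, label-free
  (autologous immune cells carry no tracker dye).
* ``reconstituted`` — size-filtered organoids seeded robotically from one
  suspension: Poisson counts around a target density, tighter (40, 150) µm
  size window, tracker-labeled immune cells at a configurable E:T ratio.

All geometry is in physical µm and independent of any imaging calibration;
:func:`render_well` digitizes a scene onto a voxel grid and adds noise.
Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from .config import Calibration, dumps_toml
from .io_plate import ImageStack, PlateLayout, write_stack


class GenerationError(RuntimeError):
    """Requested scene cannot be realized (e.g. infeasible sphere packing)."""


@dataclass(frozen=True)
class EffectModel:
    """Treatment effect applied to a ground-truth scene.

    volume_reduction_fraction
        Fraction of each tumoroid's volume killed; 0 = untouched.
    object_loss_fraction
        Probability that a tumoroid disappears entirely.
    infiltration_rate
        Probability that a labeled immune cell sits inside a tumoroid.
    single_cell_growth_factor
        Fractional *increase* of the single-cell count (0 = none, 1 = doubling),
        so that the all-zero effect is exactly the identity.
    effector_target_ratio
        Labeled immune cells added per (pre-treatment) tumoroid-resident cell.
    """

    volume_reduction_fraction: float = 0.0
    object_loss_fraction: float = 0.0
    infiltration_rate: float = 0.0
    single_cell_growth_factor: float = 0.0
    effector_target_ratio: float = 5.0

    def __post_init__(self) -> None:
        for name in ("volume_reduction_fraction", "object_loss_fraction", "infiltration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.single_cell_growth_factor < 0:
            raise ValueError("single_cell_growth_factor must be >= 0")
        if self.effector_target_ratio < 0:
            raise ValueError("effector_target_ratio must be >= 0")

    @classmethod
    def null(cls) -> "EffectModel":
        return cls()


@dataclass(frozen=True)
class GeneratorParams:
    """Scene geometry parameters (all lengths in µm)."""

    assay_kind: str = "evpt"
    field_xy_um: float = 2000.0
    field_z_um: float = 750.0
    count_range: tuple[int, int] = (50, 300)
    count_model: str = "uniform"  # "uniform" on count_range | "poisson" at count_mean
    count_mean: float = 150.0
    diameter_range_um: tuple[float, float] = (50.0, 200.0)
    diameter_log_median_um: float = 90.0
    diameter_log_sigma: float = 0.35
    min_gap_um: float = 20.0  # surface-to-surface clearance between tumoroids
    nucleus_spacing_um: float = 18.0  # one resident cell per spacing^3
    cell_diameter_um: float = 12.0
    single_cell_count_mean: float = 150.0
    tracker_labeled: bool = False
    max_place_tries: int = 500

    @classmethod
    def evpt_defaults(cls) -> "GeneratorParams":
        return cls()

    @classmethod
    def reconstituted_defaults(cls) -> "GeneratorParams":
        return cls(
            assay_kind="reconstituted",
            count_model="poisson",
            count_mean=150.0,
            diameter_range_um=(40.0, 150.0),
            diameter_log_median_um=70.0,
            diameter_log_sigma=0.25,
            tracker_labeled=True,
        )

    @property
    def nucleus_density_per_um3(self) -> float:
        return 1.0 / self.nucleus_spacing_um**3


@dataclass
class SceneTruth:
    """Exact per-well ground truth emitted by :func:`sample_scene`.

    tumoroids : DataFrame [tumoroid_id, z_um, y_um, x_um, diameter_um,
        volume_um3, nucleus_count]; diameters/volumes are post-effect.
    tumoroid_nuclei : DataFrame [tumoroid_id, z_um, y_um, x_um].
    single_cells : DataFrame [z_um, y_um, x_um].
    labeled_cells : DataFrame [z_um, y_um, x_um, infiltrated, host_tumoroid_id].
    """

    tumoroids: pd.DataFrame
    tumoroid_nuclei: pd.DataFrame
    single_cells: pd.DataFrame
    labeled_cells: pd.DataFrame
    params_used: dict
    effect_used: dict
    seed: int

    @property
    def total_volume_um3(self) -> float:
        return float(self.tumoroids["volume_um3"].sum())

    @property
    def tumoroid_count(self) -> int:
        return len(self.tumoroids)

    @property
    def infiltration_fraction(self) -> float | None:
        if len(self.labeled_cells) == 0:
            return None
        return float(self.labeled_cells["infiltrated"].mean())


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Log-normal draws rejected to the open interval (lo, hi)."""
    out = np.empty(n)
    filled = 0
    for _ in range(200):
        need = n - filled
        if need == 0:
            break
        draws = np.exp(np.log(median) + sigma * rng.standard_normal(need * 2 + 8))
        draws = draws[(draws > lo) & (draws < hi)][:need]
        out[filled : filled + len(draws)] = draws
        filled += len(draws)
    if filled < n:
        raise GenerationError("diameter distribution cannot satisfy the truncation window")
    return out


def _place_spheres(
    rng: np.random.Generator, radii: np.ndarray, params: GeneratorParams
) -> np.ndarray:
    """Non-overlapping sphere centres by rejection (dart throwing), largest first."""
    n = len(radii)
    centers = np.empty((n, 3))
    fz, fxy = params.field_z_um, params.field_xy_um
    for i, r in enumerate(radii):
        lo = np.array([r, r, r])
        hi = np.array([fz - r, fxy - r, fxy - r])
        if np.any(hi <= lo):
            raise GenerationError(
                f"tumoroid radius {r:.0f} um does not fit the "
                f"{fxy:.0f}x{fxy:.0f}x{fz:.0f} um field"
            )
        for _ in range(params.max_place_tries):
            cand = lo + rng.random(3) * (hi - lo)
            if i == 0:
                centers[0] = cand
                break
            d = np.sqrt(((centers[:i] - cand) ** 2).sum(axis=1))
            if np.all(d > radii[:i] + r + params.min_gap_um):
                centers[i] = cand
                break
        else:
            raise GenerationError(
                f"could not place tumoroid {i + 1}/{n} without overlap "
                f"after {params.max_place_tries} tries"
            )
    return centers


def _points_in_sphere(
    rng: np.random.Generator, n: int, center: np.ndarray, radius: float
) -> np.ndarray:
    direction = rng.standard_normal((n, 3))
    direction /= np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-12)
    rad = radius * rng.random(n) ** (1.0 / 3.0)
    return center + direction * rad[:, None]


def _darts_in_sphere(
    rng: np.random.Generator, n: int, center: np.ndarray, radius: float, min_sep: float
) -> np.ndarray:
    """Approximately blue-noise points inside a sphere: oversample, then thin
    to at most one point per spatial-hash cell of size ~min_sep/sqrt(3).
    Relaxed (plain uniform fill) when the sphere is too crowded."""
    cands = _points_in_sphere(rng, max(3 * n, 16), center, radius)
    cell = np.floor(cands / max(min_sep / np.sqrt(3.0), 1e-6)).astype(np.int64)
    key = (
        cell[:, 0] * 73856093 ^ cell[:, 1] * 19349663 ^ cell[:, 2] * 83492791
    )
    _, first = np.unique(key, return_index=True)
    chosen = cands[np.sort(first)][:n]
    if len(chosen) < n:  # crowded: fill the remainder without the constraint
        extra = _points_in_sphere(rng, n - len(chosen), center, radius)
        chosen = np.concatenate([chosen, extra], axis=0)
    return chosen


def _points_outside_spheres(
    rng: np.random.Generator,
    n: int,
    params: GeneratorParams,
    centers: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Uniform points in the field, rejected from tumoroid interiors."""
    margin = params.cell_diameter_um / 2.0
    lo = np.array([margin] * 3)
    span = np.array(
        [params.field_z_um, params.field_xy_um, params.field_xy_um]
    ) - 2 * margin
    out = np.empty((n, 3))
    filled = 0
    for _ in range(100):
        if filled == n:
            break
        need = n - filled
        cand = lo + rng.random((need + 16, 3)) * span
        if len(centers):
            keep = np.ones(len(cand), dtype=bool)
            for start in range(0, len(cand), 4096):
                blk = cand[start : start + 4096]
                d = cdist(blk, centers)
                keep[start : start + 4096] = np.all(d > radii[None, :], axis=1)
            cand = cand[keep]
        cand = cand[: n - filled]
        out[filled : filled + len(cand)] = cand
        filled += len(cand)
    if filled < n:
        raise GenerationError("field too crowded to place free cells")
    return out


def sample_scene(
    params: GeneratorParams | None = None,
    effect: EffectModel | None = None,
    seed: int = 0,
) -> SceneTruth:
    """Draw one well's ground truth.

    The tumoroid count is drawn from the configured count model, diameters
    from a truncated log-normal, centres by non-overlap rejection sampling.
    The effect then scales volumes by (1 - volume_reduction_fraction),
    removes a Bernoulli(object_loss_fraction) subset, grows the single-cell
    population, and places labeled cells inside surviving tumoroids with
    probability ``infiltration_rate``. Reproducible per (params, effect, seed).
    """
    params = params or GeneratorParams.evpt_defaults()
    effect = effect or EffectModel.null()
    lo_d, hi_d = params.diameter_range_um
    if not 0 < lo_d < hi_d:
        raise ValueError("diameter range must satisfy 0 < lo < hi")
    if hi_d >= min(params.field_xy_um, params.field_z_um):
        raise ValueError("diameter range exceeds the field extent")
    if params.count_range[0] < 1 or params.count_range[0] > params.count_range[1]:
        raise ValueError("count range must be positive and ordered")

    ss = np.random.SeedSequence(seed)
    rng_geom, rng_nuc, rng_single, rng_label, rng_eff = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- base geometry (independent of the effect) ---
    if params.count_model == "uniform":
        n_base = int(rng_geom.integers(params.count_range[0], params.count_range[1] + 1))
    elif params.count_model == "poisson":
        n_base = int(
            np.clip(rng_geom.poisson(params.count_mean), *params.count_range)
        )
    else:
        raise ValueError(f"unknown count_model {params.count_model!r}")
    diameters = _truncated_lognormal(
        rng_geom, n_base, params.diameter_log_median_um, params.diameter_log_sigma, lo_d, hi_d
    )
    diameters = np.sort(diameters)[::-1]  # large first eases packing
    centers = _place_spheres(rng_geom, diameters / 2.0, params)
    base_volumes = (np.pi / 6.0) * diameters**3
    n_single_base = int(rng_single.poisson(params.single_cell_count_mean))

    # --- effect draws (fixed-length streams keep losses nested across fractions) ---
    loss_u = rng_eff.random(n_base)
    survive = loss_u >= effect.object_loss_fraction

    eff_volumes = base_volumes * (1.0 - effect.volume_reduction_fraction)
    eff_diameters = (6.0 * eff_volumes / np.pi) ** (1.0 / 3.0)

    idx = np.flatnonzero(survive)
    tumoroids = pd.DataFrame(
        {
            "tumoroid_id": np.arange(len(idx)),
            "z_um": centers[idx, 0],
            "y_um": centers[idx, 1],
            "x_um": centers[idx, 2],
            "diameter_um": eff_diameters[idx],
            "volume_um3": eff_volumes[idx],
        }
    )

    # --- resident nuclei inside surviving (shrunken) tumoroids ---
    density = params.nucleus_density_per_um3
    nuc_rows = []
    counts = np.zeros(len(idx), dtype=int)
    for j, i in enumerate(idx):
        n_nuc = max(2, int(rng_nuc.poisson(eff_volumes[i] * density)))
        pts = _darts_in_sphere(
            rng_nuc,
            n_nuc,
            centers[i],
            max(eff_diameters[i] / 2.0 - params.cell_diameter_um / 4.0, 1.0),
            0.7 * params.nucleus_spacing_um,
        )
        counts[j] = n_nuc
        nuc_rows.append(
            pd.DataFrame({"tumoroid_id": j, "z_um": pts[:, 0], "y_um": pts[:, 1], "x_um": pts[:, 2]})
        )
    tumoroids["nucleus_count"] = counts
    tumoroid_nuclei = (
        pd.concat(nuc_rows, ignore_index=True)
        if nuc_rows
        else pd.DataFrame(columns=["tumoroid_id", "z_um", "y_um", "x_um"])
    )

    # --- free single cells (base population + treatment-induced growth) ---
    n_single = n_single_base + int(round(n_single_base * effect.single_cell_growth_factor))
    singles = _points_outside_spheres(
        rng_single, n_single, params, centers[idx], eff_diameters[idx] / 2.0
    )
    single_cells = pd.DataFrame(
        {"z_um": singles[:, 0], "y_um": singles[:, 1], "x_um": singles[:, 2]}
    )

    # --- tracker-labeled immune cells at the configured E:T ratio ---
    if params.tracker_labeled and effect.effector_target_ratio > 0:
        # PBMC input is fixed at seeding: scale to the pre-effect resident count
        n_labeled = int(round(effect.effector_target_ratio * density * base_volumes.sum()))
    else:
        n_labeled = 0
    if n_labeled > 0:
        infil_u = rng_label.random(n_labeled)
        infiltrated = infil_u < effect.infiltration_rate
        pos = np.empty((n_labeled, 3))
        host = np.full(n_labeled, -1)
        n_in = int(infiltrated.sum())
        if n_in and len(idx):
            probs = eff_volumes[idx] / eff_volumes[idx].sum()
            hosts = rng_label.choice(len(idx), size=n_in, p=probs)
            where = np.flatnonzero(infiltrated)
            for k, h in zip(where, hosts):
                pos[k] = _points_in_sphere(
                    rng_label, 1, centers[idx[h]], 0.9 * eff_diameters[idx[h]] / 2.0
                )[0]
                host[k] = h
        elif n_in:
            infiltrated[:] = False  # nothing left to infiltrate
        n_out = int((~infiltrated).sum())
        if n_out:
            pos[~infiltrated] = _points_outside_spheres(
                rng_label, n_out, params, centers[idx], eff_diameters[idx] / 2.0
            )
        labeled_cells = pd.DataFrame(
            {
                "z_um": pos[:, 0],
                "y_um": pos[:, 1],
                "x_um": pos[:, 2],
                "infiltrated": infiltrated,
                "host_tumoroid_id": host,
            }
        )
    else:
        labeled_cells = pd.DataFrame(
            columns=["z_um", "y_um", "x_um", "infiltrated", "host_tumoroid_id"]
        ).astype({"infiltrated": bool, "host_tumoroid_id": int})

    return SceneTruth(
        tumoroids=tumoroids,
        tumoroid_nuclei=tumoroid_nuclei,
        single_cells=single_cells,
        labeled_cells=labeled_cells,
        params_used=asdict(params),
        effect_used=asdict(effect),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingConfig:
    """Digitization and noise model for :func:`render_well`.

    Signal is rendered in photon-count-like units on top of a constant
    background, then passed through Poisson shot noise plus Gaussian read
    noise — the standard first-order camera model.
    """

    calibration: Calibration = field(default_factory=Calibration)
    background: float = 100.0
    read_noise_sd: float = 5.0
    actin_intensity: float = 600.0
    nucleus_peak: float = 900.0
    tracker_peak: float = 800.0
    nucleus_sigma_xy_um: float = 4.0
    nucleus_sigma_z_um: float = 6.0
    shell_thickness_um: float = 3.0
    actin_blur_um: float = 2.5
    intensity_jitter: float = 0.25

    @classmethod
    def survey(cls) -> "ImagingConfig":
        """Coarse whole-plate sampling: 8 µm lateral pixels, 37.5 µm z-step.

        Same physical field, ~8x fewer voxels than the default calibration;
        used for plate-scale runs where per-object precision is secondary.
        """
        return cls(calibration=Calibration(voxel_size_xy=8.0, z_step=37.5))


def _grid_shape(params_used: dict, calib: Calibration) -> tuple[int, int, int]:
    nz = max(1, int(round(params_used["field_z_um"] / calib.z_step)))
    nxy = max(1, int(round(params_used["field_xy_um"] / calib.voxel_size_xy)))
    return nz, nxy, nxy


def _kernel_peak(sigma_vox: tuple[float, float, float]) -> float:
    """Peak of the unit-impulse response of a Gaussian filter at this sigma."""
    size = [max(3, int(8 * s) | 1) for s in sigma_vox]
    imp = np.zeros(size)
    imp[size[0] // 2, size[1] // 2, size[2] // 2] = 1.0
    return float(ndimage.gaussian_filter(imp, sigma=sigma_vox).max())


def _deposit(img: np.ndarray, pts_um: np.ndarray, amps: np.ndarray, calib: Calibration) -> None:
    if len(pts_um) == 0:
        return
    spacing = np.array(calib.spacing_zyx)
    ijk = np.round(pts_um / spacing).astype(int)
    for ax in range(3):
        np.clip(ijk[:, ax], 0, img.shape[ax] - 1, out=ijk[:, ax])
    np.add.at(img, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), amps)


def _sphere_local(
    shape: tuple[int, int, int], center_um: np.ndarray, radius_um: float, calib: Calibration
):
    """Bounding box slices + physical distance grid for one sphere."""
    spacing = np.array(calib.spacing_zyx)
    lo = np.maximum(np.floor((center_um - radius_um - spacing) / spacing), 0).astype(int)
    hi = np.minimum(
        np.ceil((center_um + radius_um + spacing) / spacing) + 1, np.array(shape)
    ).astype(int)
    if np.any(hi <= lo):
        return None, None
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    axes = [
        (np.arange(l, h) * s - c) for l, h, s, c in zip(lo, hi, spacing, center_um)
    ]
    dist = np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )
    return sl, dist


def render_well(
    scene: SceneTruth, imaging: ImagingConfig | None = None, seed: int = 0
) -> ImageStack:
    """Digitize a scene onto a voxel grid and add camera noise.

    Nuclei channel: Gaussian blobs at every nucleus (tumoroid-resident,
    single-cell, labeled-cell). Actin channel: filled tumoroid bodies plus
    thin shells around free single cells. Tracker channel (only when the
    scene carries labeled cells): blobs at labeled-cell positions.
    """
    imaging = imaging or ImagingConfig()
    calib = imaging.calibration
    shape = _grid_shape(scene.params_used, calib)
    rng = np.random.default_rng(seed)
    jit = imaging.intensity_jitter

    sigma_vox = (
        imaging.nucleus_sigma_z_um / calib.z_step,
        imaging.nucleus_sigma_xy_um / calib.voxel_size_xy,
        imaging.nucleus_sigma_xy_um / calib.voxel_size_xy,
    )
    peak_per_unit = _kernel_peak(sigma_vox)

    # nuclei channel
    nuc = np.zeros(shape, dtype=np.float64)
    pts = []
    for df in (scene.tumoroid_nuclei, scene.single_cells, scene.labeled_cells):
        if len(df):
            pts.append(df[["z_um", "y_um", "x_um"]].to_numpy(float))
    all_nuc = np.concatenate(pts, axis=0) if pts else np.empty((0, 3))
    amps = imaging.nucleus_peak / peak_per_unit * (
        1.0 + jit * (rng.random(len(all_nuc)) - 0.5)
    )
    _deposit(nuc, all_nuc, amps, calib)
    nuc = ndimage.gaussian_filter(nuc, sigma=sigma_vox)

    # actin channel
    act = np.zeros(shape, dtype=np.float64)
    h = calib.voxel_size_xy  # soft partial-volume edge, ~one lateral voxel
    for row in scene.tumoroids.itertuples():
        c = np.array([row.z_um, row.y_um, row.x_um])
        r = row.diameter_um / 2.0
        sl, dist = _sphere_local(shape, c, r, calib)
        if sl is None:
            continue
        w = np.clip((r + h / 2.0 - dist) / h, 0.0, 1.0)
        level = imaging.actin_intensity * (1.0 + jit * (rng.random() - 0.5))
        np.maximum(act[sl], level * w, out=act[sl])
    cell_r = scene.params_used["cell_diameter_um"] / 2.0
    shell_level = 0.6 * imaging.actin_intensity
    for row in scene.single_cells.itertuples():
        c = np.array([row.z_um, row.y_um, row.x_um])
        sl, dist = _sphere_local(shape, c, cell_r + imaging.shell_thickness_um, calib)
        if sl is None:
            continue
        w = (np.abs(dist - cell_r) <= imaging.shell_thickness_um / 2.0).astype(float)
        if not w.any():  # sub-voxel cell: mark its centre voxel
            w.flat[np.argmin(dist)] = 1.0
        np.maximum(act[sl], shell_level * w, out=act[sl])
    if imaging.actin_blur_um > 0:
        act = ndimage.gaussian_filter(
            act,
            sigma=(
                imaging.actin_blur_um / calib.z_step,
                imaging.actin_blur_um / calib.voxel_size_xy,
                imaging.actin_blur_um / calib.voxel_size_xy,
            ),
        )

    channels = [("nuclei", nuc), ("actin", act)]

    if len(scene.labeled_cells):
        trk = np.zeros(shape, dtype=np.float64)
        lab = scene.labeled_cells[["z_um", "y_um", "x_um"]].to_numpy(float)
        amps = imaging.tracker_peak / peak_per_unit * (
            1.0 + jit * (rng.random(len(lab)) - 0.5)
        )
        _deposit(trk, lab, amps, calib)
        trk = ndimage.gaussian_filter(trk, sigma=sigma_vox)
        channels.append(("tracker", trk))

    voxels = np.empty((len(channels),) + shape, dtype=np.float32)
    roles: dict[int, str] = {}
    for i, (role, signal) in enumerate(channels):
        noisy = rng.poisson(signal + imaging.background).astype(np.float32)
        noisy += rng.normal(0.0, imaging.read_noise_sd, size=shape).astype(np.float32)
        voxels[i] = np.clip(noisy, 0.0, None)
        roles[i] = role

    import warnings as _warnings

    with _warnings.catch_warnings():
        # synthetic stacks may legitimately use coarse survey sampling
        _warnings.simplefilter("ignore")
        return ImageStack(
            voxels,
            roles,
            calib.voxel_size_xy,
            calib.z_step,
            well_id=f"seed{scene.seed}",
        )


# ---------------------------------------------------------------------------
# whole plates
# ---------------------------------------------------------------------------


def well_seed(master_seed: int, well_id: str, purpose: str) -> int:
    """Stable per-well sub-seed derived from the master seed (< 2**31)."""
    key = f"{master_seed}:{well_id}:{purpose}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def simulate_plate(
    layout: PlateLayout,
    effects: Mapping[str, EffectModel],
    master_seed: int,
    params: GeneratorParams | None = None,
    imaging: ImagingConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[str, tuple[ImageStack, SceneTruth]]:
    """Simulate every well of a layout; optionally write a run directory.

    Each well gets deterministic sub-seeds hashed from (master_seed, well_id),
    so wells are independent and the whole plate is reproducible. Every
    condition present in the layout must have an :class:`EffectModel`; the
    control condition conventionally maps to the null effect.

    Wells of one sample are aliquots of one tissue suspension, so when the
    generator's count model is the across-sample "uniform" window, a single
    per-sample seeding density is drawn from that window and the individual
    wells scatter around it with Poisson counting statistics. (An explicit
    "poisson" count model is used as-is for every well.)
    """
    if params is None:
        params = (
            GeneratorParams.reconstituted_defaults()
            if layout.assay_kind == "reconstituted"
            else GeneratorParams.evpt_defaults()
        )
    imaging = imaging or ImagingConfig()
    missing = set(layout.frame["condition"]) - set(effects)
    if missing:
        raise KeyError(f"no EffectModel for conditions: {sorted(missing)}")

    well_params: dict[str, GeneratorParams] = {}
    if params.count_model == "uniform":
        lo, hi = params.count_range
        for sample in layout.frame["sample_id"].unique():
            r = np.random.default_rng(well_seed(master_seed, str(sample), "density"))
            target = int(r.integers(lo, hi + 1))
            well_params[str(sample)] = dataclasses.replace(
                params, count_model="poisson", count_mean=float(target)
            )

    out: dict[str, tuple[ImageStack, SceneTruth]] = {}
    for row in layout.frame.itertuples():
        scene = sample_scene(
            well_params.get(str(row.sample_id), params),
            effects[row.condition],
            seed=well_seed(master_seed, row.well_id, "scene"),
        )
        stack = render_well(scene, imaging, seed=well_seed(master_seed, row.well_id, "render"))
        stack.well_id = row.well_id
        out[row.well_id] = (stack, scene)

    if outdir is not None:
        outdir = Path(outdir)
        wells_dir = outdir / "wells"
        wells_dir.mkdir(parents=True, exist_ok=True)
        truth_t, truth_s, truth_l = [], [], []
        for wid, (stack, scene) in out.items():
            write_stack(stack, wells_dir)
            truth_t.append(scene.tumoroids.assign(well_id=wid))
            truth_s.append(scene.single_cells.assign(well_id=wid))
            truth_l.append(scene.labeled_cells.assign(well_id=wid))
        pd.concat(truth_t, ignore_index=True).to_csv(
            outdir / "truth_tumoroids.csv", index=False, lineterminator="\n"
        )
        pd.concat(truth_s, ignore_index=True).to_csv(
            outdir / "truth_single_cells.csv", index=False, lineterminator="\n"
        )
        pd.concat(truth_l, ignore_index=True).to_csv(
            outdir / "truth_labeled_cells.csv", index=False, lineterminator="\n"
        )
        layout.to_csv(outdir / "layout.csv")
        meta = {
            "master_seed": int(master_seed),
            "generator": asdict(params),
            "imaging": {
                **{
                    k: v
                    for k, v in asdict(imaging).items()
                    if not isinstance(v, dict)
                },
                "calibration": asdict(imaging.calibration),
            },
            "effects": {k: asdict(v) for k, v in effects.items()},
        }
        (outdir / "params.toml").write_text(dumps_toml(meta))
    return out


def design_plate(
    condition_effects: Mapping[str, EffectModel],
    n_replicates: int,
    sample_id: str = "S1",
    assay_kind: str = "evpt",
    plate_format: int = 384,
    control_condition: str = "control",
    extra_controls: int = 0,
) -> tuple[PlateLayout, dict[str, EffectModel]]:
    """Build a layout assigning conditions round-robin across wells.

    Round-robin assignment scatters every condition (controls included)
    over the plate surface, so edge and interior positions are represented
    in each group. The control condition is added with a null effect if not
    already present in ``condition_effects``.
    """
    from .io_plate import _PLATE_DIMS, well_name  # local to avoid cycle noise

    effects = dict(condition_effects)
    effects.setdefault(control_condition, EffectModel.null())
    conditions = [control_condition] + [c for c in effects if c != control_condition]
    assignments: list[str] = []
    for rep in range(n_replicates):
        assignments.extend(conditions)
    assignments.extend([control_condition] * extra_controls)

    nrow, ncol = _PLATE_DIMS[plate_format]
    if len(assignments) > nrow * ncol:
        raise ValueError("design does not fit the plate")
    rows = []
    for i, cond in enumerate(assignments):
        wid = well_name(i // ncol, i % ncol)
        rows.append(
            {
                "well_id": wid,
                "sample_id": sample_id,
                "condition": cond,
                "dose": np.nan,
                "dose_units": "",
                "replicate_group": f"{sample_id}:{cond}",
                "is_control": cond == control_condition,
            }
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # replicate-count conventions vary by design
        layout = PlateLayout(pd.DataFrame(rows), plate_format=plate_format, assay_kind=assay_kind)
    return layout, effects
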