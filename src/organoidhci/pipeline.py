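"""End-to-end plate analysis: measure every well, gate quality, normalize to
controls, summarize replicates, and run the group statistics.

The pipeline is deterministic: identical stacks + layout + configuration
produce byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .analyze import (
    GroupComparison,
    NormalizationError,
    READOUTS,
    aggregate_replicates,
    classify_response,
    compare_groups,
    percent_of_control,
)
from .config import RunConfig
from .io_plate import (
    ImageStack,
    NORMALIZED_COLUMNS,
    PlateLayout,
    read_layout,
    read_stack,
    write_measurements,
)
from .qc import FLAG_CONTROL, QCReport, control_window_qc, image_well_qc, plate_qc_report
from .quantify import WellMeasurement, measure_well, wells_to_frame


@dataclass
class PlateResult:
    wells: pd.DataFrame
    measurements: list[WellMeasurement]
    qc: QCReport
    per_well_poc: pd.DataFrame
    normalized: pd.DataFrame
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)

    @property
    def samples_pass_qc(self) -> bool:
        return all(self.qc.sample_verdicts.values())


def analyze_plate(
    stacks: Mapping[str, ImageStack],
    layout: PlateLayout,
    config: RunConfig | None = None,
) -> PlateResult:
    """Analyze an in-memory plate of stacks against its layout."""
    config = config or RunConfig()
    measurements: list[WellMeasurement] = []
    layout_df = layout.frame.set_index("well_id")

    for wid in layout.wells:
        if wid not in stacks:
            w = WellMeasurement(well_id=wid)
            w.qc_flags.append("analysis_failed")
            measurements.append(w)
            continue
        stack = stacks[wid]
        well, inter = measure_well(stack, config, return_intermediates=True)
        if not well.qc_flags:
            ok, reasons = image_well_qc(stack, inter.get("actin"), config.qc)
            if not ok:
                well.qc_flags.append("fail_image_quality")
                well.qc_flags.extend(reasons)
        measurements.append(well)

    # control-window gate on control wells
    by_well = {w.well_id: w for w in measurements}
    for sample, sub in layout.frame.groupby("sample_id"):
        controls = [
            by_well[wid]
            for wid in sub.loc[sub["is_control"], "well_id"]
            if wid in by_well and not by_well[wid].qc_flags
        ]
        if not controls:
            continue
        frame, _ = control_window_qc(
            controls, config.qc.min_control_objects, config.qc.min_control_volume_mm3
        )
        for row in frame.itertuples():
            if not row.control_window_pass:
                by_well[row.well_id].qc_flags.append(FLAG_CONTROL)

    qc_report = plate_qc_report(measurements, layout, config.qc)
    excluded = set(qc_report.excluded_wells)

    wells_df = wells_to_frame(measurements)
    meta_cols = ["sample_id", "condition", "dose", "replicate_group", "is_control"]
    wells_df = wells_df.merge(
        layout.frame[["well_id"] + meta_cols], on="well_id", how="left"
    )

    # --- percent-of-control per sample and readout ---
    poc_rows = []
    norm_rows = []
    for sample, sub in wells_df.groupby("sample_id"):
        control_wells = list(sub.loc[sub["is_control"], "well_id"])
        for readout in READOUTS:
            values = sub.set_index("well_id")[readout].astype(float)
            ctrl_vals = values[values.index.isin(control_wells)].dropna()
            if ctrl_vals.empty:
                continue  # readout not available for this sample (e.g. label-free)
            try:
                poc = percent_of_control(
                    values.dropna(),
                    control_wells,
                    exclusions=excluded,
                    control_summary=config.normalization.control_summary,
                )
            except NormalizationError:
                continue
            for wid, v in poc.items():
                poc_rows.append(
                    {"sample_id": sample, "well_id": wid, "readout": readout, "poc": v}
                )
            for group, g in sub.groupby("replicate_group"):
                g_poc = poc[poc.index.isin(g["well_id"])]
                if g_poc.empty:
                    continue
                summary = aggregate_replicates(g_poc, readout)
                reduction = 100.0 - summary["poc_summary"]
                norm_rows.append(
                    {
                        "sample_id": sample,
                        "condition": g["condition"].iloc[0],
                        "dose": g["dose"].iloc[0],
                        "readout": readout,
                        **summary,
                        "reduction_percent": reduction,
                        "response_category": (
                            classify_response(reduction)
                            if readout == "total_volume_mm3"
                            else ""
                        ),
                    }
                )
    per_well_poc = pd.DataFrame(
        poc_rows, columns=["sample_id", "well_id", "readout", "poc"]
    )
    normalized = pd.DataFrame(norm_rows, columns=NORMALIZED_COLUMNS)
    if len(normalized):
        normalized = normalized.sort_values(
            ["sample_id", "readout", "condition", "dose"]
        ).reset_index(drop=True)

    # --- group statistics: Dunnett vs control on total-volume poc ---
    comparisons: dict[str, GroupComparison] = {}
    vol_poc = per_well_poc[per_well_poc["readout"] == "total_volume_mm3"]
    for sample, sub in wells_df.groupby("sample_id"):
        merged = sub.merge(
            vol_poc[vol_poc["sample_id"] == sample][["well_id", "poc"]], on="well_id"
        )
        ctrl_conditions = merged.loc[merged["is_control"], "condition"].unique()
        if merged["condition"].nunique() < 2 or len(ctrl_conditions) != 1:
            continue
        try:
            comparisons[str(sample)] = compare_groups(
                merged, value="poc", group="condition", reference=str(ctrl_conditions[0])
            )
        except ValueError:
            continue

    return PlateResult(
        wells=wells_df,
        measurements=measurements,
        qc=qc_report,
        per_well_poc=per_well_poc,
        normalized=normalized,
        comparisons=comparisons,
    )


def load_run_stacks(
    indir: str | Path, layout: PlateLayout, config: RunConfig
) -> dict[str, ImageStack]:
    """Read the per-well channel TIFFs of a run directory."""
    indir = Path(indir)
    wells_dir = indir / "wells" if (indir / "wells").is_dir() else indir
    stacks: dict[str, ImageStack] = {}
    calib = config.calibration
    for wid in layout.wells:
        paths = {
            role: wells_dir / f"{wid}_{role}.tif"
            for role in ("nuclei", "actin", "tracker")
            if (wells_dir / f"{wid}_{role}.tif").exists()
        }
        if not paths:
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stacks[wid] = read_stack(
                paths, calib.voxel_size_xy, calib.z_step, well_id=wid
            )
    return stacks


def analyze_run(
    indir: str | Path,
    layout: PlateLayout | str | Path,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PlateResult:
    """Disk-to-disk plate analysis; writes the standard table set to outdir."""
    config = config or RunConfig()
    if not isinstance(layout, PlateLayout):
        layout = read_layout(layout)
    stacks = load_run_stacks(indir, layout, config)
    if not stacks:
        raise FileNotFoundError(f"no well stacks found under {indir}")
    result = analyze_plate(stacks, layout, config)
    if outdir is not None:
        write_result(result, outdir, config)
    return result


def write_result(
    result: PlateResult, outdir: str | Path, config: RunConfig | None = None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_measurements(result.wells, outdir / "wells.csv")
    write_measurements(result.per_well_poc, outdir / "per_well_poc.csv")
    write_measurements(result.normalized, outdir / "normalized.csv")
    write_measurements(result.qc.per_well, outdir / "qc_flags.csv")
    write_measurements(result.qc.group_cvs, outdir / "qc_group_cvs.csv")
    comp_frames = []
    for sample, comp in result.comparisons.items():
        comp_frames.append(comp.comparisons.assign(sample_id=sample, method=comp.method))
    comp = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(
            columns=["group_1", "group_2", "mean_diff", "p_adj", "stars", "sample_id", "method"]
        )
    )
    write_measurements(comp, outdir / "comparisons.csv")
    (outdir / "report.txt").write_text(result.qc.summary_text() + "\n")
    if config is not None:
        config.to_toml(outdir / "config_used.toml")
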