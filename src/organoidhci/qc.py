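"""Well- and plate-level quality gates and precision metrics.

The control-window gate enforces a measurable assay window: a control well
passes iff it holds at least ``min_control_objects`` multicellular objects
(default 50) AND at least ``min_control_volume_mm3`` cumulative volume
(default 0.01 mm³), both inclusive. Image-quality gates catch empty wells,
debris/overgrowth, weak staining, and segmentations that fail to represent
the input image. Replicate precision is scored as the coefficient of
variation (sample SD / mean), and edge wells are compared against interior
wells to flag positional artifacts. A healthy plate excludes well under 4%
of its wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCConfig
from .io_plate import ImageStack, PlateLayout
from .quantify import WellMeasurement
from .segment3d import LabelVolume

FLAG_PASS = "pass"
FLAG_CONTROL = "fail_control_window"
FLAG_IMAGE = "fail_image_quality"
FLAG_ANALYSIS = "analysis_failed"


class QCError(ValueError):
    pass


def control_window_qc(
    controls: list[WellMeasurement],
    min_objects: int = 50,
    min_total_volume_mm3: float = 0.01,
) -> tuple[pd.DataFrame, bool]:
    """Per-control-well pass/fail against the assay-window gate + sample verdict.

    The thresholds are inclusive ("at least"). The sample verdict fails when
    more than half of the control wells fail (the gate is stated per well;
    the aggregation fraction is configurable at the caller).
    """
    if not controls:
        raise QCError("control-window QC requires at least one control well")
    rows = []
    for w in controls:
        ok = (w.object_count >= min_objects) and (
            w.total_volume_mm3 >= min_total_volume_mm3
        )
        rows.append(
            {
                "well_id": w.well_id,
                "object_count": w.object_count,
                "total_volume_mm3": w.total_volume_mm3,
                "control_window_pass": bool(ok),
            }
        )
    frame = pd.DataFrame(rows)
    verdict = bool(frame["control_window_pass"].mean() > 0.5)
    return frame, verdict


def image_well_qc(
    stack: ImageStack,
    labels: LabelVolume | None = None,
    config: QCConfig | None = None,
) -> tuple[bool, list[str]]:
    """Image-quality gate on the actin (segmentation) channel.

    Fails on: foreground fraction outside configured bounds (empty well or
    debris/overgrowth), weak labeling (median foreground < k x background),
    or a segmentation covering too little of the bright signal (the output
    no longer represents the input).
    """
    cfg = config or QCConfig()
    reasons: list[str] = []
    from .segment3d import _subsample

    img = np.asarray(stack.channel("actin"), dtype=np.float32)
    sub = _subsample(img)
    background = float(np.median(sub))
    # if even the median sits far above the darkest voxels, the majority of
    # the well is bright: overgrowth/debris, and the background estimate is
    # meaningless, so stop here
    p5 = float(np.percentile(sub, 5))
    if background > max(2.0 * p5, p5 + 50.0):
        return False, ["debris_or_overgrowth"]
    sigma = 1.4826 * float(np.median(np.abs(sub - background)))
    fg = img > background + 5.0 * max(sigma, 1e-6)
    frac = float(fg.mean())
    lo, hi = cfg.foreground_fraction_bounds
    if frac < lo:
        reasons.append("low_foreground")
    elif frac > hi:
        reasons.append("debris_or_overgrowth")
    if frac >= lo and background > 0:
        ratio = float(np.median(img[fg])) / background
        if ratio < cfg.min_label_intensity_ratio:
            reasons.append("low_label_intensity")
    if labels is not None and frac >= lo and not reasons:
        # the check targets missing structures; tolerate one-voxel
        # partial-volume halos around label boundaries
        from scipy import ndimage as _ndi

        lab_mask = _ndi.binary_dilation(
            labels.labels > 0, structure=np.ones((3, 3, 3), bool)
        )
        covered = float(lab_mask[fg].mean())
        if covered < cfg.min_segmentation_coverage:
            reasons.append("segmentation_coverage")
    return (not reasons), reasons


def cv_percent(values) -> float:
    """Coefficient of variation: sample standard deviation / mean.

    Requires at least two values and a nonzero mean. Scale-invariant:
    cv(c*x) == cv(x) for any c > 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise QCError(f"CV needs >= 2 values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise QCError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def edge_effect_check(
    wells: list[WellMeasurement],
    layout: PlateLayout,
    config: QCConfig | None = None,
) -> dict:
    """Rank-sum comparison of edge vs interior control-well total volumes.

    Verdict "edge_effect" requires both statistical evidence (two-sided
    Wilcoxon rank-sum p below the configured cutoff) and a practically
    relevant shift (edge/interior median ratio outside the configured band).
    Fewer than three wells on either side -> "not_evaluable".
    """
    cfg = config or QCConfig()
    df = layout.frame.set_index("well_id")
    edge, interior = [], []
    for w in wells:
        if w.well_id not in df.index or not df.loc[w.well_id, "is_control"]:
            continue
        (edge if df.loc[w.well_id, "is_edge"] else interior).append(w.total_volume_mm3)
    if len(edge) < 3 or len(interior) < 3:
        return {
            "verdict": "not_evaluable",
            "p_value": np.nan,
            "median_ratio": np.nan,
            "n_edge": len(edge),
            "n_interior": len(interior),
        }
    stat = stats.mannwhitneyu(edge, interior, alternative="two-sided")
    med_int = float(np.median(interior))
    ratio = float(np.median(edge)) / med_int if med_int else np.inf
    lo, hi = cfg.edge_ratio_bounds
    flagged = stat.pvalue < cfg.edge_p_threshold and not (lo <= ratio <= hi)
    return {
        "verdict": "edge_effect" if flagged else "no_edge_effect",
        "p_value": float(stat.pvalue),
        "median_ratio": ratio,
        "n_edge": len(edge),
        "n_interior": len(interior),
    }


@dataclass
class QCReport:
    """Aggregated plate QC: per-well flags, exclusion rate, replicate CVs,
    edge verdict."""

    per_well: pd.DataFrame  # well_id, flag
    exclusion_fraction: float
    group_cvs: pd.DataFrame  # replicate_group, n, cv_total_volume
    edge: dict
    sample_verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def excluded_wells(self) -> list[str]:
        """Wells dropped from analysis for any reason (well errors plus
        control-window failures)."""
        return list(self.per_well.loc[self.per_well["flag"] != FLAG_PASS, "well_id"])

    def summary_text(self) -> str:
        n_err = int(self.per_well["flag"].isin([FLAG_IMAGE, FLAG_ANALYSIS]).sum())
        n_window = int((self.per_well["flag"] == FLAG_CONTROL).sum())
        lines = [
            f"wells assayed: {len(self.per_well)}",
            f"well errors (image/analysis): {n_err} "
            f"({100 * self.exclusion_fraction:.2f}%)",
            f"control wells outside assay window: {n_window}",
            f"edge verdict: {self.edge.get('verdict', 'n/a')}",
        ]
        for sample, ok in self.sample_verdicts.items():
            lines.append(f"sample {sample}: {'PASS' if ok else 'QC FAILED'}")
        if len(self.group_cvs):
            worst = self.group_cvs.sort_values("cv_total_volume").iloc[-1]
            lines.append(
                f"worst replicate CV (total volume): {worst.cv_total_volume:.3f} "
                f"({worst.replicate_group})"
            )
        return "\n".join(lines)


def plate_qc_report(
    wells: list[WellMeasurement],
    layout: PlateLayout,
    config: QCConfig | None = None,
) -> QCReport:
    """Combine per-well flags into the plate-level report.

    ``exclusion_fraction`` = wells lost to image-quality or analysis errors /
    assayed wells — the "well error" rate of the plate; a warning is raised
    when it reaches the configured ceiling (default 4%). Control-window
    failures are an assay-window verdict, not a well error: they appear in
    the per-well flags and drive the per-sample verdicts instead.
    """
    cfg = config or QCConfig()
    df = layout.frame.set_index("well_id")
    rows = []
    by_sample_controls: dict[str, list[WellMeasurement]] = {}
    for w in wells:
        if w.qc_flags:
            flag = FLAG_ANALYSIS if FLAG_ANALYSIS in w.qc_flags else w.qc_flags[0]
        else:
            flag = FLAG_PASS
        rows.append({"well_id": w.well_id, "flag": flag})
        if w.well_id in df.index and df.loc[w.well_id, "is_control"]:
            by_sample_controls.setdefault(str(df.loc[w.well_id, "sample_id"]), []).append(w)
    per_well = pd.DataFrame(rows, columns=["well_id", "flag"])
    n = len(per_well)
    excluded = int(per_well["flag"].isin([FLAG_IMAGE, FLAG_ANALYSIS]).sum())
    fraction = excluded / n if n else 0.0
    if fraction >= cfg.max_exclusion_fraction:
        warnings.warn(
            f"{excluded}/{n} wells excluded "
            f"({100 * fraction:.1f}% >= {100 * cfg.max_exclusion_fraction:.0f}% ceiling)",
            stacklevel=2,
        )

    ok_wells = {r["well_id"] for r in rows if r["flag"] == FLAG_PASS}
    vols = {w.well_id: w.total_volume_mm3 for w in wells}
    cv_rows = []
    for group, sub in layout.frame.groupby("replicate_group"):
        vals = [vols[wid] for wid in sub["well_id"] if wid in ok_wells and wid in vols]
        if len(vals) >= 2 and np.mean(vals) != 0:
            cv_rows.append(
                {"replicate_group": group, "n": len(vals), "cv_total_volume": cv_percent(vals)}
            )
    group_cvs = pd.DataFrame(cv_rows, columns=["replicate_group", "n", "cv_total_volume"])

    sample_verdicts: dict[str, bool] = {}
    for sample, controls in by_sample_controls.items():
        frame, _ = control_window_qc(
            controls, cfg.min_control_objects, cfg.min_control_volume_mm3
        )
        fail_frac = 1.0 - frame["control_window_pass"].mean()
        sample_verdicts[sample] = bool(fail_frac <= cfg.control_fail_fraction)

    edge = edge_effect_check(wells, layout, cfg)
    return QCReport(
        per_well=per_well,
        exclusion_fraction=fraction,
        group_cvs=group_cvs,
        edge=edge,
        sample_verdicts=sample_verdicts,
    )
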