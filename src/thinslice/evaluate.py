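"""End-to-end phantom study: degrade, generate, measure, categorize, agree.

For every phantom series the thin-slice volume is degraded 4x into a
thick-slice volume; the trained generator (and optionally interpolation
baselines) turn the thick volume back into generated-thin slices.  Each
nodule is then re-segmented by fixed thresholds in every condition,
measured, typed from its HU histogram, and Lung-RADS categorized.  The
thin-slice condition plays ground truth, as in a reader study where the
thin-slice software result is the reference.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .degrade import simulate_thick, upsample_z
from .nodules import (LungRADSTable, agreement, classify_type, image_quality,
                      measure_volumes, paired_agreement, segment_nodule)
from .phantom import CohortSeries
from .training import generate
from .volume import CTVolume

SEGMENT_MARGIN_MM = 2.0


def evaluate_volume_nodules(vol: CTVolume, nodules, table: LungRADSTable,
                            condition: str, series_id: int) -> pd.DataFrame:
    """Measure and categorize every nodule of one series in one condition."""
    rows = []
    for i, nod in enumerate(nodules):
        total, solid = segment_nodule(
            vol, nod.center_mm, nod.radius_mm + SEGMENT_MARGIN_MM)
        if not total.any():
            # nodule entirely lost in this rendering: report zero-ish volume
            rows.append({"series_id": series_id, "nodule_id": i,
                         "condition": condition, "type": "GGN",
                         "total_mm3": 0.0, "solid_mm3": 0.0,
                         "category": "2"})
            continue
        ntype = classify_type(vol.voxels[total])
        m = measure_volumes(total, solid, vol.spacing, nodule_type=ntype)
        rows.append({"series_id": series_id, "nodule_id": i,
                     "condition": condition, "type": ntype,
                     "total_mm3": m.total_volume_mm3,
                     "solid_mm3": m.solid_volume_mm3,
                     "category": table.categorize(m)})
    return pd.DataFrame(rows)


@dataclass
class StudyResult:
    """Per-nodule report plus agreement of each condition against thin."""

    report: pd.DataFrame
    agreements: dict          # condition -> CategoryAgreement (vs thin)
    paired: object            # thick vs generated, reference thin
    image_metrics: pd.DataFrame


def run_study(cohort: list[CohortSeries], checkpoint: dict, r: int = 4,
              table: LungRADSTable | None = None,
              conditions=("thick", "generated", "thin")) -> StudyResult:
    """Run the three-condition nodule study over a phantom cohort."""
    table = table or LungRADSTable.default()
    frames = []
    metrics = []
    for sid, series in enumerate(cohort):
        thin = series.volume
        thick = simulate_thick(thin, r)
        vols = {"thin": thin, "thick": thick}
        if "generated" in conditions:
            gen_thin = generate(checkpoint, thick, r)
            vols["generated"] = gen_thin
            z = gen_thin.z_len
            psnr, ssim = image_quality(
                CTVolume(thin.voxels[:z], thin.spacing), gen_thin)
            metrics.append({"series_id": sid, "condition": "generated",
                            "psnr_db": psnr, "ssim": ssim})
            interp = upsample_z(thick, r, order=3)
            psnr_i, ssim_i = image_quality(
                CTVolume(thin.voxels[:interp.z_len], thin.spacing), interp)
            metrics.append({"series_id": sid, "condition": "tricubic",
                            "psnr_db": psnr_i, "ssim": ssim_i})
        for cond in conditions:
            frames.append(evaluate_volume_nodules(
                vols[cond], series.nodules, table, cond, sid))
    report = pd.concat(frames, ignore_index=True)

    ref = report[report.condition == "thin"].sort_values(
        ["series_id", "nodule_id"])
    agreements = {}
    preds = {}
    for cond in conditions:
        if cond == "thin":
            continue
        sub = report[report.condition == cond].sort_values(
            ["series_id", "nodule_id"])
        preds[cond] = list(sub.category)
        agreements[cond] = agreement(list(sub.category), list(ref.category))
    paired = None
    if "thick" in preds and "generated" in preds:
        paired = paired_agreement(preds["thick"], preds["generated"],
                                  list(ref.category))
    return StudyResult(report=report, agreements=agreements, paired=paired,
                       image_metrics=pd.DataFrame(metrics))
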