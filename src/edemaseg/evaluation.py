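"""Scan-level orchestration, the HU-threshold reference annotation, and the
four accuracy metrics (IoU, DSC, AVD, RVD).

A scan is an ordered stack of slices; each slice is segmented independently
and the per-slice masks are combined into the scan-level result. Metrics are
pooled over all voxels of a scan: IoU and DSC as percentages, AVD as the
absolute volume difference in liters (voxel count x pixel area x slice
thickness, mm^3 -> L), RVD as AVD over the reference volume in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .gmm import classify_edema_gmm, fit_gmm_em
from .histograms import PriorModel
from .imaging import BinaryMask, DensityImage, SliceStack, apply_mask
from .levelset import LevelSetParams, run_segmentation

__all__ = [
    "MetricsReport",
    "reference_annotation",
    "segment_scan",
    "compute_metrics",
    "compare_annotations",
    "count_recovered_components",
    "ANNOTATION_HU_WINDOW",
]

#: Inclusive HU window used to seed manual edema annotation.
ANNOTATION_HU_WINDOW = (-50.0, 50.0)

MM3_PER_LITER = 1e6


@dataclass(frozen=True)
class MetricsReport:
    """Overlap and volume agreement between a predicted and a reference stack.

    ``rvd_pct`` is None when the reference is empty (undefined ratio).
    """

    iou_pct: float
    dsc_pct: float
    avd_liters: float
    rvd_pct: float | None
    voxel_volume_mm3: float
    per_slice: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.iou_pct <= self.dsc_pct <= 100 or
                (self.iou_pct == self.dsc_pct == 0)):
            raise ValueError("require 0 <= IoU <= DSC <= 100")
        if self.avd_liters < 0:
            raise ValueError("AVD must be >= 0")

    def to_dict(self) -> dict:
        return {"iou_pct": self.iou_pct, "dsc_pct": self.dsc_pct,
                "avd_liters": self.avd_liters, "rvd_pct": self.rvd_pct,
                "voxel_volume_mm3": self.voxel_volume_mm3,
                "per_slice": list(self.per_slice)}


def reference_annotation(image: DensityImage, adipose_mask: BinaryMask,
                         window: tuple[float, float] = ANNOTATION_HU_WINDOW
                         ) -> BinaryMask:
    """Threshold a slice to the [-50, 50] HU window (inclusive) inside the
    subcutaneous adipose mask.

    This reproduces the automatable stages of the annotation protocol; the
    subsequent manual edit passes (removing non-edema, adding missed edema)
    are not automatable and are not modelled.
    """
    if image.shape != adipose_mask.shape:
        raise ValueError("image and mask shapes differ")
    lo, hi = window
    labeled = (image.values >= lo) & (image.values <= hi) \
        & adipose_mask.as_bool()
    return BinaryMask(values=labeled.astype(np.uint8))


def _as_mask_list(stack) -> list[BinaryMask]:
    return list(stack)


def segment_scan(stack: SliceStack, masks: SliceStack, prior: PriorModel,
                 params: LevelSetParams | None = None,
                 method: str = "cv_prior") -> tuple[SliceStack, list[dict]]:
    """Segment every slice of a scan and combine the results.

    ``method='cv_prior'`` runs the prior-constrained level set;
    ``method='gmm'`` fits the two-class mixture per slice and labels by MAP.
    A slice whose segmentation fails (degenerate fit, vanished contour) is
    returned empty and flagged rather than aborting the scan.
    """
    if method not in ("cv_prior", "gmm"):
        raise ValueError(f"unknown method {method!r}")
    if len(stack) != len(masks):
        raise ValueError("image and mask stacks are misaligned")
    params = params or LevelSetParams()
    out: list[BinaryMask] = []
    flags: list[dict] = []
    for i, (image, mask) in enumerate(zip(stack, masks)):
        if image.shape != mask.shape:
            raise ValueError(f"slice {i}: image and mask shapes differ")
        flag = {"slice": i, "ok": True, "note": ""}
        try:
            if method == "gmm":
                values = apply_mask(image, mask).masked_values()
                fitted = fit_gmm_em(values)
                pred = classify_edema_gmm(image, mask, fitted)
            else:
                pred, trace = run_segmentation(image, mask, prior, params)
                if trace["contour_vanished"]:
                    flag.update(ok=False, note="contour vanished")
        except (ValueError, RuntimeError) as exc:
            pred = BinaryMask(values=np.zeros(image.shape, dtype=np.uint8))
            flag.update(ok=False, note=str(exc))
        out.append(pred)
        flags.append(flag)
    return SliceStack(tuple(out), metadata={"method": method}), flags


def compute_metrics(pred, ref, spacing: tuple[float, float],
                    thickness: float) -> MetricsReport:
    """Pooled IoU/DSC (percent) and AVD (liters) / RVD (percent) over a scan.

    ``pred`` and ``ref`` are aligned stacks (or lists) of binary masks.
    """
    pred_list, ref_list = _as_mask_list(pred), _as_mask_list(ref)
    if len(pred_list) != len(ref_list):
        raise ValueError("prediction and reference stacks are misaligned")
    voxel_mm3 = float(spacing[0]) * float(spacing[1]) * float(thickness)
    inter = union = n_pred = n_ref = 0
    per_slice = []
    for i, (p, r) in enumerate(zip(pred_list, ref_list)):
        if p.shape != r.shape:
            raise ValueError(f"slice {i}: mask shapes differ")
        pb, rb = p.as_bool(), r.as_bool()
        s_inter = int((pb & rb).sum())
        s_union = int((pb | rb).sum())
        inter += s_inter
        union += s_union
        n_pred += int(pb.sum())
        n_ref += int(rb.sum())
        per_slice.append({
            "slice": i,
            "iou_pct": 100.0 * s_inter / s_union if s_union else 100.0,
            "dsc_pct": (200.0 * s_inter / (pb.sum() + rb.sum())
                        if (pb.sum() + rb.sum()) else 100.0),
            "pred_voxels": int(pb.sum()), "ref_voxels": int(rb.sum()),
        })
    iou = 100.0 * inter / union if union else 100.0
    dsc = 200.0 * inter / (n_pred + n_ref) if (n_pred + n_ref) else 100.0
    vol_pred = n_pred * voxel_mm3 / MM3_PER_LITER
    vol_ref = n_ref * voxel_mm3 / MM3_PER_LITER
    avd = abs(vol_pred - vol_ref)
    rvd = 100.0 * avd / vol_ref if vol_ref > 0 else None
    return MetricsReport(iou_pct=iou, dsc_pct=dsc, avd_liters=avd, rvd_pct=rvd,
                         voxel_volume_mm3=voxel_mm3,
                         per_slice=tuple(per_slice))


def compare_annotations(a, b, spacing: tuple[float, float],
                        thickness: float) -> MetricsReport:
    """Pairwise inter-observer comparison: metrics of ``a`` against ``b`` as
    reference. IoU/DSC/AVD are symmetric; RVD is directional (over ``b``)."""
    return compute_metrics(a, b, spacing, thickness)


def count_recovered_components(pred: BinaryMask, truth: BinaryMask) -> int:
    """Number of connected components of the ground truth that the prediction
    touches (8-connectivity). Measures how many distinct edema foci survive."""
    labels, n = ndimage.label(truth.as_bool(), structure=np.ones((3, 3)))
    if n == 0:
        return 0
    hit = np.unique(labels[pred.as_bool() & (labels > 0)])
    return int(hit.size)
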