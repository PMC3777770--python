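"""Segmentation quality metrics and agreement statistics.

Lesion masks are compared by absolute volume difference percent, average
symmetric surface distance (mm, Euclidean between boundary voxel centres),
and true/false positive rates — voxel-wise over a stated domain or
component-wise (a reference lesion counts as detected if any segmented voxel
overlaps it).  Across-case agreement uses Bland-Altman limits and the
Pearson correlation of paired volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .core import BinaryMask, boundary_mask, connected_components

__all__ = [
    "ConfusionCounts", "EvaluationReport", "AgreementReport",
    "volume_difference_percent", "average_symmetric_surface_distance",
    "tpr_fpr_voxelwise", "tpr_fpr_componentwise", "dice",
    "bland_altman", "pearson_r", "evaluate_lesions", "bland_altman_plot",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    vol_diff: float          # percent
    avg_dist: float          # mm
    tpr: float               # percent
    fpr: float               # percent
    mode: str                # "voxelwise" or "componentwise"
    dice: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AgreementReport:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def volume_difference_percent(ref_volume: float, seg_volume: float) -> float:
    """|reference - segmented| / reference * 100."""
    if ref_volume <= 0:
        raise ValueError("reference volume must be positive")
    return abs(ref_volume - seg_volume) / ref_volume * 100.0


def _boundary_points_mm(mask: BinaryMask) -> np.ndarray:
    coords = np.argwhere(boundary_mask(mask).mask)
    return coords * np.asarray(mask.spacing)[None, :]


def average_symmetric_surface_distance(ref: BinaryMask, seg: BinaryMask) -> float:
    """Mean over both boundary sets of nearest-boundary distance (mm).

    (sum_{x in dSeg} min_{y in dRef} d(x,y) + sum_{x in dRef} min_{y in dSeg}
    d(x,y)) / (|dSeg| + |dRef|), with exact Euclidean distances between voxel
    centres using the grid spacing.
    """
    if not ref.mask.any() or not seg.mask.any():
        raise ValueError("surface distance undefined for an empty mask")
    p_ref = _boundary_points_mm(ref)
    p_seg = _boundary_points_mm(seg)
    d_seg_to_ref, _ = cKDTree(p_ref).query(p_seg)
    d_ref_to_seg, _ = cKDTree(p_seg).query(p_ref)
    return float((d_seg_to_ref.sum() + d_ref_to_seg.sum())
                 / (len(p_seg) + len(p_ref)))


def tpr_fpr_voxelwise(ref: BinaryMask, seg: BinaryMask, domain: BinaryMask,
                      ) -> Tuple[float, float, ConfusionCounts]:
    """Voxel-level TPR = TP*100/(TP+FN), FPR = FP*100/(FP+TN) over ``domain``."""
    if not domain.mask.any():
        raise ValueError("empty evaluation domain")
    if np.any(ref.mask & ~domain.mask) or np.any(seg.mask & ~domain.mask):
        raise ValueError("ref and seg must lie inside the domain")
    r = ref.mask[domain.mask]
    s = seg.mask[domain.mask]
    counts = ConfusionCounts(
        tp=int(np.sum(r & s)), fp=int(np.sum(~r & s)),
        fn=int(np.sum(r & ~s)), tn=int(np.sum(~r & ~s)))
    if counts.tp + counts.fn == 0:
        raise ValueError("no reference positives: TPR undefined")
    if counts.fp + counts.tn == 0:
        raise ValueError("no reference negatives: FPR undefined")
    tpr = counts.tp * 100.0 / (counts.tp + counts.fn)
    fpr = counts.fp * 100.0 / (counts.fp + counts.tn)
    return tpr, fpr, counts


def tpr_fpr_componentwise(ref: BinaryMask, seg: BinaryMask,
                          connectivity: int = 26) -> Tuple[float, float]:
    """Lesion-level rates: TP = reference components overlapping the
    segmentation, FP = segmented components with no reference overlap;
    FPR denominator is FP + overlapping segmented components."""
    if ref.shape != seg.shape:
        raise ValueError("grid mismatch")
    if not ref.mask.any():
        raise ValueError("empty reference: component TPR undefined")
    ref_comp = connected_components(ref, connectivity)
    tp = sum(1 for c in range(1, ref_comp.n_components + 1)
             if np.any(seg.mask[ref_comp.labels == c]))
    fn = ref_comp.n_components - tp
    if seg.mask.any():
        seg_comp = connected_components(seg, connectivity)
        tp_seg = sum(1 for c in range(1, seg_comp.n_components + 1)
                     if np.any(ref.mask[seg_comp.labels == c]))
        fp = seg_comp.n_components - tp_seg
    else:
        tp_seg = fp = 0
    tpr = tp * 100.0 / (tp + fn)
    fpr = fp * 100.0 / (fp + tp_seg) if (fp + tp_seg) > 0 else 0.0
    return tpr, fpr


def dice(a: BinaryMask, b: BinaryMask) -> float:
    denom = a.count() + b.count()
    if denom == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int(np.sum(a.mask & b.mask)) / denom


def bland_altman(pairs: Sequence[Tuple[float, float]]) -> tuple[AgreementReport, np.ndarray]:
    """Bias and 95% limits of agreement for paired measurements.

    diffs = a - b; limits = mean(diff) +/- 1.96 * sd(diff) with the n-1
    sample standard deviation.  Also returns the (average, difference)
    points for plotting.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need >= 2 (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    report = AgreementReport(mean_diff, sd, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    return report, np.column_stack([means, diffs])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length sequences of >= 2 values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_lesions(ref: BinaryMask, seg: BinaryMask, domain: BinaryMask,
                     mode: str = "componentwise",
                     connectivity: int = 26) -> EvaluationReport:
    """Full lesion report: vol diff, avg dist, TPR/FPR (chosen mode), Dice."""
    vd = volume_difference_percent(ref.volume_mm3(), seg.volume_mm3())
    ad = (average_symmetric_surface_distance(ref, seg)
          if ref.mask.any() and seg.mask.any() else float("nan"))
    if mode == "voxelwise":
        tpr, fpr, _ = tpr_fpr_voxelwise(ref, seg, domain)
    elif mode == "componentwise":
        tpr, fpr = tpr_fpr_componentwise(ref, seg, connectivity)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EvaluationReport(vd, ad, tpr, fpr, mode, dice=dice(ref, seg))


def bland_altman_plot(pairs: Sequence[Tuple[float, float]], path=None):
    """Standard Bland-Altman scatter with bias and limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report, points = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(points[:, 0], points[:, 1], s=12)
    for v, style in ((report.mean_diff, "-"), (report.loa_low, "--"),
                     (report.loa_high, "--")):
        ax.axhline(v, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("average of methods")
    ax.set_ylabel("difference between methods")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return report, fig
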