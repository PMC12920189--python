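"""Multi-level validation of segmentation outputs.

Three levels of evaluation are provided, mirroring how perioperative
segmentation models are benchmarked:

* **patient-wise** — is the structure present at all?  Ground truth and
  prediction are called positive when their volume reaches the per-structure
  cut-off; a positive pair counts as a true positive only when the voxel-wise
  Dice exceeds a (permissive, 0.1%) threshold.  Recall, precision,
  specificity and balanced accuracy summarize the confusion counts.
* **voxel-wise** — Dice, recall, precision (all in %) and the symmetric 95th
  percentile Hausdorff surface distance (HD95, mm).
* **object-wise** — connected components are size-filtered (75 voxels, 50
  for NETC), matched one-to-one with the Hungarian algorithm on 1 - Dice
  cost, and per-pair voxel-wise metrics are averaged with unmatched
  components contributing zeros.

Per-sample records are evaluated over a sweep of binarization thresholds;
fold results are pooled into concatenated-sample mean/SD estimates; a
sensitivity analysis re-runs the patient-wise classification under stricter
true-positive Dice thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .preprocessing import connected_components, mask_volume_ml
from .types import BinaryMask, ProbabilityMap, ThresholdPolicy, require_same_grid

__all__ = [
    "ClassificationCounts",
    "FoldStats",
    "threshold_sweep",
    "patientwise_outcome",
    "classification_metrics",
    "voxelwise_metrics",
    "hd95",
    "pair_components",
    "objectwise_metrics",
    "evaluate_sample",
    "pooled_estimates",
    "select_best_threshold",
    "sensitivity_analysis",
]

DEFAULT_SENSITIVITY_THRESHOLDS = (0.1, 10.0, 25.0, 50.0, 75.0)


@dataclass
class ClassificationCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_outcomes(cls, outcomes: Sequence[str]) -> "ClassificationCounts":
        c = cls()
        for o in outcomes:
            setattr(c, o, getattr(c, o) + 1)
        return c


@dataclass
class FoldStats:
    """Per-fold summary: sample count plus per-metric mean and SD."""

    fold_id: str
    n: int
    means: Dict[str, float]
    sds: Dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("fold must contain at least one sample")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("standard deviations must be non-negative")


def threshold_sweep(
    pm: ProbabilityMap, n: int = 10
) -> List[Tuple[float, BinaryMask]]:
    """Binarize a probability map at n equally-spaced thresholds k/n, k=1..n.

    The resulting masks are nested: the mask at a higher threshold is a
    subset of the mask at any lower one.
    """
    if n < 2:
        raise ValueError(f"need at least 2 thresholds, got {n}")
    out = []
    for k in range(1, n + 1):
        t = k / n
        out.append((t, BinaryMask(pm.values >= t, pm.spacing, pm.origin)))
    return out


def patientwise_outcome(
    gt: BinaryMask,
    pred: BinaryMask,
    structure: str,
    policy: ThresholdPolicy,
    tp_dice_pct: Optional[float] = None,
) -> str:
    """Patient-level outcome (TP / FP / TN / FN) for one sample.

    Positivity of either mask means its volume reaches the structure's
    cut-off.  A positive/positive pair is a TP only when the voxel-wise Dice
    exceeds ``tp_dice_pct`` (defaults to the policy's 0.1%).
    """
    require_same_grid(gt, pred)
    cutoff = policy.cutoff_for(structure)
    if tp_dice_pct is None:
        tp_dice_pct = policy.patientwise_tp_dice_pct
    gt_pos = mask_volume_ml(gt) >= cutoff
    pred_pos = mask_volume_ml(pred) >= cutoff
    if gt_pos:
        if not pred_pos:
            return "FN"
        dice = voxelwise_metrics(gt, pred)["dice"]
        return "TP" if dice is not None and dice > tp_dice_pct else "FN"
    return "FP" if pred_pos else "TN"


def _pct(num: float, den: float) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def classification_metrics(c: ClassificationCounts) -> Dict[str, Optional[float]]:
    """Recall, precision, specificity and balanced accuracy in %, ``None``
    where a denominator is zero."""
    recall = _pct(c.TP, c.TP + c.FN)
    precision = _pct(c.TP, c.TP + c.FP)
    specificity = _pct(c.TN, c.TN + c.FP)
    bacc = (
        (recall + specificity) / 2.0
        if recall is not None and specificity is not None
        else None
    )
    return {"recall": recall, "precision": precision, "specificity": specificity,
            "bAcc": bacc}


def _surface_coords_mm(values: np.ndarray, spacing) -> np.ndarray:
    eroded = ndimage.binary_erosion(values, border_value=0)
    surface = values & ~eroded
    return np.argwhere(surface) * np.asarray(spacing)


def hd95(gt: BinaryMask, pred: BinaryMask) -> Optional[float]:
    """Symmetric 95th-percentile Hausdorff surface distance in mm.

    Defined as the maximum of the two directed 95th-percentile distances
    between the masks' surface voxels.  Both masks empty: 0; exactly one
    empty: undefined (``None``).
    """
    require_same_grid(gt, pred)
    a_empty, b_empty = gt.voxel_count == 0, pred.voxel_count == 0
    if a_empty and b_empty:
        return 0.0
    if a_empty or b_empty:
        return None
    a = _surface_coords_mm(gt.values, gt.spacing)
    b = _surface_coords_mm(pred.values, pred.spacing)
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def voxelwise_metrics(gt: BinaryMask, pred: BinaryMask) -> Dict[str, Optional[float]]:
    """Dice, recall and precision (in %) plus HD95 (mm) between two masks.

    Two empty masks agree perfectly (Dice 100, HD95 0); one empty mask gives
    Dice 0 and an undefined HD95.
    """
    require_same_grid(gt, pred)
    n_gt, n_pred = gt.voxel_count, pred.voxel_count
    inter = int((gt.values & pred.values).sum())
    if n_gt == 0 and n_pred == 0:
        return {"dice": 100.0, "recall": 100.0, "precision": 100.0, "hd95": 0.0}
    dice = 100.0 * 2.0 * inter / (n_gt + n_pred)
    return {
        "dice": dice,
        "recall": _pct(inter, n_gt),
        "precision": _pct(inter, n_pred),
        "hd95": hd95(gt, pred),
    }


def pair_components(
    gt_labels: np.ndarray, pred_labels: np.ndarray
) -> Tuple[List[Tuple[int, int, float]], List[int], List[int]]:
    """One-to-one component matching by the Hungarian algorithm.

    Inputs are labelled component arrays (already size-filtered).  The
    assignment minimizes total (1 - pairwise Dice); pairs with zero voxel
    overlap are never matched.  Returns matched ``(gt_label, pred_label,
    dice_pct)`` triples plus the unmatched labels of each side.
    """
    gt_ids = [int(v) for v in np.unique(gt_labels) if v != 0]
    pred_ids = [int(v) for v in np.unique(pred_labels) if v != 0]
    if not gt_ids or not pred_ids:
        return [], gt_ids, pred_ids

    gt_sizes = {g: int((gt_labels == g).sum()) for g in gt_ids}
    pred_sizes = {p: int((pred_labels == p).sum()) for p in pred_ids}
    cost = np.ones((len(gt_ids), len(pred_ids)))
    dice_mat = np.zeros_like(cost)
    for i, g in enumerate(gt_ids):
        overlap_labels = pred_labels[gt_labels == g]
        counts = np.bincount(overlap_labels)
        for p_idx, p in enumerate(pred_ids):
            inter = counts[p] if p < len(counts) else 0
            if inter > 0:
                dice = 2.0 * inter / (gt_sizes[g] + pred_sizes[p])
                dice_mat[i, p_idx] = dice
                cost[i, p_idx] = 1.0 - dice
    rows, cols = linear_sum_assignment(cost)
    pairs, matched_g, matched_p = [], set(), set()
    for i, j in zip(rows, cols):
        if dice_mat[i, j] > 0:
            pairs.append((gt_ids[i], pred_ids[j], 100.0 * dice_mat[i, j]))
            matched_g.add(gt_ids[i])
            matched_p.add(pred_ids[j])
    return (
        pairs,
        [g for g in gt_ids if g not in matched_g],
        [p for p in pred_ids if p not in matched_p],
    )


def objectwise_metrics(
    gt: BinaryMask, pred: BinaryMask, structure: str, policy: ThresholdPolicy
) -> Dict[str, Optional[float]]:
    """Component-detection metrics for one sample.

    Components below the structure's minimum size are discarded; survivors
    are Hungarian-matched.  Dice/recall/precision are means over matched
    pairs with every unmatched ground-truth component contributing 0 to Dice
    and recall and every unmatched predicted component contributing 0 to
    Dice and precision.  HD95 is averaged over matched pairs only.  With no
    surviving components on either side all values are ``None``.
    """
    require_same_grid(gt, pred)
    min_vox = policy.min_voxels_for(structure)
    gt_labels, gt_counts = connected_components(gt, 26, min_voxels=min_vox)
    pred_labels, pred_counts = connected_components(pred, 26, min_voxels=min_vox)
    if not gt_counts and not pred_counts:
        return {"dice": None, "recall": None, "precision": None, "hd95": None}

    pairs, un_gt, un_pred = pair_components(gt_labels, pred_labels)
    dices, recalls, precisions, hds = [], [], [], []
    for g, p, _ in pairs:
        g_mask = BinaryMask(gt_labels == g, gt.spacing, gt.origin)
        p_mask = BinaryMask(pred_labels == p, gt.spacing, gt.origin)
        vw = voxelwise_metrics(g_mask, p_mask)
        dices.append(vw["dice"])
        recalls.append(vw["recall"])
        precisions.append(vw["precision"])
        if vw["hd95"] is not None:
            hds.append(vw["hd95"])
    dices += [0.0] * (len(un_gt) + len(un_pred))
    recalls += [0.0] * len(un_gt)
    precisions += [0.0] * len(un_pred)

    def _mean(vals):
        return float(np.mean(vals)) if vals else None

    return {
        "dice": _mean(dices),
        "recall": _mean(recalls),
        "precision": _mean(precisions),
        "hd95": _mean(hds),
    }


def evaluate_sample(
    gt: BinaryMask,
    pred: BinaryMask,
    structure: str,
    policy: ThresholdPolicy,
    sample_id: str = "",
    fold: str = "0",
    threshold: float = 0.5,
) -> dict:
    """All metric levels for one (ground truth, prediction) pair, as a flat
    record suitable for a DataFrame row."""
    vw = voxelwise_metrics(gt, pred)
    ow = objectwise_metrics(gt, pred, structure, policy)
    cutoff = policy.cutoff_for(structure)
    return {
        "sample_id": sample_id,
        "structure": structure,
        "fold": fold,
        "threshold": threshold,
        "gt_volume_ml": mask_volume_ml(gt),
        "pred_volume_ml": mask_volume_ml(pred),
        "gt_positive": mask_volume_ml(gt) >= cutoff,
        "pred_positive": mask_volume_ml(pred) >= cutoff,
        "patient_outcome": patientwise_outcome(gt, pred, structure, policy),
        "dice": vw["dice"],
        "recall": vw["recall"],
        "precision": vw["precision"],
        "hd95": vw["hd95"],
        "object_dice": ow["dice"],
        "object_recall": ow["recall"],
        "object_precision": ow["precision"],
        "object_hd95": ow["hd95"],
    }


def pooled_estimates(folds: Sequence[FoldStats]) -> Dict[str, Dict[str, Optional[float]]]:
    """Pool per-fold mean/SD into overall estimates.

    The pooled mean and variance are exactly the sample statistics of the
    concatenated per-sample values:

    ``mean = sum(n_i m_i) / N``;
    ``var = [sum((n_i - 1) s_i^2) + sum(n_i (m_i - mean)^2)] / (N - 1)``.
    """
    if not folds:
        raise ValueError("no folds to pool")
    metrics = set().union(*(f.means for f in folds))
    out: Dict[str, Dict[str, Optional[float]]] = {}
    for metric in metrics:
        ns, ms, ss = [], [], []
        for f in folds:
            if metric in f.means and f.means[metric] is not None:
                ns.append(f.n)
                ms.append(f.means[metric])
                ss.append(f.sds.get(metric, 0.0))
        if not ns:
            out[metric] = {"mean": None, "sd": None}
            continue
        ns_a, ms_a, ss_a = map(np.asarray, (ns, ms, ss))
        n_total = int(ns_a.sum())
        mean = float((ns_a * ms_a).sum() / n_total)
        if n_total < 2:
            out[metric] = {"mean": mean, "sd": None}
            continue
        var = (
            ((ns_a - 1) * ss_a**2).sum() + (ns_a * (ms_a - mean) ** 2).sum()
        ) / (n_total - 1)
        out[metric] = {"mean": mean, "sd": float(np.sqrt(var))}
    return out


def select_best_threshold(records: pd.DataFrame) -> float:
    """Pick the sweep threshold maximizing mean voxel-wise Dice over the
    positive (ground-truth) samples; ties go to the higher threshold."""
    pos = records[records["gt_positive"]]
    if pos.empty:
        raise ValueError("no positive samples; cannot select a threshold")
    means = pos.groupby("threshold")["dice"].mean()
    best = means[means == means.max()].index.max()
    return float(best)


def sensitivity_analysis(
    records: pd.DataFrame,
    dice_thresholds: Sequence[float] = DEFAULT_SENSITIVITY_THRESHOLDS,
) -> pd.DataFrame:
    """Patient-wise classification under increasingly strict TP Dice
    thresholds (in %).

    Each row recomputes the confusion counts with the given threshold in
    place of the default: a positive/positive pair is a TP only when its
    voxel-wise Dice exceeds the row's threshold.  Negative rows (TN/FP) are
    unaffected by construction.
    """
    required = {"gt_positive", "pred_positive", "dice"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    rows = []
    for thr in dice_thresholds:
        tp = fn = fp = tn = 0
        for _, r in records.iterrows():
            if r["gt_positive"]:
                if r["pred_positive"] and r["dice"] is not None and r["dice"] > thr:
                    tp += 1
                else:
                    fn += 1
            else:
                fp += 1 if r["pred_positive"] else 0
                tn += 0 if r["pred_positive"] else 1
        counts = ClassificationCounts(TP=tp, FP=fp, TN=tn, FN=fn)
        row = {"dice_threshold_pct": thr, "n_total": counts.total,
               "n_positive": tp + fn, "TP": tp, "FP": fp, "TN": tn, "FN": fn}
        row.update(classification_metrics(counts))
        rows.append(row)
    return pd.DataFrame(rows)
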