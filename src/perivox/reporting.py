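"""Standardized per-timepoint and surgical reports.

For every segmented structure the report carries its volume, slice-based
diameter characteristics, tumor-to-brain ratio and component count; across
timepoints it adds the post-surgical volumetric evolution (the
extent-of-resection when the structure is the tumor) and the overall
surgical-assessment category (complete / near total / subtotal resection)
derived from the residual enhancing-tissue volume.

Diameter conventions follow the bidimensional RANO practice: measurements
are taken on the axial slice with the largest in-slice lesion area.  The
Feret diameter is the maximal caliper distance, long/short axes come from
the best-fit (second-moment) ellipse, and the equivalent diameter is that of
the circle with the same area.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
from skimage import measure

from .preprocessing import connected_components, mask_volume_ml
from .types import (
    BinaryMask,
    PatientStudy,
    StructureSet,
    ThresholdPolicy,
    require_same_grid,
)

__all__ = [
    "FeatureSet",
    "ReportDocument",
    "compute_features",
    "volumetric_evolution",
    "classify_resection",
    "build_report",
]

RESECTION_CATEGORIES = ("complete", "near total", "subtotal")


@dataclass
class FeatureSet:
    """Per-structure morphometry of one timepoint."""

    volume_ml: float
    long_axis_mm: float
    short_axis_mm: float
    feret_mm: float
    equivalent_diameter_mm: float
    tumor_to_brain_ratio_pct: float
    component_count: int

    def to_dict(self) -> dict:
        return {k: (round(v, 4) if isinstance(v, float) else v) for k, v in asdict(self).items()}


def _feret_diameter(sl: np.ndarray, spacing) -> float:
    """Maximal point-pair (caliper) distance between foreground pixel
    centers, in mm; 0 for a single pixel."""
    pts = np.argwhere(sl) * np.asarray(spacing)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 3:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear degenerate sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def compute_features(mask: BinaryMask, brain: BinaryMask) -> FeatureSet:
    """Morphometric features of one structure mask.

    Diameters are measured on the axial slice (third axis) of maximal
    in-slice area.  An empty mask yields all-zero features.  The brain mask
    must be non-empty (it is the ratio denominator).
    """
    require_same_grid(mask, brain)
    brain_ml = mask_volume_ml(brain)
    if brain_ml == 0:
        raise ZeroDivisionError("brain mask is empty")
    if mask.voxel_count == 0:
        return FeatureSet(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)

    volume = mask_volume_ml(mask)
    _, counts = connected_components(mask, connectivity=26)

    per_slice = mask.values.sum(axis=(0, 1))
    z = int(np.argmax(per_slice))
    sl = mask.values[:, :, z]
    sx, sy = mask.spacing[0], mask.spacing[1]
    area_mm2 = float(sl.sum()) * sx * sy
    eq_diam = 2.0 * float(np.sqrt(area_mm2 / np.pi))

    props = measure.regionprops(sl.astype(np.uint8), spacing=(sx, sy))[0]
    return FeatureSet(
        volume_ml=volume,
        long_axis_mm=float(props.axis_major_length),
        short_axis_mm=float(props.axis_minor_length),
        feret_mm=_feret_diameter(sl, (sx, sy)),
        equivalent_diameter_mm=eq_diam,
        tumor_to_brain_ratio_pct=100.0 * volume / brain_ml,
        component_count=len(counts),
    )


def volumetric_evolution(pre_ml: float, post_ml: float) -> Optional[float]:
    """Percent volume change from pre- to postoperative.

    ``100 * (pre - post) / pre``; negative for growth; exactly 100 when the
    postoperative volume is zero.  Returns ``None`` (not applicable) when the
    preoperative volume is zero.
    """
    if pre_ml < 0 or post_ml < 0:
        raise ValueError("volumes must be non-negative")
    if pre_ml == 0:
        return None
    if post_ml == 0:
        return 100.0
    return 100.0 * (pre_ml - post_ml) / pre_ml


def classify_resection(residual_ml: float, policy: ThresholdPolicy) -> str:
    """RANO-style surgical assessment from the residual-tumor volume.

    complete: residual below the detectability cut-off (default 0.175 ml);
    near total: residual up to ``near_total_max_ml`` (default 1.0 ml);
    subtotal otherwise.  The thresholds are policy, echoed into the report.
    """
    if residual_ml < 0:
        raise ValueError(f"residual volume must be non-negative, got {residual_ml}")
    if residual_ml < policy.complete_max_ml:
        return "complete"
    if residual_ml <= policy.near_total_max_ml:
        return "near total"
    return "subtotal"


@dataclass
class ReportDocument:
    """Serializable per-patient report: per-timepoint features, volumetric
    evolution per structure, and the surgical assessment."""

    patient_id: str
    contrast_enhancing: bool
    timepoints: Dict[str, Dict[str, dict]]
    volumetric_evolution_pct: Dict[str, Optional[float]]
    resection_category: Optional[str]
    residual_tumor_ml: Optional[float]
    brain_grid_classification: Optional[str]
    policy: dict
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "contrast_enhancing": self.contrast_enhancing,
            "timepoints": self.timepoints,
            "volumetric_evolution_pct": {
                k: (round(v, 4) if v is not None else None)
                for k, v in self.volumetric_evolution_pct.items()
            },
            "resection_category": self.resection_category,
            "residual_tumor_ml": (
                round(self.residual_tumor_ml, 4)
                if self.residual_tumor_ml is not None
                else None
            ),
            "brain_grid_classification": self.brain_grid_classification,
            "policy": self.policy,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ReportDocument":
        d = json.loads(text)
        return cls(
            patient_id=d["patient_id"],
            contrast_enhancing=d["contrast_enhancing"],
            timepoints=d["timepoints"],
            volumetric_evolution_pct=d["volumetric_evolution_pct"],
            resection_category=d["resection_category"],
            residual_tumor_ml=d["residual_tumor_ml"],
            brain_grid_classification=d["brain_grid_classification"],
            policy=d["policy"],
            warnings=d["warnings"],
        )

    def to_markdown(self) -> str:
        lines = [f"# Surgical report — patient {self.patient_id}", ""]
        kind = "contrast-enhancing" if self.contrast_enhancing else "non contrast-enhancing"
        lines.append(f"Tumor type: {kind}")
        for tp in sorted(self.timepoints):
            lines.append("")
            lines.append(f"## {tp.capitalize()}")
            lines.append("")
            lines.append("| structure | volume (ml) | long axis (mm) | short axis (mm) "
                         "| Feret (mm) | eq. diameter (mm) | tumor/brain (%) | components |")
            lines.append("|---|---|---|---|---|---|---|---|")
            for s in sorted(self.timepoints[tp]):
                f = self.timepoints[tp][s]
                lines.append(
                    f"| {s} | {f['volume_ml']:.3f} | {f['long_axis_mm']:.1f} | "
                    f"{f['short_axis_mm']:.1f} | {f['feret_mm']:.1f} | "
                    f"{f['equivalent_diameter_mm']:.1f} | "
                    f"{f['tumor_to_brain_ratio_pct']:.2f} | {f['component_count']} |"
                )
        if self.volumetric_evolution_pct:
            lines.append("")
            lines.append("## Volumetric evolution")
            lines.append("")
            for s in sorted(self.volumetric_evolution_pct):
                v = self.volumetric_evolution_pct[s]
                txt = "n/a" if v is None else f"{v:.1f}%"
                lines.append(f"- {s}: {txt}")
        if self.resection_category is not None:
            lines.append("")
            lines.append(f"**Surgical assessment: {self.resection_category} resection** "
                         f"(residual {self.residual_tumor_ml:.3f} ml)")
        for w in self.warnings:
            lines.append("")
            lines.append(f"> warning: {w}")
        return "\n".join(lines) + "\n"


def _tumor_proxy(contrast_enhancing: bool, timepoint: str) -> str:
    if contrast_enhancing:
        return "TC" if timepoint == "preoperative" else "ET"
    return "SNFH"


def build_report(study: PatientStudy, policy: ThresholdPolicy) -> ReportDocument:
    """Assemble the standardized report for one patient.

    Requires refined structure sets per timepoint.  The surgical section
    (evolution + resection category) is produced only when both timepoints
    are present; the category is based on the postoperative ET volume for
    contrast-enhancing tumors.  For non contrast-enhancing tumors no
    enhancing residual exists, so no category is assigned and the cavity
    volume documents the resection instead.
    """
    if not study.timepoints:
        raise ValueError("study has no timepoints")
    warnings: List[str] = []
    features: Dict[str, Dict[str, dict]] = {}
    volumes: Dict[str, Dict[str, float]] = {}
    for tp, data in study.timepoints.items():
        structures = data.structures
        if "BRAIN" not in structures:
            raise ValueError(f"{tp}: brain mask required for reporting")
        brain = structures["BRAIN"]
        features[tp] = {}
        volumes[tp] = {}
        for label in structures:
            if label == "BRAIN":
                continue
            fs = compute_features(structures[label], brain)
            features[tp][label] = fs.to_dict()
            volumes[tp][label] = fs.volume_ml
        if "ET" in structures and "CAVITY" in structures:
            overlap = int((structures["ET"].values & structures["CAVITY"].values).sum())
            if overlap:
                warnings.append(
                    f"{tp}: ET and CAVITY overlap by {overlap} voxels (no rule applied)"
                )

    evolution: Dict[str, Optional[float]] = {}
    category: Optional[str] = None
    residual: Optional[float] = None
    if {"preoperative", "postoperative"} <= set(study.timepoints):
        pre_v, post_v = volumes["preoperative"], volumes["postoperative"]
        for label in sorted(set(pre_v) & set(post_v)):
            evolution[label] = volumetric_evolution(pre_v[label], post_v[label])
        pre_proxy = _tumor_proxy(study.tumor_contrast_enhancing, "preoperative")
        post_proxy = _tumor_proxy(study.tumor_contrast_enhancing, "postoperative")
        if pre_proxy in pre_v and post_proxy in post_v:
            evolution["tumor"] = volumetric_evolution(pre_v[pre_proxy], post_v[post_proxy])
        if study.tumor_contrast_enhancing:
            if post_proxy in post_v:
                residual = post_v[post_proxy]
                category = classify_resection(residual, policy)
            else:
                warnings.append("postoperative ET missing; no surgical assessment")
        else:
            warnings.append(
                "non contrast-enhancing tumor: no enhancing residual; "
                "surgical assessment omitted (see cavity volume)"
            )

    return ReportDocument(
        patient_id=study.patient_id,
        contrast_enhancing=study.tumor_contrast_enhancing,
        timepoints=features,
        volumetric_evolution_pct=evolution,
        resection_category=category,
        residual_tumor_ml=residual,
        brain_grid_classification=None,
        policy=policy.to_dict(),
        warnings=warnings,
    )
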