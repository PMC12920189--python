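"""Pipeline orchestration: simulate -> segment -> refine -> report -> validate.

The segmentation stage runs the sliding-window machinery over a pluggable
patch predictor; by default this is the phantom oracle predictor (optionally
blurred/noised/perturbed) since trained network weights are outside the
scope of this package.  Every stage consumes and produces only documented
on-disk formats (NIfTI volumes, CSV manifests, JSON reports), so stages can
also be run individually from the CLI.

Cohort directory layout::

    cohort/
      manifest.csv                    # patient_id, fold, contrast_enhancing, negative
      <patient_id>/<timepoint>/
        t1c.nii.gz ... t2w.nii.gz     # sequences
        struct_TC.nii.gz ...          # ground-truth structure masks
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import nifti
from .inference import InferenceConfig, postprocess_probability, sliding_window_predict, tta_predict
from .refinement import RefinementContext, refine_structures
from .reporting import build_report
from .synthetic import PerturbationSpec, PhantomParams, generate_cohort, make_oracle_predictor, perturb_mask
from .types import (
    BinaryMask,
    PatientStudy,
    SequenceSet,
    StructureSet,
    ThresholdPolicy,
    Timepoint,
)
from .validation import (
    DEFAULT_SENSITIVITY_THRESHOLDS,
    FoldStats,
    evaluate_sample,
    pooled_estimates,
    sensitivity_analysis,
)

__all__ = ["PipelineConfig", "run_pipeline", "write_study", "read_study",
           "write_cohort", "read_cohort"]

log = logging.getLogger("perivox")

_SEQ_FILES = ("t1c", "t1w", "flair", "t2w")
_STRUCTURES_BY_TP = {
    "preoperative": ("TC", "NETC", "SNFH"),
    "postoperative": ("ET", "CAVITY", "SNFH"),
}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from a YAML file."""

    output_dir: str = "perivox_run"
    n_patients: int = 5
    fold_count: int = 5
    negative_fraction: float = 0.2
    seed: int = 0
    bin_threshold: float = 0.5
    predictor_blur: float = 0.0
    predictor_noise: float = 0.0
    perturb_severity: float = 0.0
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    inference: InferenceConfig = field(
        default_factory=lambda: InferenceConfig(patch_shape=(64, 64, 64))
    )
    phantom: PhantomParams = field(default_factory=PhantomParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "policy" in kwargs:
            kwargs["policy"] = ThresholdPolicy(**kwargs["policy"])
        if "inference" in kwargs:
            inf = dict(kwargs["inference"])
            if "patch_shape" in inf:
                inf["patch_shape"] = tuple(inf["patch_shape"])
            kwargs["inference"] = InferenceConfig(**inf)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            for k in ("shape", "spacing", "brain_semi_axes_mm", "tc_volume_ml",
                      "cavity_fraction", "residual_fragment_count", "fragment_volume_ml"):
                if k in ph:
                    ph[k] = tuple(ph[k])
            kwargs["phantom"] = PhantomParams(**ph)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["policy"] = self.policy.to_dict()
        return d


def write_study(study: PatientStudy, root: Path) -> None:
    for tp, data in study.timepoints.items():
        tp_dir = root / study.patient_id / tp
        tp_dir.mkdir(parents=True, exist_ok=True)
        if data.sequences is not None:
            for label, vol in data.sequences.items():
                nifti.write_volume(vol, tp_dir / f"{label}.nii.gz")
        for label, mask in data.structures.items():
            nifti.write_volume(mask, tp_dir / f"struct_{label}.nii.gz")


def read_study(root: Path, patient_id: str, contrast_enhancing: bool = True) -> PatientStudy:
    timepoints = {}
    for tp in ("preoperative", "postoperative"):
        tp_dir = root / patient_id / tp
        if not tp_dir.is_dir():
            continue
        seqs = {
            lab: nifti.read_volume(tp_dir / f"{lab}.nii.gz")
            for lab in _SEQ_FILES
            if (tp_dir / f"{lab}.nii.gz").exists()
        }
        structs = {}
        for f in sorted(tp_dir.glob("struct_*.nii.gz")):
            label = f.name[len("struct_"):-len(".nii.gz")]
            structs[label] = nifti.read_mask(f)
        timepoints[tp] = Timepoint(
            SequenceSet(seqs) if seqs else None, StructureSet(structs)
        )
    return PatientStudy(patient_id, timepoints, contrast_enhancing)


def write_cohort(cohort: List[Tuple[PatientStudy, int]], root: Path,
                 negatives: Optional[Dict[str, bool]] = None) -> None:
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for study, fold in cohort:
        write_study(study, root)
        rows.append({
            "patient_id": study.patient_id,
            "fold": fold,
            "contrast_enhancing": study.tumor_contrast_enhancing,
            "negative": bool(negatives.get(study.patient_id)) if negatives else
            study.timepoints["postoperative"].structures["ET"].voxel_count == 0,
        })
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)


def read_cohort(root: Path) -> List[Tuple[PatientStudy, int]]:
    manifest = pd.read_csv(root / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        study = read_study(root, row["patient_id"], bool(row["contrast_enhancing"]))
        out.append((study, int(row["fold"])))
    return out


def segment_study(
    study: PatientStudy, cfg: PipelineConfig
) -> PatientStudy:
    """Predicted counterpart of a study: sliding-window probability maps per
    structure, postprocessed (component filter for ET only) and binarized.

    The brain mask is carried over from the input (it is a pipeline input,
    not a prediction target); optional mask perturbation emulates imperfect
    models."""
    seed_base = cfg.seed * 1000 + (zlib.crc32(study.patient_id.encode()) % 997)
    pred_tps: Dict[str, Timepoint] = {}
    for tp, data in study.timepoints.items():
        gt = data.structures
        brain = gt["BRAIN"]
        predicted: Dict[str, BinaryMask] = {"BRAIN": brain}
        for label in _STRUCTURES_BY_TP[tp]:
            if label not in gt:
                continue
            target = gt[label]
            if cfg.perturb_severity > 0:
                target = perturb_mask(
                    target,
                    PerturbationSpec(severity=cfg.perturb_severity,
                                     seed=seed_base + len(predicted)),
                )
                source = gt.replace(**{label: target})
            else:
                source = gt
            predictor = make_oracle_predictor(
                source, label,
                blur=cfg.predictor_blur, noise=cfg.predictor_noise,
                seed=seed_base + len(predicted),
                patch_shape=cfg.inference.patch_shape,
            )
            if cfg.inference.tta_enabled:
                pm = tta_predict(data.sequences, predictor, cfg.inference)
            else:
                pm = sliding_window_predict(data.sequences, predictor, cfg.inference)
            pm = postprocess_probability(
                pm, brain, cfg.policy, cfg.bin_threshold,
                component_filter=(label == "ET"),
            )
            predicted[label] = BinaryMask(
                pm.values >= cfg.bin_threshold, pm.spacing, pm.origin
            )
        pred_tps[tp] = Timepoint(None, StructureSet(predicted))
    return PatientStudy(study.patient_id, pred_tps, study.tumor_contrast_enhancing)


def refine_study(study: PatientStudy) -> Tuple[PatientStudy, Dict[str, Dict[str, int]]]:
    refined_tps, logs = {}, {}
    for tp, data in study.timepoints.items():
        ctx = RefinementContext(tp, study.tumor_contrast_enhancing)
        refined, rlog = refine_structures(data.structures, ctx)
        refined_tps[tp] = Timepoint(data.sequences, refined)
        logs[tp] = rlog
    return PatientStudy(study.patient_id, refined_tps,
                        study.tumor_contrast_enhancing), logs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Full demo pipeline; returns the output directory.

    Produces per-patient surgical reports (JSON + Markdown), refined masks,
    refinement logs, per-sample / per-fold / pooled validation CSVs and a
    sensitivity-analysis CSV.  Identical config + seed give byte-identical
    outputs.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True, default=str)
    )
    phantom = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    cohort = generate_cohort(
        cfg.n_patients, phantom, fold_count=cfg.fold_count,
        seed=cfg.seed, negative_fraction=cfg.negative_fraction,
    )
    write_cohort(cohort, out / "cohort")

    records = []
    report_dir = out / "reports"
    report_dir.mkdir(exist_ok=True)
    for study, fold in cohort:
        log.info("pipeline patient=%s fold=%d", study.patient_id, fold)
        predicted = segment_study(study, cfg)
        refined, rlogs = refine_study(predicted)
        write_study(refined, out / "predictions")
        (out / "predictions" / study.patient_id / "refinement_log.json").write_text(
            json.dumps(rlogs, indent=2, sort_keys=True)
        )
        report = build_report(refined, cfg.policy)
        (report_dir / f"{study.patient_id}.json").write_text(report.to_json())
        (report_dir / f"{study.patient_id}.md").write_text(report.to_markdown())
        for tp, data in study.timepoints.items():
            for label in _STRUCTURES_BY_TP[tp]:
                if label not in data.structures or label not in refined.timepoints[tp].structures:
                    continue
                if label not in cfg.policy.positivity_cutoff_ml:
                    continue
                records.append(evaluate_sample(
                    data.structures[label],
                    refined.timepoints[tp].structures[label],
                    label, cfg.policy,
                    sample_id=f"{study.patient_id}_{tp}",
                    fold=str(fold), threshold=cfg.bin_threshold,
                ))

    df = pd.DataFrame(records)
    val_dir = out / "validation"
    val_dir.mkdir(exist_ok=True)
    df.to_csv(val_dir / "per_sample.csv", index=False, float_format="%.6f")

    metric_cols = ["dice", "recall", "precision", "hd95",
                   "object_dice", "object_recall", "object_precision", "object_hd95"]
    fold_rows, fold_stats = [], {}
    for (structure, fold), grp in df[df["gt_positive"]].groupby(["structure", "fold"]):
        means = {m: grp[m].dropna().mean() for m in metric_cols}
        sds = {m: grp[m].dropna().std(ddof=1) if grp[m].dropna().size > 1 else 0.0
               for m in metric_cols}
        fold_stats.setdefault(structure, []).append(
            FoldStats(str(fold), len(grp), means, sds)
        )
        fold_rows.append({"structure": structure, "fold": fold, "n": len(grp), **means})
    pd.DataFrame(fold_rows).to_csv(val_dir / "per_fold.csv", index=False,
                                   float_format="%.6f")

    pooled_rows = []
    for structure, folds in sorted(fold_stats.items()):
        pooled = pooled_estimates(folds)
        for metric in metric_cols:
            est = pooled.get(metric, {"mean": None, "sd": None})
            pooled_rows.append({"structure": structure, "metric": metric,
                                "mean": est["mean"], "sd": est["sd"]})
    pd.DataFrame(pooled_rows).to_csv(val_dir / "pooled.csv", index=False,
                                     float_format="%.6f")

    et = df[df["structure"] == "ET"]
    if not et.empty:
        sensitivity_analysis(et, DEFAULT_SENSITIVITY_THRESHOLDS).to_csv(
            val_dir / "sensitivity.csv", index=False, float_format="%.6f"
        )
    return out
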