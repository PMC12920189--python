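"""Cross-structure consistency refinement.

Structure masks are produced by independent single-structure models, so they
can disagree (necrosis outside the tumor core, edema overlapping the
cavity).  This module enforces the global rules that make a structure set
anatomically coherent, with the contrast-enhancing (CE) / non-CE distinction:

* preoperative, CE tumor — the tumor core (TC) is the reference and is never
  touched; NETC is restricted to TC; SNFH has TC subtracted; the whole tumor
  WT is the (now disjoint) union TC | SNFH.
* postoperative, CE tumor — the enhancing residual tissue (ET) is the
  reference; SNFH has both the cavity and ET subtracted.
* non-CE tumor — SNFH itself serves as the whole tumor mask; postoperatively
  the cavity is subtracted from SNFH first.

Absent structures are skipped; everything is restricted to the brain mask
when one is present; the brain mask itself is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .types import BinaryMask, StructureSet, require_same_grid

__all__ = ["RefinementContext", "refine_structures"]

_TIMEPOINTS = ("preoperative", "postoperative")


@dataclass(frozen=True)
class RefinementContext:
    timepoint: str
    contrast_enhancing: bool = True

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {_TIMEPOINTS}")


def refine_structures(
    structures: StructureSet, ctx: RefinementContext
) -> Tuple[StructureSet, Dict[str, int]]:
    """Apply the consistency rules; returns the refined set and a log of
    voxel counts removed (or added, for WT) per rule.

    Raises if the reference structure for the context is missing (TC for
    preoperative CE, ET for postoperative CE, SNFH for non-CE).
    """
    masks = {k: np.asarray(v.values, dtype=bool) for k, v in structures.items()}
    if len(structures):
        require_same_grid(*structures.values())
    log: Dict[str, int] = {}

    def _require(label: str) -> np.ndarray:
        if label not in masks:
            raise ValueError(
                f"refinement for {ctx.timepoint} "
                f"({'CE' if ctx.contrast_enhancing else 'non-CE'}) requires {label!r}"
            )
        return masks[label]

    if ctx.contrast_enhancing:
        if ctx.timepoint == "preoperative":
            tc = _require("TC")
            if "NETC" in masks:
                kept = masks["NETC"] & tc
                log["netc_outside_tc_removed"] = int(masks["NETC"].sum() - kept.sum())
                masks["NETC"] = kept
            if "SNFH" in masks:
                kept = masks["SNFH"] & ~tc
                log["snfh_tc_overlap_removed"] = int(masks["SNFH"].sum() - kept.sum())
                masks["SNFH"] = kept
                masks["WT"] = tc | masks["SNFH"]
                log["wt_voxels"] = int(masks["WT"].sum())
        else:
            et = _require("ET")
            if "SNFH" in masks:
                cut = et.copy()
                if "CAVITY" in masks:
                    cut |= masks["CAVITY"]
                kept = masks["SNFH"] & ~cut
                log["snfh_cavity_et_overlap_removed"] = int(
                    masks["SNFH"].sum() - kept.sum()
                )
                masks["SNFH"] = kept
    else:
        snfh = _require("SNFH")
        if ctx.timepoint == "postoperative" and "CAVITY" in masks:
            kept = snfh & ~masks["CAVITY"]
            log["snfh_cavity_overlap_removed"] = int(snfh.sum() - kept.sum())
            snfh = kept
        masks["SNFH"] = snfh
        masks["WT"] = snfh.copy()
        log["wt_voxels"] = int(masks["WT"].sum())

    if "BRAIN" in masks:
        brain = structures["BRAIN"].values
        for label in list(masks):
            if label == "BRAIN":
                continue
            kept = masks[label] & brain
            removed = int(masks[label].sum() - kept.sum())
            if removed:
                log[f"{label.lower()}_outside_brain_removed"] = removed
            masks[label] = kept

    any_mask = next(iter(structures.values()))
    refined = StructureSet(
        {
            k: BinaryMask(v, any_mask.spacing, any_mask.origin)
            for k, v in masks.items()
        }
    )
    return refined, log
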