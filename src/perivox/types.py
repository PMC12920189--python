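"""Core domain types for perioperative tumor-MRI volumes.

All volumetric objects live on a simple axis-aligned grid: a 3D array whose
third axis indexes axial slices, a per-axis voxel spacing in millimetres and
a physical origin (the coordinate of voxel ``(0, 0, 0)``).  Voxel indices are
0-based and bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "AlignmentError",
    "FormatError",
    "VolumeGrid",
    "BinaryMask",
    "ProbabilityMap",
    "SequenceSet",
    "StructureSet",
    "Timepoint",
    "PatientStudy",
    "ThresholdPolicy",
    "SEQUENCE_LABELS",
    "STRUCTURE_LABELS",
    "same_grid",
    "require_same_grid",
]

SEQUENCE_LABELS = ("t1c", "t1w", "flair", "t2w", "t1d")
STRUCTURE_LABELS = ("TC", "NETC", "SNFH", "ET", "CAVITY", "WT", "BRAIN")


class FormatError(ValueError):
    """Raised for malformed images or headers (wrong dimensionality, bad spacing)."""


class AlignmentError(ValueError):
    """Raised when two volumes expected to share a grid do not."""


def _as_tuple3(x) -> Tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) != 3:
        raise FormatError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical voxel spacing (mm).

    Parameters
    ----------
    values
        3D array of intensities (arbitrary units).
    spacing
        Voxel edge lengths in mm, one per axis; all > 0.
    origin
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise FormatError("every axis must have length >= 1")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same grid, new values (keeps the concrete subclass)."""
        return replace(self, values=values)


@dataclass
class BinaryMask(VolumeGrid):
    """A boolean structure mask on a :class:`VolumeGrid` geometry."""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise FormatError("mask values must be in {0, 1}")
            vals = vals.astype(bool)
        self.values = vals
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class ProbabilityMap(VolumeGrid):
    """A voxel-wise probability field; values constrained to [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min(initial=0.0) < 0.0 or self.values.max(initial=0.0) > 1.0:
            raise FormatError("probabilities must lie in [0, 1]")


def same_grid(a: VolumeGrid, b: VolumeGrid, tol: float = 1e-4) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


def require_same_grid(*vols: VolumeGrid) -> None:
    for v in vols[1:]:
        if not same_grid(vols[0], v):
            raise AlignmentError(
                f"grids differ: {vols[0].shape}@{vols[0].spacing} vs {v.shape}@{v.spacing}"
            )


class _LabelledVolumes(Mapping):
    """Mapping of label -> volume with a shared-grid invariant."""

    _allowed: Tuple[str, ...] = ()
    _kind = VolumeGrid

    def __init__(self, volumes: Dict[str, VolumeGrid]):
        for label, vol in volumes.items():
            if label not in self._allowed:
                raise KeyError(f"unknown label {label!r}; allowed: {self._allowed}")
            if not isinstance(vol, self._kind):
                raise TypeError(f"{label}: expected {self._kind.__name__}")
        vols = list(volumes.values())
        if vols:
            require_same_grid(*vols)
        self._volumes = dict(volumes)

    def __getitem__(self, label: str):
        return self._volumes[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self._volumes)

    def __len__(self) -> int:
        return len(self._volumes)

    def replace(self, **updates):
        merged = {**self._volumes, **updates}
        return type(self)(merged)


class SequenceSet(_LabelledVolumes):
    """MR sequences of one timepoint (t1c, t1w, flair, t2w, optional t1d).

    The derived difference channel ``t1d`` may only be present when both of
    its parents (t1c and t1w) are.
    """

    _allowed = SEQUENCE_LABELS
    _kind = VolumeGrid

    def __init__(self, volumes: Dict[str, VolumeGrid]):
        super().__init__(volumes)
        if "t1d" in self._volumes and not {"t1c", "t1w"} <= set(self._volumes):
            raise ValueError("t1d requires both t1c and t1w to be present")


class StructureSet(_LabelledVolumes):
    """Named binary structure masks of one timepoint, on one shared grid."""

    _allowed = STRUCTURE_LABELS
    _kind = BinaryMask


@dataclass
class Timepoint:
    sequences: Optional[SequenceSet]
    structures: StructureSet


@dataclass
class PatientStudy:
    """Sequences and structures for the pre/postoperative timepoints of one patient."""

    patient_id: str
    timepoints: Dict[str, Timepoint]
    tumor_contrast_enhancing: bool = True

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValueError("a study needs at least one timepoint")
        bad = set(self.timepoints) - {"preoperative", "postoperative"}
        if bad:
            raise ValueError(f"unknown timepoints: {sorted(bad)}")


@dataclass
class ThresholdPolicy:
    """All tunable decision thresholds of the pipeline, in one place.

    positivity_cutoff_ml
        Minimum structure volume for a sample to count as positive at the
        patient level (ET 0.175 ml, NETC 0.05 ml, CAVITY 0.1 ml, TC 0.1 ml).
    postprocess_min_volume_ml
        Connected components of a binarized probability map smaller than this
        are erased during postprocessing.
    objectwise_min_voxels
        Components below this voxel count are discarded before object-wise
        matching (75 voxels; 50 for NETC).
    patientwise_tp_dice_pct
        Minimum voxel-wise Dice (in %) between prediction and ground truth
        for a positive case to count as a true positive.
    complete_max_ml / near_total_max_ml
        Residual-tumor volume bounds for the surgical-assessment categories
        (complete < complete_max_ml <= near total <= near_total_max_ml < subtotal).
    """

    positivity_cutoff_ml: Dict[str, float] = field(
        default_factory=lambda: {"ET": 0.175, "NETC": 0.05, "CAVITY": 0.1, "TC": 0.1}
    )
    postprocess_min_volume_ml: float = 0.05
    objectwise_min_voxels: Dict[str, int] = field(
        default_factory=lambda: {"default": 75, "NETC": 50}
    )
    patientwise_tp_dice_pct: float = 0.1
    complete_max_ml: float = 0.175
    near_total_max_ml: float = 1.0

    def __post_init__(self) -> None:
        vals = list(self.positivity_cutoff_ml.values()) + [
            self.postprocess_min_volume_ml,
            self.patientwise_tp_dice_pct,
            self.complete_max_ml,
            self.near_total_max_ml,
        ]
        if any(v < 0 for v in vals) or any(v < 0 for v in self.objectwise_min_voxels.values()):
            raise ValueError("policy thresholds must be non-negative")
        if self.complete_max_ml > self.near_total_max_ml:
            raise ValueError("complete_max_ml must not exceed near_total_max_ml")

    def cutoff_for(self, structure: str) -> float:
        try:
            return self.positivity_cutoff_ml[structure]
        except KeyError:
            raise ValueError(f"no positivity cut-off defined for structure {structure!r}")

    def min_voxels_for(self, structure: str) -> int:
        return self.objectwise_min_voxels.get(
            structure, self.objectwise_min_voxels.get("default", 75)
        )

    def to_dict(self) -> dict:
        return {
            "positivity_cutoff_ml": dict(self.positivity_cutoff_ml),
            "postprocess_min_volume_ml": self.postprocess_min_volume_ml,
            "objectwise_min_voxels": dict(self.objectwise_min_voxels),
            "patientwise_tp_dice_pct": self.patientwise_tp_dice_pct,
            "complete_max_ml": self.complete_max_ml,
            "near_total_max_ml": self.near_total_max_ml,
        }
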