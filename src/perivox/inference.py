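"""Whole-volume probability maps from a pluggable patch predictor.

A *patch predictor* is anything fulfilling :class:`PatchPredictor`: it
declares its input channels and patch shape, and maps a multi-channel patch
to a same-shape probability patch.  Trained networks, hand-written mocks and
the synthetic oracle predictor are interchangeable behind this contract.

Whole-volume inference tiles the (zero-padded) volume with a sliding window
at a configurable overlap (default 50%), averages overlapping window
predictions, and optionally wraps the pass in runtime test-time augmentation
(axis flipping, axial rotation, gamma contrast).  Postprocessing keeps only
probabilities inside the brain mask and erases connected components that are
too small or confined to a single axial slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from scipy import ndimage

from .preprocessing import connected_components
from .types import (
    AlignmentError,
    BinaryMask,
    ProbabilityMap,
    SequenceSet,
    ThresholdPolicy,
    VolumeGrid,
    require_same_grid,
)

__all__ = [
    "PatchPredictor",
    "InferenceConfig",
    "sliding_window_predict",
    "tta_predict",
    "ensemble_probability",
    "postprocess_probability",
]

TTA_TRANSFORMS = ("flip", "rotation", "gamma")


@runtime_checkable
class PatchPredictor(Protocol):
    """Contract stood in place of a trained segmentation network.

    ``channels`` lists the required input sequence labels, ``patch_shape``
    the spatial patch size.  The call receives a ``(C, X, Y, Z)`` patch plus
    the patch origin (corner voxel index in the unpadded volume; may be
    negative where the volume was padded) and returns probabilities of shape
    ``(X, Y, Z)`` in [0, 1].  Calls must be deterministic.
    """

    channels: Tuple[str, ...]
    patch_shape: Tuple[int, int, int]

    def __call__(self, patch: np.ndarray, origin: Tuple[int, int, int]) -> np.ndarray:
        ...


@dataclass
class InferenceConfig:
    """Knobs of the sliding-window / augmentation / ensembling stage."""

    patch_shape: Tuple[int, int, int] = (160, 160, 160)
    overlap: float = 0.5
    tta_enabled: bool = False
    tta_transforms: Tuple[str, ...] = TTA_TRANSFORMS
    ensemble_mode: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.ensemble_mode not in ("average", "amax"):
            raise ValueError(f"ensemble_mode must be 'average' or 'amax'")
        bad = set(self.tta_transforms) - set(TTA_TRANSFORMS)
        if bad:
            raise ValueError(f"unknown TTA transforms: {sorted(bad)}")


def _window_starts(dim: int, patch: int, stride: int) -> List[int]:
    starts = list(range(0, dim - patch + 1, stride))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def _stack_channels(seq: SequenceSet, channels: Sequence[str]) -> np.ndarray:
    missing = [c for c in channels if c not in seq]
    if missing:
        raise ValueError(f"sequence set lacks predictor channels {missing}")
    return np.stack([np.asarray(seq[c].values, dtype=float) for c in channels])


def sliding_window_predict(
    seq: SequenceSet, predictor: PatchPredictor, cfg: InferenceConfig
) -> ProbabilityMap:
    """Tile the volume with overlapping patches and average the predictions.

    The volume is zero-padded symmetrically up to at least one patch per
    axis; every voxel is covered by at least one window; overlapping window
    outputs are fused by unweighted mean; padding is removed afterwards.
    """
    if not len(seq):
        raise ValueError("empty sequence set")
    stack = _stack_channels(seq, predictor.channels)
    grid = seq[next(iter(seq))]
    shape = np.array(stack.shape[1:])
    patch = np.array(predictor.patch_shape, dtype=int)

    pad_total = np.maximum(patch - shape, 0)
    pad_lo = pad_total // 2
    pad_hi = pad_total - pad_lo
    padded = np.pad(stack, [(0, 0)] + [(int(a), int(b)) for a, b in zip(pad_lo, pad_hi)])
    pshape = np.array(padded.shape[1:])

    stride = np.maximum(np.round(patch * (1.0 - cfg.overlap)).astype(int), 1)
    acc = np.zeros(pshape, dtype=np.float64)
    cnt = np.zeros(pshape, dtype=np.int64)
    for i in _window_starts(pshape[0], patch[0], stride[0]):
        for j in _window_starts(pshape[1], patch[1], stride[1]):
            for k in _window_starts(pshape[2], patch[2], stride[2]):
                sl = (slice(i, i + patch[0]), slice(j, j + patch[1]), slice(k, k + patch[2]))
                origin = (i - int(pad_lo[0]), j - int(pad_lo[1]), k - int(pad_lo[2]))
                pred = np.asarray(predictor(padded[(slice(None),) + sl], origin))
                if pred.shape != tuple(patch):
                    raise ValueError(
                        f"predictor returned shape {pred.shape}, expected {tuple(patch)}"
                    )
                acc[sl] += pred
                cnt[sl] += 1
    fused = acc / cnt
    unpad = tuple(slice(int(a), int(a + n)) for a, n in zip(pad_lo, shape))
    values = np.clip(fused[unpad], 0.0, 1.0)
    return ProbabilityMap(values, grid.spacing, grid.origin)


def _map_sequences(seq: SequenceSet, fn) -> SequenceSet:
    return SequenceSet({k: v.with_values(fn(np.asarray(v.values, float))) for k, v in seq.items()})


def _gamma_adjust(values: np.ndarray, gamma: float) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return values.copy()
    scaled = (values - lo) / (hi - lo)
    return scaled**gamma * (hi - lo) + lo


def tta_predict(
    seq: SequenceSet, predictor: PatchPredictor, cfg: InferenceConfig
) -> ProbabilityMap:
    """Test-time augmentation: mean of the identity pass and one pass per
    enabled transform, with geometric transforms inverted on the predicted
    map before averaging (gamma needs no inversion).  Reproducible for a
    fixed ``cfg.seed``."""
    if not cfg.tta_enabled:
        raise ValueError("tta_predict requires cfg.tta_enabled")
    rng = np.random.default_rng(cfg.seed)
    maps = [sliding_window_predict(seq, predictor, cfg).values]
    for name in [t for t in TTA_TRANSFORMS if t in cfg.tta_transforms]:
        if name == "flip":
            axis = int(rng.integers(0, 3))
            aug = _map_sequences(seq, lambda v: np.flip(v, axis=axis))
            out = sliding_window_predict(aug, predictor, cfg).values
            maps.append(np.flip(out, axis=axis))
        elif name == "rotation":
            angle = float(rng.uniform(-20.0, 20.0))
            aug = _map_sequences(
                seq,
                lambda v: ndimage.rotate(v, angle, axes=(0, 1), reshape=False,
                                         order=1, mode="nearest"),
            )
            out = sliding_window_predict(aug, predictor, cfg).values
            back = ndimage.rotate(out, -angle, axes=(0, 1), reshape=False,
                                  order=1, mode="nearest")
            maps.append(np.clip(back, 0.0, 1.0))
        elif name == "gamma":
            gamma = float(rng.uniform(0.5, 2.0))
            aug = _map_sequences(seq, lambda v: _gamma_adjust(v, gamma))
            maps.append(sliding_window_predict(aug, predictor, cfg).values)
    grid = seq[next(iter(seq))]
    return ProbabilityMap(np.mean(maps, axis=0), grid.spacing, grid.origin)


def ensemble_probability(
    maps: Iterable[ProbabilityMap], mode: str = "average"
) -> ProbabilityMap:
    """Voxel-wise fusion of 1-5 probability maps: mean or maximum."""
    maps = list(maps)
    if not 1 <= len(maps) <= 5:
        raise ValueError(f"expected between 1 and 5 maps, got {len(maps)}")
    require_same_grid(*maps)
    if mode == "average":
        fused = np.mean([m.values for m in maps], axis=0)
    elif mode == "amax":
        fused = np.max([m.values for m in maps], axis=0)
    else:
        raise ValueError("mode must be 'average' or 'amax'")
    return ProbabilityMap(fused, maps[0].spacing, maps[0].origin)


def postprocess_probability(
    pm: ProbabilityMap,
    brain: BinaryMask,
    policy: ThresholdPolicy,
    bin_threshold: float = 0.5,
    component_filter: bool = True,
) -> ProbabilityMap:
    """Two-step cleanup of a probability map.

    Step 1 zeroes all probabilities outside the brain mask.  Step 2 binarizes
    the map at ``bin_threshold``, and erases (sets to zero) the probabilities
    of every connected component whose volume is below the policy's minimum
    (default 0.05 ml) or which does not extend over at least two consecutive
    axial slices.  Surviving probabilities are returned unchanged; the
    operation is idempotent.  ``component_filter=False`` applies only the
    brain-restriction step (the component filter is reserved for the
    residual-tumor structure in the standard pipeline).
    """
    if not 0 < bin_threshold <= 1:
        raise ValueError(f"bin_threshold must be in (0, 1], got {bin_threshold}")
    require_same_grid(pm, brain)
    values = np.where(brain.values, pm.values, 0.0)
    if not component_filter:
        return ProbabilityMap(values, pm.spacing, pm.origin)
    binary = BinaryMask(values >= bin_threshold, pm.spacing, pm.origin)
    labels, counts = connected_components(binary, connectivity=26)
    voxel_ml = pm.voxel_volume_ml
    for label, count in enumerate(counts, start=1):
        comp = labels == label
        z_extent = np.ptp(np.flatnonzero(comp.any(axis=(0, 1)))) + 1
        if count * voxel_ml < policy.postprocess_min_volume_ml or z_extent < 2:
            values[comp] = 0.0
    return ProbabilityMap(values, pm.spacing, pm.origin)
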