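"""Synthetic perioperative phantoms and controllable imperfect predictions.

The generator emulates the structures a perioperative glioma study works
with, on a small isotropic grid: preoperatively an ellipsoidal brain holding
an enhancing tumor core (TC) with a necrotic interior (NETC) and a
surrounding FLAIR-hyperintense halo (SNFH); postoperatively a resection
cavity replacing the core, with small enhancing residual fragments (ET)
scattered along the cavity margin and a shrunken halo.  MR sequences are
rendered as piecewise-constant tissue intensities plus Gaussian noise
(no bias field, no texture): enhancing tissue is bright on t1c but not t1w,
the cavity is CSF-dark on t1c and bright on t2w, the halo is bright on
FLAIR.

Tumor-like structures are rasterized as *exact-count balls*: the requested
volume is converted to a voxel count and exactly that many nearest-to-center
voxels are set, so ground-truth volumes are known to the voxel.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .inference import PatchPredictor
from .types import (
    BinaryMask,
    PatientStudy,
    SequenceSet,
    StructureSet,
    Timepoint,
    VolumeGrid,
)

__all__ = [
    "PhantomParams",
    "PerturbationSpec",
    "exact_volume_mask",
    "ellipsoid_mask",
    "generate_patient",
    "generate_cohort",
    "perturb_mask",
    "make_oracle_predictor",
    "OraclePredictor",
]

# Piecewise-constant tissue intensities per MR sequence (arbitrary units).
TISSUE_INTENSITY: Dict[str, Dict[str, float]] = {
    "t1c": {"brain": 600, "enhancing": 1000, "necrosis": 300, "snfh": 650, "cavity": 150},
    "t1w": {"brain": 600, "enhancing": 620, "necrosis": 320, "snfh": 640, "cavity": 160},
    "flair": {"brain": 500, "enhancing": 550, "necrosis": 250, "snfh": 900, "cavity": 120},
    "t2w": {"brain": 500, "enhancing": 560, "necrosis": 700, "snfh": 800, "cavity": 950},
}


@dataclass
class PhantomParams:
    """Study conditions for the phantom generator.

    Volumes in ml, lengths in mm.  Fragment volumes deliberately straddle
    the 0.175 ml residual-tumor detectability cut-off.
    """

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semi_axes_mm: Tuple[float, float, float] = (42.0, 38.0, 34.0)
    tc_volume_ml: Tuple[float, float] = (15.0, 35.0)
    necrosis_fraction: float = 0.3
    snfh_margin_mm: float = 8.0
    cavity_fraction: Tuple[float, float] = (0.6, 0.9)
    residual_fragment_count: Tuple[int, int] = (1, 3)
    fragment_volume_ml: Tuple[float, float] = (0.05, 1.0)
    center_jitter_mm: float = 6.0
    noise_sd: float = 10.0
    contrast_enhancing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.necrosis_fraction < 0 or self.necrosis_fraction >= 1:
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if min(self.tc_volume_ml) < 0 or min(self.fragment_volume_ml) < 0:
            raise ValueError("volumes must be non-negative")


@dataclass
class PerturbationSpec:
    """Controlled degradation of a mask; severity 0 is the identity."""

    severity: float = 0.0
    operations: Tuple[str, ...] = ("dilate", "erode", "translate")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must be in [0, 1]")
        allowed = {"dilate", "erode", "translate", "drop_component", "add_false_component"}
        bad = set(self.operations) - allowed
        if bad:
            raise ValueError(f"unknown operations: {sorted(bad)}")


def ellipsoid_mask(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_mm: Tuple[float, float, float],
    semi_axes_mm: Tuple[float, float, float],
) -> np.ndarray:
    """Boolean ellipsoid rasterized over voxel centers."""
    grids = np.meshgrid(
        *[(np.arange(n) * s - c) / a
          for n, s, c, a in zip(shape, spacing, center_mm, semi_axes_mm)],
        indexing="ij",
        sparse=True,
    )
    return sum(g**2 for g in grids) <= 1.0


def exact_volume_mask(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_vox: Tuple[float, float, float],
    volume_ml: float,
) -> np.ndarray:
    """Quasi-spherical mask holding *exactly* ``round(volume / voxel_volume)``
    voxels: the that-many voxels nearest to the center, with deterministic
    lexicographic tie-breaking."""
    voxel_ml = float(np.prod(spacing)) / 1000.0
    n = int(round(volume_ml / voxel_ml))
    out = np.zeros(shape, dtype=bool)
    if n <= 0:
        return out
    grids = np.meshgrid(
        *[(np.arange(sh) - c) * s for sh, c, s in zip(shape, center_vox, spacing)],
        indexing="ij",
        sparse=True,
    )
    dist2 = sum(g**2 for g in grids).ravel()
    order = np.argsort(dist2, kind="stable")[:n]
    out.ravel()[order] = True
    return out.reshape(shape)


def _ball_radius_mm(volume_ml: float) -> float:
    return (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _render_sequences(
    params: PhantomParams,
    brain: np.ndarray,
    regions: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> SequenceSet:
    """Paint tissue intensities, innermost regions last, then add noise."""
    order = ["snfh", "cavity", "enhancing", "necrosis"]
    volumes = {}
    for seq, levels in TISSUE_INTENSITY.items():
        img = np.zeros(params.shape, dtype=np.float64)
        img[brain] = levels["brain"]
        for tissue in order:
            if tissue in regions:
                img[regions[tissue]] = levels[tissue]
        if params.noise_sd > 0:
            img[brain] += rng.normal(0.0, params.noise_sd, size=int(brain.sum()))
        np.clip(img, 1.0, None, out=img, where=brain)
        volumes[seq] = VolumeGrid(img, params.spacing)
    return SequenceSet(volumes)


def _timepoint_masks(
    params: PhantomParams, rng: np.random.Generator, negative: bool
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Returns (preop structures, postop structures, shared geometry)."""
    shape, spacing = params.shape, params.spacing
    brain_center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    brain = ellipsoid_mask(shape, spacing, brain_center, params.brain_semi_axes_mm)

    tc_ml = float(rng.uniform(*params.tc_volume_ml))
    jitter = rng.uniform(-params.center_jitter_mm, params.center_jitter_mm, size=3)
    center_vox = tuple(
        (c + j) / s for c, j, s in zip(brain_center, jitter, spacing)
    )

    tc = exact_volume_mask(shape, spacing, center_vox, tc_ml) & brain
    netc = (
        exact_volume_mask(shape, spacing, center_vox, tc_ml * params.necrosis_fraction)
        & tc
    )
    halo_r = int(np.ceil(params.snfh_margin_mm / min(spacing)))
    ball = ndimage.generate_binary_structure(3, 1)
    snfh_pre = ndimage.binary_dilation(tc, ball, iterations=halo_r) & brain & ~tc

    cavity_ml = tc_ml * float(rng.uniform(*params.cavity_fraction))
    cavity = exact_volume_mask(shape, spacing, center_vox, cavity_ml) & brain

    et = np.zeros(shape, dtype=bool)
    if not negative:
        n_frag = int(rng.integers(params.residual_fragment_count[0],
                                  params.residual_fragment_count[1] + 1))
        cav_r = _ball_radius_mm(cavity_ml)
        for _ in range(n_frag):
            frag_ml = float(rng.uniform(*params.fragment_volume_ml))
            frag_r = _ball_radius_mm(frag_ml)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = (cav_r + frag_r + 1.0) * direction
            frag_center = tuple(
                cv + o / s for cv, o, s in zip(center_vox, offset, spacing)
            )
            frag = exact_volume_mask(shape, spacing, frag_center, frag_ml)
            et |= frag & brain & ~cavity
    post_margin = max(int(np.ceil(params.snfh_margin_mm * 0.6 / min(spacing))), 1)
    snfh_post = (
        ndimage.binary_dilation(cavity | et, ball, iterations=post_margin)
        & brain & ~cavity & ~et
    )

    pre = {"TC": tc, "NETC": netc, "SNFH": snfh_pre, "BRAIN": brain}
    post = {"ET": et, "CAVITY": cavity, "SNFH": snfh_post, "BRAIN": brain}
    geom = {"brain": brain, "tc": tc, "netc": netc, "cavity": cavity, "et": et,
            "snfh_pre": snfh_pre, "snfh_post": snfh_post}
    return pre, post, geom


def generate_patient(
    params: PhantomParams,
    patient_id: str = "p000",
    negative: bool = False,
    seed: Optional[int] = None,
) -> PatientStudy:
    """Generate one perioperative study (sequences + ground-truth masks).

    ``negative`` suppresses the postoperative residual fragments, producing
    a structure-absent (ET-negative) sample.  Fully deterministic for a
    given seed (defaults to ``params.seed``).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pre_masks, post_masks, geom = _timepoint_masks(params, rng, negative)

    pre_regions = {
        "snfh": geom["snfh_pre"],
        "enhancing": geom["tc"] & ~geom["netc"],
        "necrosis": geom["netc"],
    }
    post_regions = {
        "snfh": geom["snfh_post"],
        "cavity": geom["cavity"],
        "enhancing": geom["et"],
    }
    pre_seq = _render_sequences(params, geom["brain"], pre_regions, rng)
    post_seq = _render_sequences(params, geom["brain"], post_regions, rng)

    def _structset(masks: Dict[str, np.ndarray]) -> StructureSet:
        return StructureSet(
            {k: BinaryMask(v, params.spacing) for k, v in masks.items()}
        )

    return PatientStudy(
        patient_id=patient_id,
        timepoints={
            "preoperative": Timepoint(pre_seq, _structset(pre_masks)),
            "postoperative": Timepoint(post_seq, _structset(post_masks)),
        },
        tumor_contrast_enhancing=params.contrast_enhancing,
    )


def generate_cohort(
    n_patients: int,
    params: PhantomParams,
    fold_count: int = 5,
    seed: int = 0,
    negative_fraction: float = 0.0,
) -> List[Tuple[PatientStudy, int]]:
    """Generate a cohort with cross-validation fold labels.

    Each patient (with both timepoints) is assigned to exactly one fold;
    fold sizes differ by at most one.  ``negative_fraction`` of the patients
    (rounded) carry no residual tumor.
    """
    if n_patients < fold_count:
        raise ValueError("need at least one patient per fold")
    rng = np.random.default_rng(seed)
    n_neg = int(round(negative_fraction * n_patients))
    negatives = set(rng.choice(n_patients, size=n_neg, replace=False).tolist())
    order = rng.permutation(n_patients)
    folds = {int(p): i % fold_count for i, p in enumerate(order)}
    cohort = []
    for i in range(n_patients):
        study = generate_patient(
            params,
            patient_id=f"p{i:03d}",
            negative=i in negatives,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append((study, folds[i]))
    return cohort


def perturb_mask(gt: BinaryMask, spec: PerturbationSpec) -> BinaryMask:
    """Apply seeded morphological/topological corruption scaled by severity.

    At severity 0 the mask is returned unchanged.  When both dilate and
    erode are enabled one of the two is picked at random per seed (applying
    both would largely cancel); translation shifts by up to 6 voxels;
    drop/add component operations fire with probability equal to severity.
    """
    values = gt.values.copy()
    s = spec.severity
    if s == 0:
        return BinaryMask(values, gt.spacing, gt.origin)
    rng = np.random.default_rng(spec.seed)
    struct = ndimage.generate_binary_structure(3, 1)

    morph = [op for op in ("dilate", "erode") if op in spec.operations]
    if morph:
        op = morph[int(rng.integers(len(morph)))]
        iters = int(round(s * 3))
        if iters > 0 and values.any():
            if op == "dilate":
                values = ndimage.binary_dilation(values, struct, iterations=iters)
            else:
                values = ndimage.binary_erosion(values, struct, iterations=iters)
    if "translate" in spec.operations:
        shift = int(round(s * 6))
        if shift > 0:
            axis = int(rng.integers(3))
            sign = 1 if rng.random() < 0.5 else -1
            values = np.roll(values, sign * shift, axis=axis)
            # zero-fill the wrapped slab
            sl = [slice(None)] * 3
            sl[axis] = slice(0, shift) if sign > 0 else slice(-shift, None)
            values[tuple(sl)] = False
    if "drop_component" in spec.operations:
        labels, n = ndimage.label(values, structure=np.ones((3, 3, 3)))
        drop = [lab for lab in range(1, n + 1) if rng.random() < s]
        if drop:
            values[np.isin(labels, drop)] = False
    if "add_false_component" in spec.operations and rng.random() < s:
        r = 2 + int(round(s * 3))
        center = tuple(int(rng.integers(r, dim - r)) for dim in values.shape)
        blob = ellipsoid_mask(values.shape, gt.spacing,
                              tuple(c * sp for c, sp in zip(center, gt.spacing)),
                              (r,) * 3)
        values = values | blob
    return BinaryMask(values, gt.spacing, gt.origin)


class OraclePredictor:
    """Location-aware patch predictor built from a known structure mask.

    Fulfils the :class:`~perivox.inference.PatchPredictor` contract; the
    output patch is the (optionally Gaussian-blurred, noised) indicator of
    the chosen structure restricted to the patch.  Blur and noise fields are
    precomputed on the whole volume, so predictions are deterministic and
    consistent across overlapping windows.
    """

    def __init__(
        self,
        structures: StructureSet,
        structure: str,
        blur: float = 0.0,
        noise: float = 0.0,
        seed: int = 0,
        patch_shape: Tuple[int, int, int] = (64, 64, 64),
        channels: Tuple[str, ...] = ("t1c",),
    ):
        if structure not in structures:
            raise ValueError(f"structure {structure!r} not in set: {sorted(structures)}")
        self.channels = channels
        self.patch_shape = patch_shape
        field = structures[structure].values.astype(np.float64)
        if blur > 0:
            field = ndimage.gaussian_filter(field, blur)
        if noise > 0:
            field = field + np.random.default_rng(seed).normal(0.0, noise, field.shape)
        self._field = np.clip(field, 0.0, 1.0)

    def __call__(self, patch: np.ndarray, origin: Tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(self.patch_shape, dtype=np.float64)
        src, dst = [], []
        for o, p, n in zip(origin, self.patch_shape, self._field.shape):
            lo, hi = max(o, 0), min(o + p, n)
            if lo >= hi:
                return out
            src.append(slice(lo, hi))
            dst.append(slice(lo - o, hi - o))
        out[tuple(dst)] = self._field[tuple(src)]
        return out


def make_oracle_predictor(
    structures: StructureSet,
    structure: str,
    blur: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    patch_shape: Tuple[int, int, int] = (64, 64, 64),
) -> OraclePredictor:
    """Predictor whose sliding-window map, binarized at 0.5, reproduces the
    chosen ground-truth structure exactly when blur = noise = 0."""
    return OraclePredictor(structures, structure, blur, noise, seed, patch_shape)
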