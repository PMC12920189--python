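# Methods

This note documents the models, conventions and design choices behind
`perivox`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic phantoms do and do not show.

## Grid conventions

All volumes live on axis-aligned grids with 0-based voxel indices,
half-open bounding boxes, and the third array axis indexing axial slices.
Spacing is per-axis voxel edge length in mm; volumes are converted to ml as
`voxel_count × spacing_x × spacing_y × spacing_z / 1000`. NIfTI I/O keeps a
diagonal affine (spacing on the diagonal, origin in the translation
column); masks persist as uint8, probability maps as float32. Registration,
bias-field correction and skull stripping are out of scope — inputs are
assumed co-registered and a brain mask is an input, not a prediction.

## Preprocessing

The canonical order is: (i) resample to 1 mm isotropic, (ii) tight-crop to
the head, (iii) build the t1d = t1c − t1w difference channel, (iv) clip
intensities to the [0, 99.5] percentile range, (v) zero-mean normalization
of nonzero voxels.

Numerical choices:

- **Resampling** uses corner-aligned sampling (output voxel *i* sits at
  physical coordinate *i*·target), trilinear for intensities and
  nearest-neighbour for masks (preserves binarity). Output shape is
  `round(shape × spacing / target)`. On a linear ramp the interior values
  reproduce closed-form linear interpolation to 1e-6.
- **Percentile clipping** uses linear-interpolation percentiles over *all*
  voxels including background zeros. Whether background should be excluded
  is genuinely open; including it is the simpler contract and is what the
  tests pin down.
- **Normalization** is zero-mean, *unit-variance* over the voxels that were
  nonzero before normalization; exact zeros stay zero. The variance step is
  standard practice and is exposed as a switch (`unit_variance=False`) for
  pipelines that want pure mean-centering. A constant nonzero foreground is
  mean-subtracted and the scaling step is skipped rather than raising.
- **Connected components** default to 26-connectivity, the most permissive
  standard 3D neighbourhood.

## Sliding-window inference and the predictor contract

A *patch predictor* declares its input channels and patch shape and maps a
`(C, X, Y, Z)` patch to a same-shape probability patch; the call also
receives the patch origin in (unpadded) volume coordinates. The origin is
not needed by convolutional models, which may ignore it, but it is what
makes location-aware mock predictors — including the phantom oracle and
window-indexing probes used in tests — expressible within the same
contract.

Whole-volume assembly tiles the volume at a configurable overlap (default
50%, i.e. stride = patch/2), padding symmetrically with zeros when an axis
is shorter than the patch. Overlapping window predictions are fused by
**unweighted mean**: Gaussian window weighting was deliberately not used
because the unweighted mean has an exact, testable identity (a voxel-wise
defined predictor is reproduced bit-exactly at any overlap). The default
inference patch is 160³ voxels; the phantom-scale pipelines use 64³ so full
runs complete in seconds — patch shape is a predictor property, not a
constant of the method.

**Test-time augmentation** averages the identity pass with one pass per
enabled transform (flip, axial rotation, gamma contrast), inverting
geometric transforms on the predicted map before averaging. Flips use a
random axis and are exactly invertible; rotation draws an angle in
[−20°, 20°] about the axial axis with trilinear regridding, so its
inversion is approximate (standard TTA behaviour); gamma rescales each
channel to [0, 1], applies the exponent drawn from [0.5, 2.0], and maps
back — an intensity transform needing no inversion. All draws come from the
config seed, making TTA reproducible.

**Ensembling** fuses 1–5 probability maps voxel-wise by mean (`average`) or
maximum (`amax`).

**Postprocessing** is two-step: (1) zero all probabilities outside the
brain mask; (2) binarize at the reporting threshold, and erase every
connected component smaller than 0.05 ml *or* not extending over at least
two consecutive axial slices. "Consecutive slices" is read as ≥2 adjacent
axial slices on the 1 mm grid. The component rules operate on the map
binarized at the same threshold later used for reporting, and erase
probabilities (not just mask voxels), which makes the operation idempotent.
In the orchestrated pipeline the component filter is applied to the
residual-tumor structure only; all other structures get the
brain-restriction step alone.

## Cross-structure refinement

Single-structure models are trained independently, so their masks can
disagree. The consistency rules, split by contrast-enhancing (CE) status:

- *preop CE*: TC is the untouched reference; NETC ← NETC ∩ TC;
  SNFH ← SNFH \ TC; WT ← TC ∪ SNFH (a disjoint union). Restricting NETC to
  TC also implies NETC is excluded from the refined SNFH.
- *postop CE*: ET is the untouched reference; SNFH ← SNFH \ (CAVITY ∪ ET).
  Cavity and ET are removed jointly, which is order-independent by
  construction. Overlap *between* ET and the cavity has no defined rule and
  is left untouched; the report flags it as a warning.
- *non-CE*: SNFH serves as the whole tumor mask; postoperatively the cavity
  is subtracted from it first.

Absent structures are skipped; all outputs are restricted to the brain mask
when present (reference masks are unchanged by this whenever they lie
inside the brain, which holds for phantoms and any plausibly skull-stripped
input); the brain mask itself is never modified. Refinement is idempotent.

## Reporting

Per structure and timepoint the report carries volume (ml), diameter
characteristics, tumor-to-brain ratio (reported as a percentage) and
component count. Diameters are **slice-based**, measured on the axial slice
of maximal in-slice lesion area, matching the bidimensional RANO
convention: the Feret diameter is the maximal point-pair (caliper) distance
between foreground pixel centers (computed on the convex hull); long/short
axes are the major/minor axes of the second-moment best-fit ellipse; the
equivalent diameter is `2·sqrt(area/π)`. 3D alternatives were rejected as
inconsistent with an area-based convention. A single-pixel lesion has a
well-defined equivalent diameter (2/√π mm) and a degenerate (zero) Feret.

Volumetric evolution is `100·(pre − post)/pre` %, negative under growth,
exactly 100 when the postoperative volume is zero, and not-applicable
(reported as null, not an exception) when the preoperative volume is zero.
For CE tumors the tumor proxy is TC preoperatively and ET postoperatively;
for non-CE tumors SNFH serves as the tumor proxy.

The surgical assessment maps the postoperative residual (ET) volume to
*complete* (< 0.175 ml — the ET detectability cut-off), *near total*
(≤ 1.0 ml) or *subtotal*. The exact category bounds are not fixed by the
RANO citation chain, so they are policy fields echoed into every report,
never hard-coded. Non-CE tumors have no enhancing residual; no category is
assigned and the cavity volume documents the resection (a warning says so).
A Brain-Grid location field is carried as a placeholder (null): it requires
atlas registration, which is out of scope. Reports serialize to JSON with
sorted keys and fixed rounding, so identical inputs give identical bytes.

## Validation framework

- **Threshold sweep**: the probability map is binarized at ten
  equally-spaced thresholds k/10, k = 1..10 (threshold 0 would binarize
  everything, so the open lower boundary is excluded); the masks are nested
  by construction. The reported operating point maximizes mean voxel-wise
  Dice over positive samples, ties broken toward the higher threshold.
- **Patient-wise**: positivity of *both* ground truth and prediction uses
  the same per-structure volume cut-off (the symmetric reading); TP
  additionally requires Dice > 0.1%.
- **Voxel-wise**: Dice/recall/precision in %, HD95 in mm via surface voxels
  (6-neighbourhood erosion residue) and KD-tree nearest distances, linear
  interpolation percentiles. Two empty masks agree perfectly (Dice 100,
  HD95 0) — such samples are negative and excluded from positive-sample
  aggregates anyway; one empty operand gives Dice 0 and an undefined HD95.
- **Object-wise**: components below 75 voxels (50 for NETC) are discarded;
  survivors are matched one-to-one by the Hungarian algorithm minimizing
  total 1 − Dice with zero-overlap pairs forbidden. Sample-level values are
  means over matched pairs with unmatched ground-truth components
  contributing 0 to Dice and recall and unmatched predictions 0 to Dice and
  precision; HD95 averages over matched pairs only (components that were
  never paired have no meaningful surface distance).
- **Pooling**: fold means/SDs are pooled into exactly the sample statistics
  of the concatenated per-sample values
  (`var = [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m)²]/(Σnᵢ−1)`), verified against
  concatenation to 1e-9.
- **Sensitivity analysis**: patient-wise confusion counts are recomputed
  with the TP Dice threshold swept through {0.1, 10, 25, 50, 75}%;
  negative-sample rows are unchanged by construction and the TP count is
  non-increasing in the threshold.

All percentages are reported on the 0–100 scale.

## Synthetic phantoms

The generator emulates a perioperative CE-glioma study on a 96³ grid at
1 mm (tests use 64³ with proportionally smaller structures): an ellipsoidal
brain (semi-axes 42/38/34 mm); preoperatively a tumor core of 15–35 ml with
a 30% necrotic interior (NETC ⊂ TC) and an 8 mm dilated FLAIR-hyperintense
halo (SNFH, disjoint from TC); postoperatively a cavity of 60–90% of the
core volume, 1–3 residual fragments of 0.05–1 ml placed on the cavity
margin — deliberately straddling the 0.175 ml detectability cut-off — and a
shrunken halo disjoint from cavity and residual. Tumor-like structures are
*exact-count balls* (the requested volume converted to a voxel count, and
exactly that many nearest-to-center voxels set), so ground-truth volumes
are exact and requested-vs-realized volume agreement is within rasterization
error for ellipsoidal structures (≤5% for targets ≥0.5 ml). Sequences are
piecewise-constant tissue intensities (enhancing tissue bright on t1c but
not t1w; cavity CSF-dark on t1c, bright on t2w; halo bright on FLAIR) with
Gaussian noise of SD 10 inside the brain. Clean phantoms already satisfy
every refinement invariant, making refinement a fixed point on them.

What the phantoms do **not** model: MR physics (bias fields, partial
volume, texture), anatomy (ventricles, midline, atlas space), irregular
lesion geometry, and imperfect co-registration. Passing tests therefore
demonstrate the correctness of the computational pipeline — geometry,
accounting, metrics, determinism — not segmentation performance on clinical
data.

The *oracle predictor* turns a ground-truth structure into a patch
predictor (optionally blurred/noised with precomputed, seeded fields so
overlapping windows agree); with no corruption the assembled map binarized
at 0.5 reproduces the structure bit-exactly. The *perturbation* module
degrades masks with severity-scaled dilation/erosion (one of the two per
seed — applying both would cancel), translation, component dropping and
false-component injection; mean Dice against the original is
non-increasing in severity when averaged over seeds.

Cohorts assign each patient (both timepoints) to exactly one of five folds,
with fold sizes differing by at most one and a configurable fraction of
residual-negative patients.

## Orchestration and problem sizes

The `run` pipeline chains simulate → segment (oracle) → postprocess →
refine → report → validate. The sequence- and tumor-type classification
stages of a full clinical system are interface points satisfied by manifest
labels (trained classifiers are out of scope). Demo and test runs use 5
patients on 96³ (or 3 on 64³) grids with 64³/48³ patches, completing in
well under two minutes on one CPU; the acceptance flip-point search probes
volumes at one-voxel (0.001 ml) resolution over 0.05–0.5 ml. Determinism is
end-to-end: one seed drives phantom geometry, noise, TTA draws and
perturbations (per-patient streams derive from a CRC of the patient id), and
reports/CSVs serialize with fixed rounding so reruns are byte-identical.

## Known limitations

- Diameters assume in-plane isotropy of the reporting grid (the standard
  1 mm resampled space); strongly anisotropic native grids should be
  resampled first.
- HD95 is computed between surface *voxel centers*; sub-voxel surface
  placement is not modelled.
- The TTA rotation inverse is approximate (interpolation twice); flip and
  gamma passes are exact.
- Object-wise HD95 over unmatched components is undefined by convention
  here; alternatives (penalty distances) exist in other lesion-wise
  benchmarks and would change absolute values.
- The non-CE surgical assessment is intentionally absent rather than
  SNFH-derived; an SNFH-volume-based category would need thresholds with no
  clinical grounding.
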