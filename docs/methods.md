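# Methods

This note describes the models and procedures implemented in `brainslide`,
the choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about behaviour on real slides.

## Problem setting

A digitized histology slide carries a grid of mouse-brain coronal sections,
possibly with empty positions and hand-written ink notes. The pipeline
(1) detects tissue sections and notes, (2) links each section to its cell in
an experimental layout table, (3) selects the anatomically closest layer of a
reference template stack, (4) registers that layer onto the section with an
affine stage followed by landmark-regularized diffeomorphic elastic
registration, and (5) transfers the layer's named regions of interest (ROIs,
e.g. caudoputamen) onto the section and scores the result.

## Detection (`detect`)

The baseline detector is classical: the slide is inverted (tissue is darker
than the glass background), thresholded (Otsu by default), closed with a
2-px disk, and split into connected components. Components are classified by
shape: compact blobs (area ≥ `min_brain_area`, default 1500 px; solidity
≥ 0.80) are brains; thin strokes (solidity < 0.80 or mean stroke width
≤ 4 px, computed as twice the mean distance-to-background) are notes;
everything else is dropped. Stroke width is measured on the *pre-closing*
foreground: closing is needed to solidify tissue but fattens thin ink
strokes, which would otherwise disguise a dense scribble as a compact blob. Output order is fixed by (y_min, x_min). The
detector is a plain function returning `DetectedObject`s, so a trained
instance-segmentation model can replace it without changing the rest of the
pipeline. Thresholds are configuration with stated defaults; none of them is
derived from data.

## Metadata linking (`link`)

Brain centroids (pixels) and layout cells (column/row indices) are brought
into one unit of measurement by per-axis z-scoring (zero-variance axes are
centered only), then matched by the Hungarian algorithm. The cost is the
*squared* Euclidean distance: it matches the convention of the landmark term
(see below) and is smooth everywhere. Assignment is rectangular — a slide
with missing brains leaves layout cells unmatched, and these are reported,
never guessed. Optimality is verified against exhaustive permutation search
in the test suite.

## Layer matching (`atlas_match`)

Query and template layers are resized so the longer side is 460 px (aspect
preserved, zero-padded to a common square). Each layer is then coarsely
aligned to the query by a reduced-iteration similarity registration (200
iterations by default, run at a downsampled working resolution of 460/4 px
to keep a full stack sweep fast) and scored by normalized cross-correlation
after alignment; the best-scoring layer wins, with ties resolved to the
lower layer id. The matcher fills the interface a trained classifier would
occupy (image in, layer id out); accuracy is reported with a ±k layer
tolerance, since neighbouring coronal sections are anatomically
near-equivalent.

## Correspondences (`landmarks`)

Sparse semantic correspondences come from a classical mutual-best-match
("best buddies") detector: Harris corners in both images, zero-mean
unit-norm patch descriptors (15×15 px), and a pair is kept only when each
point is the other's highest-correlation match with correlation ≥ 0.6. At
most 32 pairs are kept, strongest first. A median-absolute-deviation filter
(factor 3.5 on the deviation of each pair's displacement from the
componentwise median displacement) rejects wild correspondences, which would
otherwise corrupt the landmark term; the rule is scale-free. Expert-supplied
landmark CSV files pass through the same container and the same filter.

## Registration (`register`)

**Affine stage.** A similarity transform (rotation, isotropic scale,
optional x-reflection, translation, fixed center at the image center) is
fitted by minimizing `1 − NCC` with Adam (learning rate 0.01, 1000
iterations). Gradients are forward finite differences over the four
continuous parameters; translation is parameterized in units of half the
image diagonal so a single learning rate moves all parameters on comparable
scales. Reflection is a discrete two-way restart; the restart with the lower
final loss wins. Initialization is the identity, optionally shifted so the
intensity centroids coincide (on by default).

**Elastic stage.** The deformation is parameterized by cubic-B-spline
coefficients of a stationary velocity field `v` on a coarse lattice
(default spacing: image size / 16, one extra control row/column beyond each
edge). The dense displacement used to resample the moving image is the
group exponential `exp(v)` computed by scaling and squaring (6 steps), which
keeps the Jacobian determinant of the map positive — topology preservation
is enforced as a hard contract: a non-positive determinant anywhere raises
an error instead of returning a folded field. The loss is

    Loss = NCC + λ1·DF + λ2·LRT,      λ1 = λ2 = 0.5

with DF the diffusion regularizer (mean squared forward-difference gradient
of the dense displacement; zero for any pure translation) and LRT the
landmark term: the squared Euclidean distance between warped moving-image
landmarks and their fixed-image correspondences, summed over pairs and both
coordinates. The term entering the weighted loss is normalized by the number
of pairs so λ2 = 0.5 means the same thing with 4 landmarks as with 40; the
unnormalized sum is reported alongside. Landmarks enter the elastic stage
only; the affine stage is landmark-free. When landmarks disagree with the
smoothness prior, the quadratic pull lets the field deform more where
anatomy demands it — the per-iteration loss breakdown
(`total = ncc + λ1·df + λ2·lrt`, exact to 1e-9 at every logged iteration)
makes this auditable.

**Field conventions.** One velocity field yields two exact mutual inverses:
images are warped backward through `exp(v)` (output coordinate x samples the
moving image at `x + u(x)`), points are warped forward through `exp(−v)`.
Both operations "add an interpolated displacement", each from its own dense
field, and composing them is the identity up to interpolation error.
Non-diffeomorphic fields invert numerically by fixed-point iteration.

**Gradients.** Gradients of the elastic loss are analytic: the NCC gradient
with respect to the warped image, chained through the spatial gradient of
the moving image and the exact adjoint of the separable B-spline
interpolation (two small matrix products per component). The scaling-and-
squaring exponential is linearized (treated as the identity) in the backward
pass — a standard small-deformation approximation that is exact at v = 0 and
accurate for the smooth, moderate fields this pipeline estimates; loss
*values* are always evaluated through the exact exponential. The optimizer
is Adam with conventional β parameters, learning rate 0.01, 1000 iterations
per stage.

**Polarity.** The pipeline registers inverted luminance (tissue bright on a
~zero background) so that the zero fill of out-of-bounds backward sampling
matches the background. `register` itself applies no inversion — stain
polarity is the caller's preprocessing concern.

## ROI transfer and scoring (`evaluate`)

ROI masks are resampled with nearest-neighbour interpolation through the
composed transform (affine, then the elastic field in the aligned frame) in
a single backward pass; polygon vertices are forward-mapped point-wise. An
ROI that leaves the field of view returns an empty mask with a warning flag,
not an error. Overlap is scored as F1 on binary masks, which equals the Dice
coefficient 2|A∩B|/(|A|+|B|); F1 is computed per (brain, ROI) pair at full
resolution and aggregated by mean. Expert 1–5 ratings binarize at ≤ 2
("useful": no or minor adjustment needed) — a single constant used in
exactly one place — and inter-rater agreement uses unweighted Cohen's kappa,
on either the 5-category or the binarized scale.

## Phantoms (`phantom`)

The generator emulates the study conditions end to end with exact ground
truth. One synthetic coronal section is a smoothly-wobbled, left/right
asymmetric ellipse filled with band-limited noise texture (mid-gray on a
near-white background, faint scanner noise), carrying a large CP-like and a
small commissure-like ROI (both slightly darker, both strictly inside the
tissue) and ≥ 8 landmarks on texture extrema. A template stack morphs one
base section along a monotone one-parameter family (width grows, height
shrinks, texture drifts), so layer similarity falls off with layer distance
and ±k tolerance accuracy is meaningful. Slides paste one jittered
(±8° rotation, ±5 % scale, ±6 px translation), elastically deformed
(max 6 px by default, B-spline velocity fields with everywhere-positive
Jacobian) copy of a random stack layer into each non-missing cell of a
rows×cols grid (128-px tiles, 36-px margins), and draw 1–3-px-wide ink
polylines in an off-tissue strip, mutually separated by ≥ 8 px so the truth
object count stays well defined under morphological closing. All randomness flows through one seeded
generator; every artifact is a pure function of (parameters, seed).

What phantoms do *not* model: stain-specific appearance (H&E vs Nissl vs
IHC), tears and folds, intensity inhomogeneity, partial sections, real
anatomical variability between subjects, and cross-modality contrast between
atlas drawings and tissue. Passing the phantom suite therefore demonstrates
the correctness of the geometry, optimization and bookkeeping — not that the
classical detector, matcher or correspondence finder reach trained-model
accuracy on real slides. Those three components are deliberately pluggable.

## Problem sizes and numerical choices

Phantom sections are 128 px (96 px in the paired landmark-efficacy runs),
slides up to 3×5 sections; registration runs single-threaded on CPU in a few
seconds (affine) to ~15 s (elastic) per pair at these sizes. Bilinear
interpolation everywhere except nearest-neighbour for masks; out-of-bounds
samples are zero. Finite-difference step 1e-3 in the affine stage;
B-spline adjoint is exact; ties in detection ordering, layer matching and
assignment break deterministically (position, lower id, lower index). The
MAD filter keeps pairs within `3.5·MAD + 1e-9` of the median displacement —
the epsilon keeps an all-consistent pair set intact when MAD is exactly
zero. Degenerate inputs fail loudly: zero-variance images in NCC, empty
metadata tables, duplicate labels, non-positive Jacobians, malformed
landmark rows (with line numbers).

## Known limitations

* The elastic backward pass linearizes the exponential; for displacements
  far beyond the ~8 px regime exercised here the approximate gradient could
  slow or stall convergence before the Jacobian contract ever fires.
* The affine stage's loss landscape is only locally convex; rotations far
  beyond ±15° or gross initial misplacement need a better initializer than
  intensity centroids.
* The matcher assumes the query section truly has a counterpart in the
  searched layer range; it always returns the argmax layer and never
  abstains.
* Rectangular assignment absorbs translation and isotropic scale between the
  two grids (via standardization) but not rotation or shear of the slide
  layout.
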