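# Methods

## The measurement being automated

The vertebral heart scale (VHS) expresses cardiac silhouette size in
vertebral-length units so that it is comparable across dogs of different
body size.  Six landmarks are placed on a lateral thoracic radiograph:
the long axis of the heart from the carina to the apex (`A`→`B`), the
short axis at the widest point, drawn perpendicular to the long axis
(`C`→`D`), and a vertebral reference segment from the cranial aspect of
T4 to the caudal end of the ninth vertebra (`E`→`F`), i.e. six vertebral
lengths.  Then

    VHS = 6 · (|AB| + |CD|) / |EF|

and hearts are classed *small* (VHS < 8.2), *normal* (8.2 ≤ VHS ≤ 10,
both boundaries inclusive, taken literally from the defining
inequalities) or *large / cardiomegaly* (VHS > 10).  The score is a ratio
of lengths, hence invariant under rotation, translation and uniform
scaling; this invariance is enforced by property tests.

## Model

The regressor is a pyramid vision transformer.  Each stage embeds
non-overlapping patches, adds a learnable position embedding, and stacks
pre-norm transformer blocks whose attention is **spatial-reduction
attention (SRA)**: queries come from the full token grid while keys and
values come from a reduced copy in which each `R×R` neighborhood is
concatenated, linearly projected back to the stage width and
layer-normalized.  Attention is `softmax(QKᵀ/√d + B)V` with an optional
learned per-head relative-position bias `B` (a `(2M−1)²` table indexed by
quantized query-to-key offsets; a config flag disables it).

A **feature fusion module** combines a texture-level early-stage map and
a shape-level later-stage map: each passes through its own 3×3
convolutional unit projecting to a common width, the coarse map is
bilinearly upsampled to the fine grid, and the two are concatenated along
channels.  Global average pooling then feeds a fully connected regression
head whose twelve sigmoid outputs are the six keypoints in normalized
[0, 1] coordinates, plus a classification path (below).

The **orthogonal layer** is the final differentiable layer.  With
`(x1,y1),(x2,y2)` the long axis and `(x3,y3),(x4,y4)` the short axis, it
replaces `y4` by

    s = −(x1−x2)/(y1−y2),    ŷ4 = s·(x4−x3) + y3

which makes `CD` exactly perpendicular to `AB` (the dot product vanishes
algebraically).  Gradients flow through `s` to all contributing
coordinates; in particular `∂ŷ4/∂x4 = s`, verified against finite
differences.  When `AB` is horizontal (`|y1−y2| < 1e−6`) the slope is
undefined and the symmetric rule is applied instead — `x4` is replaced by
`x3`, making `CD` vertical — so the perpendicularity contract holds for
every input.  The projection is exactly idempotent.  The layer is active
during training and at inference.

Two numerical choices matter here:

* **Head initialization.**  At an uninformed initialization every
  sigmoid output sits at 0.5, so `y1−y2 ≈ 0` and the orthogonal layer's
  slope is enormous, which destabilizes the first hundred steps badly.
  Both heads therefore start near zero: the regression head's weights
  are drawn at σ = 1e−3 with its bias set to the logit of a rough
  anatomical layout (oblique long axis, horizontal vertebral segment),
  so decoded points begin at that layout and the slope is well
  conditioned from step one; the auxiliary class head likewise starts
  near zero (uniform logits), so early cross-entropy gradients grow
  gently instead of distorting the shared trunk before coordinate
  learning starts.  The layout constant is generic, not fitted to any
  dataset.
* **Classification path.**  The described output is only the twelve
  coordinates, yet the objective includes a cross-entropy term, so two
  head modes are provided: `aux_head` (default) — a parallel 3-unit
  linear head on the pooled fused features — and `soft_vhs`, in which
  logits are negative squared distances of the *predicted VHS* to
  class-interval midpoints over a temperature, making classification
  fully geometric.  In both modes the class label *reported at inference*
  is always derived from the predicted keypoints through the VHS
  thresholds, so geometry and diagnosis can never disagree.

Two printed-formula ambiguities are resolved as follows: the fusion
equation's repeated operand is read as fusing the low- *and* high-level
features (the surrounding description of the module), and the stated
convolution hyperparameters (1×16 kernels, stride 96, dilation 9), which
are not geometrically realizable on the stated grids, are replaced by
stride-1, padding-1 3×3 projections plus bilinear upsampling — the
standard operator pair with the same intent.  Both are recorded here as
deliberate design choices.  The relative-bias table is likewise stated
with an asymmetric shape inconsistent with a square attention map; the
implementation uses the symmetric `(2M−1)²` form standard for relative
position biases.

## Objective and training

    L = (1/n) Σᵢ [ CE(f(xᵢ), y_tᵢ) + γ · MSE(f(xᵢ), yᵢ) ]

with γ = 0.01 and the class target derived from the ground-truth VHS.
γ = 0 recovers classification-only training (the "C-accuracy"
baseline); `objective="mse"` trains keypoints alone and is what the
bootstrap regressor uses.

**MSE units.**  The regression targets are normalized to [0, 1] (the
sigmoid's range), but the squared error in the loss is measured in
pixels of the square model frame — residuals are scaled by the input
size before squaring.  With normalized residuals, γ·MSE would sit around
1e−5 against a cross-entropy near 1, and measured runs confirm the joint
objective then never learns geometry; with pixel units the two terms
have comparable magnitude (and at 512 px input the MSE term dominates,
consistent with coordinate error being the primary training signal).
This unit convention is a deliberate design choice of this package.

Optimization is Adam at a constant learning rate with seeded shuffling
and global gradient-norm clipping at 1.0 in the desk preset — the
cross-entropy term produces occasional large gradients on
class-boundary-ambiguous samples, and clipping prevents those spikes
from perturbing the fine localization the MSE term is converging to.
The loop checkpoints the parameters with the best validation R-accuracy
and restores them at the end.  A non-finite loss aborts with a
diagnostic.

Two scales are configured:

| preset | input | stages | dims | heads | R | depths | lr | schedule |
|---|---|---|---|---|---|---|---|---|
| `full` | 512 | 4 | 64/128/320/512 | 1/2/5/8 | 8/4/2/1 | 2/2/2/2 | 3e-5 | 1000 epochs |
| `desk` | 96 | 2 | 32/64 | 1/2 | 4/2 | 2/2 | 1e-3 | ~2000 steps |

The desk preset is the package's CPU-scale working point: patch sizes
(6, 2) give 16×16 and 8×8 token grids, the MLP ratio is 2 and the fusion
width 64 (~0.3 M parameters); the higher constant learning rate (with
clipping, above) is appropriate for training this small model from
scratch, while the full-scale geometry and the original optimization
settings remain available behind the `full` preset.  Early stopping uses a patience of 600 steps on
validation accuracy (a patience much shorter than the validation period
times a few evaluations stops mid-climb on noisy small validation sets).

## Synthetic data

Real labeled radiographs are not publicly accessible, so the generator
renders the minimal scene that makes the six landmarks well defined and
the score controllable: a bright vertebral column of ≥9 equal-length
rounded segments along a gently curved arc (E and F at the cranial edge
of segment 4 and caudal edge of segment 9), and an elliptical cardiac
silhouette whose major-axis endpoints are A and B and whose minor axis
C–D crosses perpendicularly at the midpoint — so ground-truth
perpendicularity is exact by construction, matching the labeling rule the
landmarks are defined by.  Axis lengths are solved so the rendered VHS
equals the requested score exactly, with the aspect ratio |CD|/|AB| drawn
from [0.6, 0.85].  The whole scene is rotated (up to ±8°) and translated
analytically before rendering, so keypoints are exact and no resampling
blurs the image; additive Gaussian noise (sd 0.04 on the [0, 1] scale)
and a smooth illumination gradient are applied last.

Class frequencies default to the 208 : 573 : 619 three-class training
distribution the generator emulates; per-class VHS is uniform within
[6.5, 8.2), [8.2, 10], (10, 13] — the thresholds are all that is known
about the distribution, so uniform-within-class is assumed and
configurable.

What the generator does **not** emulate: breed and pose variation,
overlapping soft-tissue and rib structure, pleural effusion, exposure
artifacts, non-lateral projections.  Passing tests therefore demonstrate
that the architecture, objective and geometric layers are implemented
correctly and can be trained end-to-end to recover a controllable
VHS signal — not that the trained weights transfer to clinical images.

## Few-shot bootstrap

To emulate accelerating manual annotation, a base keypoint regressor is
trained on a small labeled split (three quarters of it; one quarter is
held out to report mean per-point pixel error) with the MSE objective,
then applied to every unlabeled image, writing `status="coarse"` records
for later human refinement.  Agreement between coarse and reference
coordinates is summarized by ICC(2,1) — the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation, the
standard form for inter-rater continuous measurements; the form is
printed alongside the value so the choice is auditable.

## Problem sizes used by the test suite and acceptance script

Desk-scale runs train on 500 synthetic images (validation 150) for about
2000 steps at batch 16, and the bootstrap uses 150 labeled plus 200
unlabeled images — sizes chosen so the whole suite runs on a single CPU
core in minutes while keeping every class populated.  The joint-vs-CE
comparison is run at a reduced scale (5 seeds, short runs) because its
claim is qualitative: with γ = 0 no gradient reaches the keypoint head,
so the geometric classification cannot beat the joint objective's.

## Known limitations

* Perpendicularity is guaranteed in the square model frame (and any
  uniformly scaled frame).  Mapping predictions back to a non-square
  source image scales x and y differently, which does not preserve
  angles; VHS and class are therefore always computed in the square
  frame.
* The engine is NumPy on one core: training wall-time, not statistics,
  limits the scale of what the tests demonstrate.
* `classify_vhs` requires positive finite scores; the vectorized model
  path floors |EF| at 1e-6 so early-training predictions yield large but
  finite scores.
* The factor 6 (vertebral span) is an exposed constant, not a CLI flag;
  other species or vertebral counts would change it.
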