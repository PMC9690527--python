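# Methods

## Problem and model

The package segments osteosarcoma (bone tumor) regions in independent 2-D
grayscale MRI slices: each pixel is classified tumor/background against a
physician-style binary mask. Slices from different scanners differ in
global brightness and most of each frame is empty background, so the
pipeline normalizes per slice and crops to the anatomy before the network
ever sees a pixel. No 3-D context, registration, or bias-field correction
is modelled — slices are treated as independent images.

The segmentation network, ACRNet, is a 4-stage encoder–decoder built from
parameter-sparse blocks:

- **Reservation block**: 1×1 convolution → channel layer-norm → ReLU.
  Changes channel count only; parameters c_in·c_out + 3·c_out.
- **Retracting block**: depthwise 3×3 (one kernel per channel, zero
  padding) → pointwise 1×1. Parameters 9·c_in + c_in·c_out (+ biases)
  versus 9·c_in·c_out for a full convolution.
- **Residual unit**: two retracting blocks with layer-norms, added to an
  identity (or 1×1-projected) skip before the final ReLU.
- **Attention condenser**: 2× max-pool → 1×1 reduction to c/ratio → ReLU
  → depthwise-separable embedding → 1×1 expansion to c → 2× nearest
  upsample → sigmoid. The resulting per-channel, per-position gates in
  (0,1) multiply the stage's features: attention can only attenuate, a
  property the tests assert elementwise.

Encoder stages (widths 32/64/128/256 by default, two residual units and
one condenser per stage) are joined by 2× max-pool + reservation blocks;
the decoder mirrors them with nearest-neighbour upsampling, skip
concatenation, a reservation block to merge channels, and one residual
unit per level; the head is a 1×1 convolution + sigmoid. The default
network has 582,529 trainable parameters (counted at instantiation and
cross-checked against a closed-form per-block audit in the tests),
comfortably inside the 6.91 M budget the lightweight design targets. The
published architecture's exact widths and depths are not recoverable from
its description, so this layout is an explicit reconstruction choice.

The excitation ordering in the channel-attention primitive is inner ReLU,
outer sigmoid — the standard squeeze-and-excite arrangement.

## Loss and training

The Tversky loss 1 − T(α, β) with α = 0.25 (false-positive weight),
β = 0.75 (false-negative weight), ε = 1e-8 drives training; the analytic
gradient is implemented directly and verified against finite differences.
T is computed over the whole minibatch (one global sum rather than a
per-image mean). α = β = 0.5 recovers the Dice coefficient exactly, which
the tests check as an algebraic identity.

The optimizer is Adam at the published learning rate 1e-4 (the optimizer
itself is unstated in the source design; Adam is the common choice for
medical segmentation and is stable with Tversky loss). The loss is
written as 1 − T so that it is minimizable (T = 1 is perfect). Checkpoint
selection uses Dice on the held-out fold. Splits are patient-level: a
seeded permutation assigns round(0.7·n) patients to training (210 → 147/63)
and 10-fold cross-validation partitions the training ids into folds whose
sizes differ by at most one.

Everything is seeded: weight initialization (He-uniform for convolutions,
ones/zeros for norm scales/offsets), batch shuffling, noise injection, and
the phantom generator, so fixed-seed reruns are bit-identical on CPU. The
layers and backpropagation are implemented in NumPy with im2col
convolutions; every layer's gradient is validated against central finite
differences in the test suite.

Two initialization choices matter for trainability at the fixed published
learning rate. The condenser's expansion bias starts at +2 so gates open
near sigmoid(2) ≈ 0.88: with condensers stacked in every stage,
zero-centred gates (0.5 each) would attenuate the forward signal
geometrically before training begins. The final norm scale of each
residual branch starts at zero, so every residual unit begins as (a ReLU
of) the identity. Both are standard stabilization tricks for residual and
gated architectures; without them, short training runs at lr 1e-4 stall on
some seeds.

## Augmentation and compound decision

The eight dihedral symmetries of the square (rotations k·90° CCW, each
optionally followed by a horizontal flip) form the augmentation orbit.
The literal recipe "originals + three rotations, then horizontal and
vertical flips of each" double-counts group elements; emitting the 8
unique orbit members makes the stated 8× expansion hold exactly, with all
copies pairwise distinct for asymmetric inputs. Noise augmentation is
additive Gaussian (σ = 0.05 of the normalized range on 25% of images by
default), applied after normalization, clipped to [0,1], never applied to
labels or at inference; the distributional choice is the package's own,
as the source design names no distribution.

Compound decision re-runs the model on all 8 copies, re-aligns outputs
with the inverse transforms, and takes a per-pixel majority vote with
ties counted as tumor (consistent with the recall priority). The printed
sign-function form of the vote, ½ − ½·sign(σ − n/2), selects the
*minority* and is undefined at ties; the implementation uses the
majority-vote reading and keeps the literal form behind a
`literal_eq6` flag for auditability. Binarize-then-vote is the default;
probability averaging is available behind a flag. Fusion over the full
orbit makes predictions exactly dihedral-equivariant, which the tests
check exhaustively.

## Metric conventions

Tumor is the positive class. The panel reports accuracy, precision, F1,
IoU and DSC, plus two recall variants: `recall_standard` = TP/(TP+FN) and
`recall_paper` = TN/(TN+FN), the negative-class ratio some published
panels print; F1 is computed from precision and `recall_paper` to match
that panel. Degenerate 0/0 ratios score 1 when both masks are empty
(perfect agreement) and 0 when only one is. Dataset aggregation is the
unweighted mean of per-slice metrics. SETT (mean wall time per training
epoch) is reported but never asserted against hardware-dependent values.

## Synthetic phantoms

The generator emulates what the pipeline must cope with, not MR physics:
a dark background, a bright rotated-ellipse "limb" with smooth sinusoidal
texture and Gaussian texture noise, one tumor blob whose boundary is
r(θ) = r0·(1 + a·Σ harmonics) (star-convex, hence a single 4-connected
component), a per-image global brightness offset emulating inter-scanner
variation, and three plane labels per synthetic patient sharing one
lesion geometry with small per-slice perturbations. Presets: `easy`
(contrast 0.4, irregularity 0.12, jitter 0.1) and `hard` (contrast 0.15,
irregularity 0.35, jitter 0.3); preset geometry scales with the frame so
a 64 px phantom has proportionally sized anatomy. What passing tests on
phantoms do **not** show: robustness to real MRI artifacts (bias fields,
motion, partial volume, heterogeneous lesion texture), multi-lesion
slices, or distribution shift between hospitals.

## Problem sizes and numerical choices

The test suite trains a 3-stage, ~32 k-parameter ACRNet (widths 16/32/64,
ratio 2) on 200 easy 64×64 phantoms for 10 epochs at lr 1e-4, batch size
1, reaching held-out mean Dice ≈ 0.90–0.94 across seeds — the package's
scaled-down convergence bar, chosen so the full property suite stays a
desk-scale computation. Batch size 1 is deliberate: at a fixed small
learning rate, update count dominates short-horizon convergence, and
per-position layer-norm makes single-sample batches statistically sound.

Other numerics: mean-threshold ties map to foreground (the binarization
formula is 0/0 at the mean); min–max normalization of a constant image
maps to a configurable constant (default 0); hole filling uses
4-connectivity flood fill from the border; the effective region is the
bounding box of *all* white pixels, not just the largest component; boxes
are 0-based and inclusive; images resize bilinearly, masks with
nearest-neighbour so they stay binary; probability ties at the 0.5
threshold count as tumor; network input sizes must be divisible by
2^(stages−1)·2 for the pooling pyramid. Checkpoints are NumPy `.npz`
archives with the architecture configuration embedded as JSON.
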