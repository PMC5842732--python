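# Methods

## Problem and model

The package segments and differentiates two kinds of FLAIR-hyperintense
brain lesions — white-matter hyperintensities (WMH, the imaging hallmark of
cerebral small vessel disease) and stroke lesions — as a per-voxel
three-class classification problem (background/healthy, WMH, stroke) on
axial FLAIR slices. The classifier is **uResNet**, a u-shaped residual
fully-convolutional network:

* **Analysis path** — four resolution scales with channel widths
  (32, 64, 128, 192) by default, two residual elements (ResEle) per scale,
  and 2×2/stride-2 max-pooling between scales (total down-sampling ×8).
  A ResEle computes `ReLU(conv3×3(x)) + shortcut(x)`; the shortcut is the
  identity when input and output widths agree and a trainable 1×1 linear
  projection otherwise. Only 3×3 kernels are used in the residual branches,
  trading large receptive fields for depth and non-linearity at low
  parameter cost.
* **Synthesis path** — three 2×2/stride-2 transposed convolutions whose
  outputs are combined with the matching analysis scale by **summation**
  (not concatenation) skip connections, each junction followed by a ReLU,
  and one final 1×1 convolution into class scores with a per-voxel softmax.

The default build therefore has 12 trainable layers — 8 ResEle, 3
deconvolutions, 1 final convolution — and 1,014,627 trainable parameters.
Because the network is fully convolutional, training on 64×64 patches and
inference on whole slices use the same weights unchanged; inference pads
each slice to in-plane dimensions divisible by 8 with the background floor
(−3) and crops the result back.

Architectural points the defaults fix (the architecture's usual description leaves
them open): all eight ResEle sit in the analysis path, two per scale; the
residual branch carries one 3×3 convolution (a two-convolution variant is a
known alternative and is out of scope here); a ReLU follows each synthesis
summation junction but not the ResEle-internal summation (so a ResEle with
a zeroed branch is an exact identity) and not the final 1×1 convolution;
no batch normalization or dropout anywhere. Weights are seeded
Glorot-uniform; biases start at zero.

This implementation is self-contained numpy: convolutions are GEMMs over
sliding-window design matrices, the transposed convolution is an exact
block reshape (kernel = stride = 2, so blocks do not overlap), and every
layer implements an explicit backward pass. All backward passes are
finite-difference tested against their forward passes, and the convolution
forward is tested against `scipy.signal.correlate2d`.

## Losses

Four objectives share one interface over probabilities and one-hot labels,
all defined as sums over the N voxels of a batch:

* categorical cross-entropy `−Σₙ yₙ log f(Θ,xₙ)`;
* class-weighted cross-entropy with weights ω(yₙ) (default ω = inverse
  class frequency of the training patch set, normalized to mean 1, since
  no canonical values exist);
* online bootstrapped cross-entropy: voxels whose true-class probability
  exceeds τ (default 0.8, a conventional choice) are dropped from the sum;
* soft Dice loss `1 − (1/C) Σ_c 2Σyp / (Σp + Σy + ε)` with ε = 1e-7; a
  class absent from both labels and prediction mass contributes Dice 1
  (loss 0), the natural convention for the otherwise-undefined 0/0 case.

Logs are floored at 1e-12. Analytic gradients with respect to the
probabilities are provided for each loss and chained through the softmax
Jacobian by the trainer; they are finite-difference verified.

## Patch sampling

Lesion voxels are ~0.2–0.5% of a volume, so dense slice training would be
dominated by background. Instead, patch centers are drawn without
replacement from 20% of WMH voxel locations and 80% of stroke voxel
locations (stroke is far rarer), and each center is shifted in-plane by an
integer jitter drawn uniformly from the inclusive range [−P/2, +P/2]
(P = 64), so lesions can appear anywhere in a patch rather than always at
its center. The patch set is drawn once and fixed across epochs; an epoch
is one pass over it.

**Window anchoring.** An even-sized window has no central voxel, so "the
window centered at the shifted location" is ambiguous by half a voxel. The
window is anchored on the half-voxel boundary rounded toward the source
voxel (implementation: the stored center is c+Δ+1 when Δ<0, and the window
spans [c′−P/2, c′+P/2)). With this convention the originating lesion voxel
is contained in the window for every Δ ∈ [−32, 32]², which in turn
guarantees every extracted label patch contains at least one lesion voxel
— a property the trainer asserts rather than handles. Windows crossing the
volume boundary are padded (image: background floor −3; labels: class 0)
so the sampling fractions stay exact. Augmentation applies an independent
left–right flip to each patch (and its labels) with probability 0.5.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), mini-batches of 128 patches,
learning rate 5e-4 with a ×0.1 step decay after epoch 25, ~30 epochs,
seeded shuffling each epoch. Loss gradients are summed over batch voxels
(matching the sum-form objectives); Adam's per-parameter normalization
makes the update scale-invariant to that choice. Model selection evaluates
the final-epoch checkpoint; no early stopping. Whole-volume Dice on
monitoring cases can be recorded at checkpoints and is always computed on
volumes, never on patches. A helper builds two-fold cross-validation
splits stratified by stroke presence.

## Intensity normalization

Each channel is standardized to zero mean and unit standard deviation over
the brain mask ("background" = everything outside the mask), the statistics
being computed **before** clipping; afterwards all voxels below −3 standard
deviations are saturated at −3, giving every image the same background
floor. The brain mask is a robust-maximum threshold (99th percentile ×
threshold fraction, default 0.5) followed by largest-connected-component
selection and per-slice hole filling so CSF-dark ventricles stay inside
the intracranial volume.

## Synthetic phantoms

No suitable public cohort with per-voxel WMH *and* stroke annotations is
bundled, so the package generates phantom cohorts that reproduce the
statistical structure the method depends on, not anatomy or MR physics:

* 128×128×12 grids at 1×1×4 mm (axial-slice-stacked, anisotropic; the
  in-plane extent is kept well above the 64-voxel patch size, as in
  clinical acquisitions, so jittered patch windows rarely cross the
  volume boundary);
* elliptical brain (tissue intensity 1.0) with a dark central CSF-like
  region (0.25) standing in for the ventricles, on a zero background;
* WMH lesions: confluent clusters of 2–4 small ellipsoidal blobs
  (in-plane radii 1.5–3.5 voxels), 70% anchored on the periventricular
  ring, 30% in deep tissue; contrast +3 noise-σ above tissue;
* stroke lesions: larger focal blobs (radii 3.5–6.5 voxels, with
  satellites), deep, non-overlapping with WMH; contrast +4.5 noise-σ —
  brighter and larger than WMH, which is what makes the two classes
  separable by a learned model;
* additive Gaussian noise, σ = 0.1 in tissue units (≈10% of tissue
  signal), with slightly smoothed lesion edges but crisp labels.

These contrasts mirror clinically plausible FLAIR appearance (lesions a
few noise standard deviations above normal white matter, strokes brighter
than WMH). Default cohorts give ≥99% background voxels and several times
more WMH than stroke voxels — the same direction (if not the exact 99.8%
and 14:1) as clinical data. Cohorts place stroke lesions in a configurable
fraction of cases (default 0.35, matching mixed stroke-service cohorts)
and vary the WMH lesion count mildly across cases for volumetric spread.

What the phantoms do **not** emulate: gyral/sulcal anatomy, partial-volume
effects at tissue interfaces, bias fields, multi-protocol intensity
heterogeneity, annotation noise. Passing the end-to-end tests therefore
demonstrates the machinery is correct and the protocol can learn and
differentiate the two lesion classes under controlled conditions — it does
not certify clinical-grade accuracy.

## Desk-scale benchmark

`uresnet.engine.run_benchmark` is the package's end-to-end experiment:
12 training / 6 held-out phantom cases (stroke in half of each), the
standard sampling protocol (~1,100 patches), a reduced-width network
(channel widths 8/16/24/32, ~36k parameters — the full-width protocol is
unchanged but unnecessary for phantom contrast), cross-entropy, and the
protocol's 30 epochs. The mini-batch size is reduced from 128 to 32: with
a small fixed patch set, the number of optimizer steps is what carries
cross-entropy past its early collapse onto the majority class, and smaller
batches give four times the steps at identical compute. Everything derives
from a single seed. The benchmark also runs with jitter disabled
(center-only sampling) to measure the ablation direction.

On clinical data, center shifting prevents the network from overfitting a
lesion-at-center location prior and improves held-out accuracy. The blob
phantoms do not reproduce that benefit: their lesions are homogeneous and
strongly hyperintense, so the intensity cue dominates, there is no
location prior worth unlearning, and center-only windows carry more lesion
voxels per patch (a denser positive signal). The ablation on phantoms
therefore measures a different trade-off than the clinical ablation does —
a known limitation of the phantom model, reported as measured by the
acceptance script rather than asserted away.

## Numerical choices and edge cases

* float32 network arithmetic; float64 losses and statistics.
* Argmax ties at inference break toward the lowest class index.
* Dice of two empty masks is 1 (agreement on absence).
* Bland–Altman uses sample (n−1) standard deviations; RPC = 1.96σ of the
  paired differences; CV = 100σ / mean of the per-case measurement means;
  the bias is tested against zero with a two-sided one-sample t-test.
* The Wilcoxon signed-rank test uses the normal approximation with zeros
  discarded; the effect size is |z|/√(n₁+n₂); all-zero differences give
  p = 1 and effect size 0 by convention.
* Degenerate inputs (constant images, empty masks, zero within-mask
  variance, empty patch sets) raise dedicated errors rather than
  propagating NaNs; a non-finite training loss raises a divergence error
  naming the epoch.

## Known limitations

Pure-numpy training is CPU-bound; the full-width network at clinical
cohort sizes would need hours, which is why the bundled experiment is
desk-scale. Phantom realism is deliberately limited (above). Multi-channel
input (pseudo-T1) is supported and exercised structurally but the bundled
benchmark is single-channel FLAIR, consistent with FLAIR-only input being
sufficient for this task.
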