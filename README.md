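# uresnet

Segmentation **and differentiation** of white-matter hyperintensities (WMH)
and stroke lesions on FLAIR brain MRI with a u-shaped residual
fully-convolutional network.

WMH are the FLAIR-bright signature of cerebral small vessel disease; their
volume is a key quantitative endpoint in epidemiological studies and
trials. Stroke lesions are also FLAIR-bright and often coexist and
coalesce with WMH, so a useful automatic method must not only find
hyperintensities but tell the two pathologies apart. This package is aimed
at image-analysis researchers who want a transparent, dependency-light
reference implementation of that approach: every component — network,
backpropagation, losses, sampler, statistics — is plain numpy/scipy and is
unit-tested against independent oracles, and a synthetic phantom module
provides reproducible end-to-end experiments without clinical data.

## Method

Per-voxel three-class classification (background / WMH / stroke) by
**uResNet**: an analysis path of residual elements
`H_l = ReLU(conv3x3(H_{l-1})) + W_l H_{l-1}` (identity shortcut when
widths match, 1×1 projection `W_l` otherwise) over four scales separated
by 2×2/stride-2 max-pooling, and a synthesis path of 2×2/stride-2
transposed convolutions joined to the matching analysis scale by
**summation** skip connections, closed by a 1×1 convolution and per-voxel
softmax `ρ_c = exp(H_L^c) / Σ_c exp(H_L^c)`. The default build has 12
trainable layers (8 residual elements, 3 deconvolutions, 1 final
convolution) and ~1.0 M parameters.

Training minimizes one of four objectives (categorical, class-weighted, or
online-bootstrapped cross-entropy, or soft multi-class Dice loss) with
Adam on 64×64 in-plane patches sampled at 20% of WMH and 80% of stroke
voxel locations, each center shifted by a uniform in-plane jitter of up to
half the patch size so lesions are not always at the patch center.
Inference is a single fully-convolutional pass over whole slices.
Evaluation covers per-class Dice, lesion volumes as % of intracranial
volume, OLS volume-agreement trends with R², and Bland–Altman bias /
RPC (1.96 σ of paired differences) / CV, plus Wilcoxon signed-rank effect
sizes `|z|/√(n₁+n₂)`.

See `docs/methods.md` for the full model description, conventions, and
limitations.

## Worked example

```python
import numpy as np
from uresnet import (NetworkSpec, build_uresnet, count_parameters,
                     run_benchmark)

net = build_uresnet(NetworkSpec())
print(net.n_residual_elements(), net.n_deconv_layers(), count_parameters(net))
# 8 3 1014627

res = run_benchmark(seed=7, jitter=True)   # ~5 min on one CPU
print(f"held-out Dice  WMH {res['dice_wmh']:.3f}  stroke {res['dice_stroke']:.3f}")
# held-out Dice  WMH 0.741  stroke 0.609
```

`run_benchmark` generates a 12-case training and 6-case held-out phantom
cohort (128×128×12 voxels at 1×1×4 mm; hyperintense WMH-like clusters and
brighter focal stroke-like lesions on a noisy brain ellipse), samples
~1,100 jittered lesion-centred patches, trains a reduced-width uResNet for
30 epochs with cross-entropy, segments the held-out volumes whole, and
reports mean whole-volume Dice per lesion class — i.e. the trained network
both finds the hyperintensities and assigns them to the correct pathology
class. `res["report"]["summary"]` additionally carries the volumetric
agreement statistics (trend, R², Bland–Altman bias/RPC/CV) between
automatic and reference volumes.

The same pipeline is scriptable from the shell:

```sh
uresnet simulate --out-dir cohort --n-cases 10 --seed 1
uresnet sample   --in-dir cohort --out-dir patches --seed 1
uresnet train    --patches patches/patches.npz --out-dir model --seed 1 \
                 --set train.n_epochs=20 --set network.channel_widths=[8,16,24,32]
uresnet predict  --in-dir cohort --checkpoint model/checkpoint.npz --out-dir pred
uresnet evaluate --in-dir cohort --pred-dir pred --out-dir eval
```

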