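# omsas

Binary tumor segmentation of 2-D osteosarcoma MRI slices with **ACRNet**,
a lightweight attention-condenser residual encoder–decoder, trained with
the Tversky loss and fused at test time by compound decision
(dihedral test-time augmentation + per-pixel majority vote).

The package is aimed at researchers who need an accurate, parameter-sparse
segmentation pipeline that runs on modest hardware: the default network has
≈0.58 M trainable parameters, well inside the 6.91 M budget of the
published lightweight design it follows.

## The method

Given a grayscale slice, preprocessing thresholds it at its mean intensity
(p_binary = 1 iff p ≥ μ), fills enclosed holes, crops slice and label mask
to the bounding box of the anatomy silhouette, min–max normalizes
(p_norm = (p − p_min)/(p_max − p_min)), and resizes to the network input.
Training data is expanded to the 8-element dihedral orbit of each sample
(rotations by 0/90/180/270° with and without a horizontal flip), with
Gaussian noise added to a random subset.

ACRNet replaces ordinary convolutions with two parameter-sparse blocks:
*reservation* blocks (1×1 conv + channel layer-norm + ReLU; change channel
count only) and *retracting* blocks (depthwise 3×3 + pointwise 1×1),
stacked into residual units. Each encoder stage ends in an **attention
condenser**: the feature map is condensed (2× max-pool, channel reduction
to c/ratio), embedded with a depthwise-separable conv, expanded back, and
squashed by a sigmoid into gates e ∈ (0,1) that rescale the input
(M′ = M · e) — selective attention that never amplifies. The exposed
channel-attention primitive is the classic squeeze/excite pair

    z_c = (1/hw) Σ_ij M[c,i,j],   e = σ(W_ρ · ReLU(W_σ · z)).

Training minimises the Tversky loss

    L = 1 − Σ R_i Q_i / (Σ R_i Q_i + α Σ R_i (1−Q_i) + β Σ Q_i (1−R_i) + ε)

with α = 0.25, β = 0.75, ε = 1e-8: false negatives (missed tumor) cost
three times as much as false positives, pushing the model toward recall.
At α = β = 0.5 the index reduces exactly to the Dice coefficient.

At inference, the 8 dihedral copies of a slice are each predicted,
re-aligned with the inverse transforms, and fused by per-pixel majority
vote (σ_{j,k} = Σ_i p_{i,j,k}; tumor iff σ ≥ n/2, ties → tumor). The fused
prediction is exactly equivariant under the dihedral group.

Metrics follow the standard confusion-matrix panel (accuracy, precision,
F1, IoU, DSC = 2·IoU/(1+IoU)) plus two recall variants: the conventional
sensitivity TP/(TP+FN) and the negative-class ratio TN/(TN+FN) used in
some published panels (both are always reported).

## Worked example

```python
import numpy as np
from omsas import (ACRNetSegmenter, easy_params, generate_phantom,
                   preprocess_sample, PreprocessConfig)

cfg = PreprocessConfig(target_size=(64, 64))
imgs, masks = [], []
for i in range(250):
    slc, mask, _ = generate_phantom(easy_params(seed=11), i)
    ps, pm = preprocess_sample(slc, mask, cfg)
    imgs.append(ps.pixels); masks.append(pm.pixels)
imgs, masks = np.stack(imgs), np.stack(masks)

est = ACRNetSegmenter(stage_widths=(16, 32, 64), input_size=(64, 64),
                      learning_rate=1e-4, epochs=10, batch_size=1,
                      random_state=11, tta=False)
est.fit(imgs[:200], masks[:200])
print(f"parameters: {est.n_parameters_}")
print(f"final training loss: {est.history_[-1]['loss']:.4f}")
print(f"held-out mean DSC: {est.score(imgs[200:], masks[200:]):.4f}")
```

prints (about 3 minutes on one CPU):

```
parameters: 31889
final training loss: 0.0868
held-out mean DSC: 0.9378
```

i.e. a 32 k-parameter ACRNet trained for 10 epochs at the default learning
rate segments held-out easy phantoms with mean Dice ≈ 0.94.

The same pipeline is scriptable from the shell:

```
omsas synth --patients 20 --slices 6 --preset easy --out data --seed 17
omsas preprocess --manifest data/manifest.csv --out proc --size 64
omsas train --manifest proc/manifest.csv --out run --seed 17
omsas predict --model run/best.npz --image proc/images/P0000_000.png --out pred/m.png
omsas evaluate --pred-dir pred --truth-dir proc/masks --out metrics.csv
```

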