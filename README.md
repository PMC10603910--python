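# secpnet

Multi-class 2D medical-image segmentation with an **SE-connection pyramid
network** and an auto-context cascade, built for tasks that mix very large
and very small structures — the motivating case is organ-at-risk (OAR)
delineation in head-and-neck CT for nasopharyngeal-carcinoma radiotherapy,
where the 13 target organs span roughly 8 cm³ (eyes) to 134 cm³ (temporal
lobe) and small organs are routinely under-segmented by plain U-Nets.

## The model

The primary network is a U-shape encoder–decoder whose copy
skip-connections are replaced by **SEC (SE-connection) modules**. An SEC
fuses two adjacent resolution levels: the deeper map is convolved (3×3,
same padding) to the shallower channel width, bilinearly upsampled 2×
(avoiding transposed-convolution checkerboard artifacts), concatenated with
the encoder feature of its level, convolved back down, and finally gated by
a **squeeze-and-excitation (SE) block** — global average pooling per
channel, a two-layer bottleneck with sigmoid output, channel-wise
rescaling. An SE block at the network bottom starts the chain, and each
SEC's output serves both as the decoder skip input and as the deeper input
to the next-shallower SEC, so global context and multi-size organ
information flow through a pyramid from the bottom of the network upward.

A second, plain U-Net refines the result by **auto-context**: it receives
the original image concatenated channel-wise with the primary network's
per-class softmax probabilities.

Training follows the standard recipe for this model family: per-pixel
multi-class cross-entropy L = −Σᵢ pᵢ log₂ qᵢ, SGD (momentum 0.9, weight
decay 1e-4, batch ≤ 16), and polynomial learning-rate decay
lr = lr₀ (1 − n/N)^0.9 with lr₀ = 0.01 over N = 100 epochs, in four ordered
stages: plain backbone → pyramid network initialised from the backbone →
secondary network with the primary frozen → end-to-end fine-tune at lr₀/10.

Evaluation implements Dice = 2|A∩B|/(|A|+|B|), precision TP/(TP+FP) and
recall TP/(TP+FN) per class, both **Dice per case** (one Dice per patient
volume, averaged) and **Dice global** (all volumes pooled), patient-level
k-fold cross-validation, repeated-run mean ± sample-std aggregation and a
paired two-sided t-test.

Because clinical CT with reference contours cannot ship with a code
package, `secpnet.phantoms` generates seeded synthetic slice populations
that reproduce the structural challenges of the task: a 13-organ size
spectrum scaled from published average organ volumes, left/right organ
pairs, per-slice organ absence, jitter, an intensity ramp and noise.

The network layers run on a compact numpy reverse-mode autodiff core
(`secpnet.autodiff`) with numba-compiled convolution kernels; every
backward rule is verified against central differences in the test suite.

## Worked example

```python
import numpy as np
from secpnet import (NetworkConfig, CascadeNet, TrainPlan, run_staged_training,
                     evaluate_masks, predict_labels)
from secpnet.phantoms import small_five_class_spec, generate_arrays
from secpnet.training import batched_probabilities

train_images, train_masks, _ = generate_arrays(small_five_class_spec(seed=123))
test_images, test_masks, pats = generate_arrays(
    small_five_class_spec(n_patients=2, seed=1123))

cfg = NetworkConfig.small(num_classes=5)   # depth 3, widths 8/16/32/64
plan = TrainPlan(batch_size=4, stage_epochs={
    "backbone": 70, "secp": 50, "secondary": 50, "finetune": 30})
cascade = CascadeNet(cfg, np.random.default_rng(7))
result = run_staged_training(cascade, train_images, train_masks, plan, seed=7)

probs = batched_probabilities(result.cascade.primary, test_images)
pred = predict_labels(probs)
vols = [(pred[pats == p], test_masks[pats == p]) for p in dict.fromkeys(pats)]
report = evaluate_masks(vols, num_classes=5)
print(round(report.mean_dice, 3))
print(report.per_class["dice"].round(3).to_dict())
```

On one CPU this trains in a few minutes and prints

```
0.985
{0: 0.999, 1: 0.999, 2: 0.993, 3: 0.999, 4: 0.95}
```

— the held-out mean foreground Dice (per case) and the per-class Dice:
class 0 is background, classes 1–4 are the large organ, the left/right
pair and the small organ. The smallest organ scores lowest, mirroring the
small-organ difficulty the pyramid design targets.

The same pipeline is available from the shell:

```
secpnet phantom generate --preset small --out data/
secpnet train --config cfg.yaml --data data/manifest.csv --out run/
secpnet evaluate --checkpoint run/finetune --data data/manifest.csv --out metrics
secpnet overlay --image img.png --pred pred.png --truth msk.png \
    --class-index 4 --out overlay.png   # green TP / red FP / blue FN
```

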