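# Methods

## Model

`secpnet` implements three network tiers for multi-class 2D segmentation:

1. **Backbone** — a plain U-Net: `depth` encoder stages of two
   3×3-conv(–BN)–ReLU blocks with 2× max pooling between them, a
   bottleneck stage, and a mirrored decoder (bilinear 2× upsampling, skip
   concatenation, two conv blocks), closed by a 1×1 convolution to the
   class logits. Bilinear interpolation is used instead of transposed
   convolution to avoid checkerboard artifacts.
2. **Primary (pyramid) network** — the same encoder/decoder, but the copy
   skips are replaced by SE-connection (SEC) modules. The bottleneck is
   gated by an SE block to form the deepest pyramid level; for levels
   `depth−1 … 1` an SEC fuses the encoder feature of its level ("level 1")
   with the pyramid output from one level deeper ("level 2") through the
   fixed pipeline conv(3×3, C₂→C₁) → bilinear ×2 → concat → conv(3×3,
   2C₁→C₁) → SE gate. Each SEC output is both the decoder skip of its
   level and the deeper input of the next SEC, giving a bottom-up
   information flow. The shallowest skip remains the plain encoder
   feature, and the decoder's first upsampling consumes the raw
   (ungated) bottleneck. With this wiring the pyramid adds exactly
   `depth−1` SEC modules plus one bottom SE block; a parameter-group audit
   in the test suite pins this count, and a gradient-flow audit checks
   that no branch is dead.
3. **Cascade** — auto-context refinement: a second plain U-Net whose input
   is the original image concatenated with the primary softmax
   probabilities (`in_channels + num_classes` channels).

Classes are mutually exclusive organ labels, so the head is a softmax (not
per-class sigmoids) and prediction is the per-pixel argmax with ties broken
toward the lowest class index.

### Architecture parameters

| parameter | default | notes |
|---|---|---|
| `depth` | 4 | number of 2× downsamplings; inputs must be multiples of 2^depth |
| `stage_channels` | (64, 128, 256, 512, 1024) | canonical U-Net widths; the CPU preset `NetworkConfig.small` uses depth 3 with (8, 16, 32, 64) |
| `se_reduction` | 16 | SE bottleneck ratio (the SE literature's default); hidden width clamped to ≥ 1; the CPU preset uses 4 so that narrow stages keep a useful bottleneck |
| `batch_norm` | on | batch norm after every 3×3 convolution (standard for the family); configurable off. The SEC's two convolutions are deliberately plain conv+bias — the module's published pipeline has exactly five steps, and its nonlinearity comes from the SE gate |
| `in_channels` | 1 | grayscale slices; multi-channel allowed |

The exact depth/width of the published architecture is not specified
beyond "an original U-Net"; the defaults above are the package's choice
and everything is configurable.

## Training recipe

Loss is the per-pixel multi-class cross-entropy with the **base-2
logarithm**, mean over pixels of −log₂(q_true + ε), ε = 1e-12. Base 2 is
kept as the recipe's printed form; a config switch selects the natural
logarithm, which rescales loss and gradient by exactly ln 2 (asserted in
the tests) and cannot change the optimisation direction. The mean (not
sum) over pixels keeps gradient scale independent of batch size.

Optimisation is SGD with momentum 0.9 and weight decay 1e-4, batch size
≤ 16, and the polynomial decay lr = lr₀ (1 − n/N)^0.9 applied before each
epoch, lr₀ = 0.01, N = 100 epochs. The epoch budget applies **per stage**
(the schedule's own account is ambiguous on this; per-stage is the
package's reading), and each stage restarts the decay.

The cascade trains in four ordered stages (each optional, never
reordered):

1. `backbone` — train the plain U-Net; "convergence" is operationalised
   as the epoch budget with an early stop when the loss changes by less
   than 1e-4 (relative) over 10 epochs;
2. `secp` — build the pyramid network, copy every shared encoder/decoder/
   head weight from stage 1 (the SEC/SE additions start fresh), train;
3. `secondary` — freeze the primary (it runs once in eval mode — batch
   statistics frozen — and its probability maps are cached), train the
   secondary U-Net on the auto-context stacks. The secondary warm-starts
   from the stage-1 backbone wherever shapes match; only its first
   convolution, whose input gains the probability channels, starts fresh.
   (The source recipe leaves the secondary's initialisation unspecified;
   warm-starting makes the refinement stage reliable at small step
   budgets, where a from-scratch secondary can lose rare classes.);
4. `finetune` — unfreeze everything and fine-tune end-to-end at lr₀/10
   (the reduction factor is the package's choice; the source recipe fixes
   the primary and then fine-tunes the whole network without naming a
   rate).

No data augmentation is applied anywhere. A fixed seed makes the full
staged run bit-reproducible on CPU (seeded init, seeded shuffling, no
stochastic layers).

## Evaluation

Per class: Dice 2|A∩B|/(|A|+|B|), precision TP/(TP+FP), recall
TP/(TP+FN). Conventions, chosen once and tested:

* empty-vs-empty Dice is defined as 1 (with the confusion counts
  available to flag it) so the identity Dice(A, A) = 1 holds universally;
* zero-denominator precision/recall are NaN and **excluded** from means
  rather than zero-filled, in the same spirit in which background-dominated
  accuracy/specificity are excluded from the protocol entirely;
* background (class 0) is excluded from all reported means;
* "Dice per case" pools all slices of a patient into one volume, computes
  one Dice per volume and averages; "Dice global" pools every volume into
  a single pixel-set pair. Per-case is the default grouping.

Cross-validation splits at the **patient** level (all slices of a patient
share a fold) into k folds whose sizes differ by at most one,
deterministically under a seed. Repeated runs aggregate entrywise as mean
± sample standard deviation (ddof 1). The paired two-sided t-test runs on
per-run score differences; zero-variance differences are degenerate and
flagged (all-zero → p = 1, constant nonzero → the p → 0 limit).

## Phantoms

The generator emulates the structural difficulties of OAR segmentation
without anatomical realism: axis-aligned ellipses on a square canvas with

* a 13-organ default population whose **areas** follow published average
  organ volumes through the areal analogue `volume^(2/3)` (equivalent
  radius ∝ volume^(1/3), 5 px/cm, largest organ ≈ 26 px radius on the
  256 px canvas) — eyes, submandibulars and thyroid end up small exactly
  as in the real task, each under 5 % of foreground pixels;
* left/right organ pairs at mirrored canonical positions;
* per-slice Bernoulli organ absence (presence probabilities 0.4–0.95),
  centre jitter (Gaussian, ~1–1.5 px) and semi-axis jitter (±15 %);
* distinct per-organ mean intensities, a linear top-to-bottom background
  ramp, Gaussian noise, clipping to [0, 1].

Organs draw in descending area order with first-drawn-wins occupancy; the
canonical layouts keep organs disjoint, so no class is engulfed. Spec
validation rejects organs that cannot fit the canvas at their jittered
extent (3σ centre bound). Slice (patient p, slice s) derives its RNG
stream from `SeedSequence(seed, spawn_key=(p, s))`, so datasets regenerate
byte-identically and each slice is independent of generation order.

What the phantoms do **not** model: organ shape variability beyond
ellipses, CT physics (beam hardening, partial volume), inter-organ
texture, anatomically correlated positions, 3D continuity across slices.
Passing the learning test therefore shows that the architecture, recipe
and pipeline can fit and generalise a structured multi-scale task end to
end — not that clinical-grade accuracy is achieved on real CT.

## Numerical core and performance

No deep-learning framework is used: layers run on a small reverse-mode
autodiff engine over float64 numpy arrays (`secpnet.autodiff`), with the
convolution forward/backward contractions compiled by numba
(`secpnet._kernels`; a pure-numpy im2col fallback keeps the package
importable without numba). Every backward rule is checked against central
differences. Bilinear 2× resampling uses the half-pixel-centre
convention as an explicit linear map, so its adjoint is exact. numba's
fastmath may reassociate sums; differences are at rounding level.

`secpnet._runtime.configure_runtime()` (called by the CLI, the test suite
and `run_staged_training`) pins the BLAS pool to one thread — the tensors
here are too small for threading to pay — and raises glibc's
mmap/trim thresholds so the tape's large short-lived buffers are recycled
on the heap instead of being returned to the kernel each step.

## Scaled-down study conditions

CPU-scale experiments (tests and `scripts/acceptance.py`) use the small
preset (depth 3, widths 8/16/32/64, SE reduction 4) on the 5-class 64 px
phantom population: 8 training patients × 4 slices, 2 held-out patients,
batch size 4, stage epochs 70/50/50/30 (≤ 200 total) with the standard
recipe (SGD momentum 0.9, weight decay 1e-4, poly decay from lr₀ = 0.01).
Batch 4 rather than 16 trades per-step parallelism for four times as many
SGD updates per epoch, which at this tiny dataset size is what the
small-organ classes need. Under these conditions the backbone alone
reaches held-out mean foreground Dice ≈ 0.98, and the test suite requires
the pyramid/cascade tiers to reach ≥ 0.80 with the cascade within 0.02 of
the primary.

## Known limitations

* 2D slices only; no 2.5D/3D variants, and no slice-stack context.
* No Hausdorff or surface-distance metrics.
* No DICOM series handling; PNG/NIfTI single-slice I/O only, with
  per-slice min-max intensity normalisation (an optional CT window can be
  applied first; real HU calibration is out of scope).
* The autodiff core implements exactly the operations these networks
  need; it is not a general framework (no broadcasting beyond the cases
  used, no higher-order gradients).
* float64 throughout favours testability over speed; large configurations
  (depth 4, width 64+, 256 px) are practical for inference but slow to
  train without a GPU framework.
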