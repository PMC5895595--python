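# Methods

## The diagnostic pipeline

`acnedx` implements a two-stage, patch-based method for describing
facial acne vulgaris from a photograph. The unit of analysis is a
50×50 RGB patch. A face image is cut by a stride-50 sliding window
into abutting tiles; a **binary classifier** (skin vs non-skin) masks
out hair, eyes and background; a **seven-class classifier** assigns
each remaining skin tile to one of papule (c0), cyst (c1), blackhead
(c2), normal skin (c3), pustule (c4), whitehead (c5) or nodule (c6).
The per-class fractions of those argmax decisions form the *integral
report*, and a symptom set is read off the fractions.

Assumptions inherited from the design: lesions are recognizable at the
50×50 scale (large cysts/nodules that overflow one tile lose context);
tiles are independent (no spatial smoothing of decisions); the face
fills the frame and skin is the dominant surface.

## Architectures

* **Self-constructed CNN** — Conv64, Conv64, maxpool, Conv64, maxpool,
  dropout, flatten, dense-128, dropout, dense-N, softmax. Convolutions
  are 3×3, stride 1, same-padded; pooling is 2×2 with *ceiling*-mode
  output size, giving the spatial trace 50 → 25 → 13 and a flatten
  width of 13·13·64 = 10816. This is the unique conventional geometry
  consistent with that width. The published form has N = 2; the
  seven-class desk-scale model uses the same body with N = 7.
* **Headless VGG16-shaped extractor** — thirteen 3×3 convolutions in
  blocks of widths (64, 128, 256, 512, 512) with five *floor*-mode 2×2
  poolings: 50 → 25 → 12 → 6 → 3 → 1, emitting a 512-d feature vector.
  The two pooling-rounding modes differ deliberately; each is forced
  by its printed output width. ImageNet weights are an optional
  checkpoint asset; the architecture runs (and is tested) with random
  initialization, so no test depends on downloaded weights.
* **Dense head** — flatten, dense-256 (ReLU), dropout, dense-N,
  softmax, attachable to the 512-d features.

Dropout rate is 0.5 everywhere (the classical default; no rate is
published). Conv and hidden dense activations are ReLU.

The layers, backpropagation, and the Adam/SGD optimizers are
implemented in numpy (im2col + BLAS GEMM, NHWC layout, float32).
Correctness is established by finite-difference gradient checks in
`tests/test_nn.py`. Max-pool gradients split equally among tied
maxima; the first layer's input gradient is skipped as it is never
consumed.

## Training protocol

Stratified 80/10/10 train/validation/test split (cumulative rounding,
so 6000 per class gives exactly 4800/600/600). Optimization follows
the published setting: Adam with learning rate 0.001, β₁ = 0.9,
β₂ = 0.999, batch size 64, training seed 1337; after all epochs the
snapshot with the highest validation accuracy is retained (earliest
epoch on ties — the published criterion names validation performance
but no tie rule). Losses are the binary and categorical cross
entropies with natural logarithms; probabilities are clipped at 1e-7
before logs. The training loop optimizes the numerically equivalent
softmax cross-entropy on logits.

Preprocessing: the binary task rescales pixels to [0, 1] by dividing
by 255; the seven-class task standardizes globally by one scalar mean
and standard deviation fitted on the training split (the published
constants, 183.643 and 38.210, are the authors' train-set statistics;
for synthetic data the statistics are re-fitted the same way).

Fine-tuning is plain SGD (momentum 0, unpublished) with learning rate
in the published [0.001, 0.01] interval, default 0.001, updating only
the last *n* convolutional layers of the extractor plus the head.

Determinism contract: identical data, configuration, and seeds give
identical histories *within one installation*; bit-level agreement
across BLAS builds is not promised.

## Augmentation

The four elementary transforms are 3×3 homogeneous matrices on
1-based (row, col) coordinates with the image center at
((h+1)/2, (w+1)/2). Rotation follows the printed closed form exactly.
The printed shear and zoom offsets are not center-preserving as
written (the shear offsets even reference a zoom symbol); they are
implemented in the corrected, center-preserving form, consistent with
the rotation matrix's construction. Random augmentation samples each
parameter uniformly (defaults: rotation ±40°, shift ±5 px, shear
±0.2 rad, zoom 0.8–1.2, horizontal flip probability 0.5 — the
transform family is published, the ranges are not), composes
rotation·shift·shear·zoom, and resamples by inverse mapping with
bilinear interpolation and edge fill. `augment_to_target` enlarges
each class to a fixed target count, keeping originals unchanged
(the fixed-enlargement reading of the augmentation protocol).

## Evaluation

ROC curves are built over the distinct scores (descending, sentinel
above the maximum); AUC is the trapezoidal area, which equals the
tie-corrected Mann–Whitney statistic — the test suite checks this
equality to 1e-12 against an exhaustive pair-counting oracle. Youden's
J = max(TPR − FPR); ties on J resolve to the *smallest* threshold
(favoring sensitivity; the published per-class thresholds imply no
rule). Items scoring exactly the threshold are predicted positive.
Multiclass quality is read from the row-normalized confusion matrix,
whose diagonal is per-class recall; rows with no actual items are
flagged rather than divided.

## The symptom rule

The published worked examples pair six proportion vectors with six
symptom sets. The rule implemented — ignore c3, keep classes with
proportion ≥ 0.10, cap at the 3 largest, resolve boundary ties toward
the lower class index — is the unique simple rule consistent with all
six rows: one row includes a 0.11 (threshold ≤ 0.11), another excludes
a 0.07 (threshold > 0.07), and a third drops a qualifying 0.11 only
because three larger classes exist (forcing the cap). Both threshold
and cap are configurable. Whether the published vectors are
argmax-fractions or mean softmax probabilities is unstated;
argmax-fraction is implemented because the aggregation is described as
statistics over per-tile classification results.

## Synthetic fixtures

The clinical dataset behind the original study is private, so the
package generates its own labeled data. Recipes (see
`acnedx.synthetic`): normal skin is a beige base (200, 160, 140) with
per-pixel Gaussian noise (sd 10, truncated at 4 sd); lesion classes
overlay discs whose color and size encode the class (small red disc =
papule; large dark-red disc = cyst; 1–3 dark dots = blackhead; red
disc with white center = pustule; small white dot = whitehead; large
low-contrast dark-red region covering >40% of the patch = nodule);
non-skin is either dark striped hair texture (all channels < 80) or a
saturated cool-hued uniform background (green through blue, the
typical clinical backdrop), drawn 50/50. The binary task's skin class
is a uniform mixture over the seven skin classes — skin examples
include diseased skin, matching the study's data composition; without
this, lesion tiles would be masked as non-skin before the seven-class
stage ever saw them. Faces are 10×10 grids of
such tiles with per-tile seeds `seed + row·cols + col`, so every tile
is reproducible in isolation.

These fixtures are separable by low-order color/shape statistics *by
construction* — a linear classifier on channel means already separates
skin from non-skin at ≥95%. Passing desk-scale tests therefore shows
that the pipeline's plumbing, training loop, threshold selection and
aggregation are correct; it says nothing about accuracy on clinical
photographs, which vary in lighting, pose, skin tone and lesion
appearance in ways the recipes do not model.

## Desk-scale study conditions

Chosen once for the synthetic re-run and used by both the test suite
and `scripts/acceptance.py`: binary task, 200 patches/class, 20
epochs; seven-class task, 150 patches/class, 12 epochs; the protocol
seed stays 1337. The composite face holds 40 non-skin, 36 normal, 12
blackhead and 12 pustule tiles (skin fractions 0.6/0.2/0.2). At these
sizes the full suite and the acceptance script each run in minutes on
one CPU.

## Known limitations

* Random-weight VGG16 features are exercised for shape/contract tests
  only; transfer-learning quality claims require the pre-trained
  checkpoint, which is not bundled.
* Exact pixel-level reproduction of the authors' augmented images is
  not possible: the printed shear/zoom matrices contain slips and the
  sampling ranges are unpublished.
* The printed per-class Youden rows are mutually inconsistent for
  three of four rows (e.g. 0.900 + 0.923 − 1 ≠ 0.857); the
  implementation follows the definitions, not the printed rows.
* Non-overlapping stride-50 tiling only; overlapping windows and
  lesion counting within a tile are out of scope.
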