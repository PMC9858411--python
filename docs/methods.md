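# Methods

## Problem and model

Dental caries on panoramic radiographs falls into three clinically distinct
classes: occlusal (Type I, on the biting surface), proximal (Type II, at the
contact surface between adjacent teeth) and cervical (Type III, at the tooth
neck, often superimposed on pulp radiolucency). The classes are visually
similar and spatially close, so a single softmax segmentation map tends to
collapse them. This package implements a multi-head encoder–decoder network
that gives each class its own sigmoid output and treats the problem as three
coupled binary segmentations.

**Encoder.** One of five standard convolutional feature extractors
(MobileNetV2, Inception-V3, EfficientNet-B0, ResNet50, VGG16), built from
scratch on the package's NumPy autodiff engine and tapped at five scales:
Sc0 (1/32 of the input, the deepest feature map) and four skip connections
Sc1..Sc4 at 1/16, 1/8, 1/4 and 1/2. Tap layers follow the conventional
per-backbone skip points (e.g. `block_13_expand_relu` for MobileNetV2,
`stage4_unit1_relu1` for ResNet50). Two adaptations were required:

* Inception-V3 is built with TF-'SAME' padding throughout instead of the
  stock valid-padded stem, so every stride-2 stage halves the input exactly
  and the taps land on clean power-of-two scales. Channel structure
  (mixed0..mixed10) is unchanged.
* ResNet50 uses pre-activation bottleneck units, under which
  `stage{k}_unit1_relu1` naturally sits at the incoming stage scale.

**Decoder (multi-level feature concatenation).** Starting from a pointwise
(1x1) projection of Sc0 to 256 channels, the stream is repeatedly doubled by
a 4x4/stride-2 transposed convolution and merged with the next skip feature,
which is first projected to 256 channels by a pointwise convolution. The
merge is channel concatenation by default (`merge_op="sum"` selects
element-wise addition instead — both readings of the source design exist in
the field; concatenation is the documented layer table). Each of the four
merge levels also emits a branch — 3x3 convolution to 128 channels, batch
norm, ReLU — upsampled (nearest-neighbour) by 8/4/2/1 so all four branches
land at the 1/2-input scale, where they are concatenated into a 512-channel
fused map.

**Output block (multi-predicted output).** The fused map splits into three
fully independent paths: 3x3 ConvBNReLU to 32 channels, then a 1x1
convolution with a single sigmoid unit. Nothing is shared after the split
(verified bit-exactly in tests), so one lesion class cannot suppress
another's output — the property that motivates the architecture. A final
bilinear 2x upsampling brings each probability map to input resolution
(`output_upsample="native"` evaluates at 1/2 scale instead; whether the
original model upsampled or evaluated at half resolution is not
determinable, so both are supported and every report records its evaluation
resolution).

One published layer-table ambiguity is decided in config: the table leaves
the level-4 branch (L21) unconsumed and feeds the head from the raw level-4
merge (L19). The default here uses L21 — symmetric with the other three
branches and leaving no dead layer — with `mpo_level4_source="L19"` to
follow the table literally. The unused transposed convolution L20 exists in
the graph and is executed only in trace mode so shape tests can cover the
complete ledger L1–L28.

## Loss and metrics

Each head k is trained with binary cross-entropy against its class mask,

    L_k = mean_{pixels, samples} -[ y log P + (1-y) log(1-P) ],
    L   = (L_1 + L_2 + L_3) / 3,

with probabilities clipped to [1e-7, 1-1e-7] before the logarithms. The
per-pixel mean (rather than a raw sum) makes the loss magnitude independent
of resolution and batch size; `reduction="sum"` gives the unnormalised form.

Evaluation binarises each probability map at a threshold (default 0.5, the
standard sigmoid cut — the source never states one) and pools pixel
confusion counts per type over the whole test set (micro aggregation;
`aggregate="macro"` averages per-image metrics instead — the source is
silent on this too). Precision, recall, F1 and IoU are reported as
percentages; degenerate denominators yield 0 with a warning, and an empty
prediction∪truth union yields IoU 100 (two empty masks agree perfectly).
The cross-type summary is an F1 average weighted by per-type lesion-label
counts; because published summary rows of this kind are generally computed
from unpublished test-subset counts, the weights used are always reported
beside the average and never assumed.

## Synthetic fixtures

The generator renders a deliberate caricature of a panoramic radiograph: a
dark noisy background, one bright arch of ellipsoidal teeth, and dark
elliptical lesions planted according to class-specific spatial priors —
Type I on tooth tops, Type II at contact points between adjacent teeth,
Type III at tooth necks. Per-image lesion counts are Poisson with default
means 746/504, 1627/504 and 378/504 per type, matching the class imbalance
of the reference clinical dataset (746/1627/378 labels over 504 images).
Geometry scales with the canvas, so the nominal 900x1700 world and the
small training canvases used on CPU share one code path. Every lesion is
stored as a polygon whose rasterisation is exactly the rendered region, so
COCO round trips are lossless, and everything is deterministic per
(seed, index).

What a green test on fixtures establishes: the three-head mechanism,
preprocessing, loss and metrics behave correctly on separable classes with
the right frequency structure. What it does not establish: performance on
real radiographs — the fixtures have no superimposition, no restorations,
no pulp radiolucency, and far cleaner class geometry than clinical data.

## Training

Defaults follow the reference recipe: Adam (lr 0.001, Keras-style eps
1e-7), batch size 8, 100 epochs, joint optimisation of the mean three-head
BCE, no augmentation, no LR schedule, no early stopping, final-epoch
checkpoint. Weight init is He-uniform with explicit seeds everywhere
(backbone and decoder draw from one seeded generator), so identical configs
build bit-identical networks and train → evaluate is reproducible run to
run. ImageNet-pretrained encoders are not available offline; construction
is seeded-random and `pretrained=True` fails with a clear message.

## Numerical and engineering choices

* Pure-NumPy engine (`dcdnet.nn`): im2col + BLAS sgemm convolutions,
  transposed convolution as one gemm + column scatter, reverse-mode tape
  autodiff. Backward passes re-materialise column matrices instead of
  caching them; measured on one CPU core this is as fast as caching and
  keeps the memory profile flat (~2 GB during training at 32x64/batch 8).
* All padding follows the TF 'SAME' convention (extra pixel bottom/right),
  so stride-2 layers halve even inputs exactly — the contract the decoder's
  shape ledger is tested against.
* Batch norm: batch statistics in training, running statistics at
  inference, epsilon 1e-3. The running-statistic momentum is 0.9, not
  Keras' 0.99: in the short (≤200-step) CPU-scale runs this package
  targets, 0.99 leaves most of the (0,1) initialisation in the running
  estimates and systematically distorts eval-mode predictions; 0.9
  converges the estimates within ~50 steps. At full-scale step counts the
  two are equivalent.
* Average pooling includes zero padding in its mean (it is implemented as a
  fixed uniform depthwise convolution); this differs from exclude-padding
  implementations only on border pixels.
* Nearest-neighbour upsampling in decoder branches; bilinear (half-pixel
  convention) only for the final 2x output resize. Mask resizing is
  nearest-neighbour followed by re-binarisation so masks stay strictly
  binary; image resizing is bilinear without anti-aliasing (deterministic).
* Centre crop uses floor offsets for odd remainders.
* The train/test split is a seeded uniform shuffle taking round(0.75·n)
  ids for training; patient-level grouping of the original data cannot be
  reconstructed, so no grouping is attempted.

## The desk-scale memorisation experiment

The acceptance-level training check is a seeded overfit: 8 synthetic
fixtures, batch 8, lr 0.001, at most 200 Adam steps, MobileNetV2 encoder,
with training-set F1 checked every 20 steps and early stop at F1 ≥ 80 for
Types I and II. It runs at 32x64 input — full-resolution (256x512) training
is hours of CPU time in NumPy, and input resolution is the only scaled-down
knob; optimizer, batch size, learning rate and architecture widths are the
reference values. With the shipped seed the criterion is met after 40 steps
(F1 ≈ 91.5 / 91.8 / 82.8 for Types I/II/III on the training set). On
held-out fixtures after a short run (the acceptance script), Type III
routinely scores near 0 while Types I and II learn — the rare-small-class
failure mode the multi-head design is meant to expose rather than hide.

## Known limitations

* No DICOM input, no contrast normalisation or augmentation.
* No pretrained encoder weights (offline environment); transfer learning is
  out of reach, so absolute segmentation quality on real data is not
  comparable to GPU-scale transfer-learned results.
* EfficientNet decoder channel table ships for the B0 variant only.
* Single-output ablation (`heads=1`) produces a class-agnostic union map;
  per-type attribution is undefined by construction (it is replicated
  across the three output slots for API uniformity).
* Latency measurements (`benchmark_fps`) are hardware-dependent and
  informational only.
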