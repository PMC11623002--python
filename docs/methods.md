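# Methods

## Problem setting

`splitfed` simulates a consortium of hospitals that want to train one
3-class classifier for grayscale brain scans without pooling their images.
Two obstacles are modeled explicitly:

1. **Severe class imbalance.** The reference class counts are 896 (Mild
   Dementia), 64 (Moderate Dementia) and 3,200 (Non Dementia); the
   imbalance ratio of a class is its count divided by the majority count
   (0.28 and 0.02 here). A quarter-subsample that preserves these ratios
   (800/224/16) is the package's standard working set.
2. **Data privacy.** Raw images never leave a client. Only cut-layer
   activations ("smashed data"), the shared labels, the loss gradient at
   the cut, and client-side *weights* are exchanged.

## Split federated learning

The classifier is a ResNet18-style network cut after the stem:

* **Client front** — 7x7/2 conv, batch norm, ReLU, 3x3/2 max pool; then a
  3x3 conv + batch norm + ReLU refinement and dropout (p = 0.5). Output:
  64 channels at 1/4 the input resolution (56x56 for 224x224 inputs).
  The ReLU after the refinement batch norm is a choice; the alternative
  (no ReLU before the cut) is a one-line change.
* **Server back** — one conv-BN-ReLU-conv-BN refinement at 64 channels,
  then three basic residual blocks (128/256/512 channels, stride-2 first
  conv, 1x1 projection shortcuts), global average pooling, and a linear
  head to 3 classes.

One **global round**: a fraction `frac` (default 1.0) of the `n_clients`
(default 2) is selected; each selected client streams its shard in
batches through client-forward → server-step → client-backward against a
*single shared server half* that is updated sequentially across clients;
afterwards the participating clients' front weights (including batch-norm
running statistics) are federated-averaged and installed as the global
client model, which is also the evaluation model. Optimizers are Adam,
learning rate 1e-4, batch 64, categorical cross-entropy — the reference
training configuration.

Design choices worth knowing:

* Client optimizer state is reset whenever weights averaged over more
  than one participant are installed (stale Adam moments after a weight
  replacement are ill-defined). With a single participant the install is
  an identity and the state is kept — this is what makes one-client SFL
  collapse *exactly* to centralized training of the composed model, the
  strongest end-to-end correctness property the tests assert.
* The FL baseline trains full composed copies locally and averages
  everything; the SL baseline relays the client front from client to
  client against the shared server, with no averaging.
* Client processing order is ascending id; shard batching, client
  selection and all initializations derive from one run seed, so a run is
  bit-reproducible (the history CSV is byte-identical across repeats).
* Initialization is He (Kaiming) for the classifier halves — the standard
  choice for ReLU residual networks, and materially faster to leave the
  majority-predictor plateau on imbalanced data than Glorot — and Glorot
  for the GAN, except label embeddings (see below).

**Split-equivalence oracle.** Because the server treats the smashed batch
as a leaf tensor and returns `dLoss/d(cut)`, the chained client backward
must reproduce the composed model's gradient for every parameter. The
test suite checks this at relative error ≤ 1e-5 in float32 (it is in fact
bit-exact here, since both paths execute the same kernels in the same
order), in both batch-norm modes.

## Conditional GAN for minority synthesis

The generator embeds the class label (dim 50), projects it to a
one-channel (s/4, s/4) map, projects the 100-dim latent (leaky-ReLU) to a
second map, concatenates, upsamples 2x, applies a 4x4 stride-2 transposed
convolution (64 filters) and a final 4x4 stride-1 transposed convolution
to one tanh channel. The discriminator projects the embedded label to a
full-resolution channel, concatenates it with the image, applies five 3x3
stride-2 convolutions (128 filters, leaky-ReLU 0.2), dropout 0.4 and a
sigmoid unit. At the default 256x256 configuration the per-layer
trainable parameter counts (413,696 / 208,896 / 2,112 / 1,025 generator;
3,342,336 / 2,432 / 4x147,584 / 8,193 discriminator) are asserted by the
conformance tests; kernel sizes (3x3 / 4x4) are fixed by those counts.
The label-embedding row is vocabulary-dependent and parameterized by
`n_classes`, so it is excluded from conformance.

The value function is E[log D(x)] + E[log(1 − D(G(z)))]; the trainer uses
the non-saturating generator loss −E[log D(G(z))] (the saturating form is
available). Discriminator: separate real and fake half-batches; generator:
one step through the frozen discriminator per batch. Adam 2e-4 with
beta1 = 0.5. Three design points matter on imbalanced data and are on by
default: real half-batches are drawn with equal per-class probability
(otherwise a 13-image class gets almost no discriminator feedback); fake
labels are drawn only from classes present in the GAN's training set
(otherwise capacity is spent on classes with no real examples); and label
embeddings are initialized at unit scale rather than the conventional
0.05 — when the discriminator can win without looking at labels, a label
pathway that starts 40x weaker than the image pathway is simply never
picked up, and the generator then produces class-agnostic images. With
unit-scale embeddings the synthesized classes separate cleanly (measured
by the phantom cavity-area statistic).

**Augmentation.** `augment_minority` raises each client shard's class
counts to `ceil(target_ratio x majority)` (default target 0.5 — full
balancing is deliberately avoided: too much synthetic data risks
overfitting to the generator's idiosyncrasies) using GAN samples passed
through CLAHE and resized to the shard's image size. Test sets are never
augmented. The GAN is trained per deployment choice either on pooled
training minorities (the default in the experiment driver) or per client.

## CLAHE

`apply_clahe` is tile-based histogram equalization with an OpenCV-style
clip limit: per-tile 256-bin histograms are clipped at
`clip_limit x area/256` (default clip 2.0, 8x8 tiles), the excess is
redistributed uniformly, and per-pixel values are blended bilinearly
between the four neighbouring tile mappings. The lookup uses the midpoint
(cdf − hist/2) rule so an already-equalized tile is a fixed point of the
transform. Enhancement runs before the resize to the classifier input
(224 in the full-size pipeline), in that order.

## Phantom data

Real scans are replaced by deterministic "phantoms": a bright elliptical
rim around textured tissue with a dark central cavity whose area grows
with class index (`severity_scale`, default 1.0; cavity radius
0.18·sqrt(1 + class·severity) of the half-image) — a crude geometric
stand-in for ventricular enlargement that survives CLAHE and resizing.
Pixel noise is Gaussian (sd 0.05), with small jitters of skull axes
(±2%), cavity radius (±4%) and center (±0.03). At these defaults a
leave-one-out nearest-centroid probe on 16x16 thumbnails scores ≥ 0.9,
so the classes carry real signal; at high noise the probe collapses to
chance. Everything is a pure function of the `PhantomSpec` (size, counts,
noise, severity, seed).

What phantoms do *not* model: acquisition physics, bias fields, anatomy
beyond one cavity, inter-subject correlation, or any resemblance to real
dementia staging. Passing tests therefore demonstrate that the protocol,
the GAN machinery and the augmentation logic work end to end on a
learnable imbalanced task — not that the pipeline reaches any particular
accuracy on clinical data.

## Numerical engine

No deep-learning framework is used: `splitfed.nn` is a small define-by-run
reverse-mode autodiff on numpy (float32 by default; float64 for the
finite-difference gradient checks that validate every layer). Convolution
is im2col + BLAS matmul; transposed convolution is convolution of the
zero-dilated input with the flipped kernel, cropped to Keras-'same'
output sizes (which the architecture tables assume); batch-norm backward
uses the standard closed form; FedAvg accumulates in float64 so averaging
identical weight sets is exact. Adam with zero gradient and fresh state
is a provable no-op, which the zero-gradient-packet test relies on.

## Problem sizes in the test and acceptance runs

Heavy end-to-end runs use sizes chosen for a single CPU:

* pipeline data: 64x64 phantoms, 800/224/16 per class (the preserved
  0.28/0.02 ratios), 80/20 stratified split, 2 IID client shards;
* classifier: width multiplier 0.5 (channels 32/64/128/256) — the
  full-width network is exercised by the conformance, shape and
  equivalence tests;
* SFL: 5 epochs, batch 64, Adam 1e-4;
* GAN: 32x32, base_channels 32, 200 epochs, batch 32, trained on the
  training-pool minority classes; its samples are enhanced and resized to
  64x64 before joining a shard (same synthesize-then-enhance order as the
  full-size pipeline, which synthesizes at 256 and resizes to 224);
* the augmentation comparison repeats sharding + training over three
  seeds and compares the median *minority-class recall*, defined as the
  unweighted mean recall over the classes below the majority count.

The metric definition deserves a note. The reference experiments report a
single recall for the 3-class task without stating its averaging basis,
and call both low-count classes "minority class 1" and "minority class 2";
a mean over the minority classes is the faithful desk-scale reading. The
recall of the single rarest class is reported alongside but not asserted:
at this problem size it rests on three test images and thirteen real
GAN-training examples, making it a four-level statistic dominated by the
synthetic-to-real fidelity of a generator fitted to thirteen images. A
control with an oracle generator (fresh phantoms from the true
distribution standing in for GAN output) drives that rarest-class recall
to 1.0 under the identical protocol, so the augmentation mechanism itself
is sound; a conditional GAN of this size, however, cannot be relied on to
calibrate the rarest class's geometry from so few examples, whereas the
0.28-ratio class (179 training images) improves consistently.

Unit tests use 32x32 phantoms and width 0.25 throughout.

## Known limitations

* In-process simulation only: clients and servers are function calls, not
  sockets; no stragglers, compression, encryption or secure aggregation.
* The published precision/recall of the reference experiments are single
  numbers for a 3-class task with an unstated averaging convention; this
  package reports per-class and macro-averaged values and makes no
  attempt to reproduce a "precision = 1.00" style figure.
* Non-IID sharding is a config hook, not implemented behavior.
* The engine is CPU-only and unoptimized beyond im2col/BLAS; it is meant
  for correctness and desk-scale experiments, not production training.
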