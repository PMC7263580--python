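# Methods

## Problem setting

`braincbir` implements a content-based image retrieval (CBIR) system for
single-organ medical imaging, where the retrieval unit is a 2-D grayscale
slice and the semantic label is a disease category.  The characteristic
difficulty of this setting is that different diseases of the same organ
share almost all of their anatomy: a query and a counter-example may differ
only in a small lesion occupying a few percent of the image.  Network
architectures built for natural scenes aggregate features into a single
global summary and tend to lose exactly that local evidence, so the
descriptor here is built to carry global and local information at once.

The system has three workflows sharing one convolutional network:

1. **Training** — the network is trained as a supervised disease classifier
   (softmax cross-entropy, backpropagation) on labelled images.  The
   classification task is a proxy: features that separate disease classes
   are also the features that make same-disease images close in descriptor
   space.
2. **Database construction** — every archive image is passed through the
   trained network; its penultimate-layer activation (the *raw descriptor*,
   4096-dim by default) is compressed by PCA (1024-dim by default) and
   stored, with its id and label, in an HDF5 feature database that also
   carries the fitted PCA transform and metadata.
3. **Retrieval / evaluation** — a query image is embedded the same way and
   compared to the stored vectors by Euclidean distance
   S(v, v0) = ‖v − v0‖₂; records are returned in ascending distance order.
   Quality is summarised by precision P = a/(a+b), recall R = a/(a+c), the
   per-query average precision AP (mean of the precision values at each
   rank where a relevant item appears, normalised by the total number of
   relevant items) and their mean over the query set (MAP).

## Network

The building block is a residual module: the main branch stacks three
same-padded convolutions (3x3 by default), so the receptive field grows
3 -> 5 -> 7 pixels across the stack; the three intermediate feature maps —
local to increasingly contextual — are concatenated, reduced back to the
block width by a 1x1 convolution, and added to a skip connection (identity
when input and output widths agree, a 1x1 projection otherwise).  Each
main-branch convolution is followed by group normalisation (8 groups,
per-channel affine); the skip path carries none, so zeroing the main branch
reduces the block exactly to its (projected) input.  Group statistics were
chosen over batch statistics because they are independent of batch
composition, which keeps inference deterministic and identical between
training and evaluation mode.

The full network applies one block at each of three scales — full
resolution, 1/2 and 1/4, connected by 2x2 max pooling — and summarises each
scale's feature map by a **global maximum** per channel.  The maximum,
rather than a spatial mean, is what preserves small-lesion evidence: a
filter that fires strongly on a 3-pixel lesion contributes its full
response to the descriptor regardless of the lesion's area, whereas an
average would dilute it by the lesion-to-image area ratio.  The three
pooled vectors are concatenated, standardised per sample (zero mean, unit
variance across the vector; this removes global activation shifts such as
those induced by an intensity-inverted modality and conditions the head's
optimisation), and passed through a fully connected layer with ReLU whose
output is the raw descriptor; a final linear layer produces the class
logits.  Softmax is computed shift-invariantly (max subtracted).

Because global pooling precedes the fully connected layers, the descriptor
length is independent of the input resolution.

Two deliberate initialisation choices matter for retrieval quality:

* The descriptor head's weights are scaled down by 0.05 after He
  initialisation.  The descriptor is then dominated by structure *built by
  training* (class-discriminative directions) rather than by the random
  projection of the initial weights; without this, Euclidean distances
  between descriptors are governed by class-irrelevant variance (by the
  Johnson–Lindenstrauss argument a random 4096-dim projection simply
  reproduces the geometry of its input, modality differences included).
* Convolution weights use He initialisation; all biases start at zero.

Implementation: the network, including backpropagation, is written directly
on NumPy (im2col convolutions lowered to BLAS matrix products, float32
throughout).  Gradients of every layer and of the composed network are
verified against central finite differences in the test suite.

## Training

Adam (lr 1e-3, betas 0.9/0.999, batch 16, 20 epochs by default) with two
additions:

* **Label smoothing 0.1.**  Besides regularising the classifier, smoothing
  is known to pull same-class penultimate features into tight clusters,
  which is precisely what descriptor retrieval needs; without it the loss
  can separate classes in logit space while leaving descriptors dispersed.
* **Decoupled weight decay 1e-3** on weight matrices (not biases): feature
  directions the classification loss never uses receive no gradient, and
  the decay term shrinks them rather than letting them distort distances.

The train/validation split is stratified by label and seeded; every class
keeps at least one training image, and at least one validation image when
it has two or more.  A fixed seed reproduces the loss trajectory exactly on
a fixed platform.  The initial loss is ~ln(K) for K balanced classes, the
analytic value under uniform predicted probabilities; this is asserted in
the tests.

The channel plan is (24, 48, 96) across the three scales.  A narrower plan
was tried first and trained inconsistently within the 20-epoch budget
(several seeds remained near the uniform-prediction plateau); the wider
plan converges reliably at roughly double the cost, which is the better
trade at desk scale.

## PCA compression

PCA is fitted by SVD of the mean-centred descriptor matrix; the components
are the top-k right singular vectors, identical (up to sign) to the leading
eigenvectors of the sample covariance, and the tests verify this against an
independent eigendecomposition and against scikit-learn.  Sign ambiguity is
resolved by making each component's largest-magnitude entry positive, so a
refit is byte-reproducible.  If k exceeds the numerical rank of the data
(routine at desk scale: 150 images cannot support 1024 components), k is
clipped to the rank with a warning.  Because the projection is orthonormal,
distances between reduced vectors never exceed the distances between the
centred originals, and with k at the full data rank the embedding preserves
them exactly.  PCA is fitted on the same trained-network descriptors that
populate the database and is stored inside the database file, so queries
are reduced with the identical transform.  A `--no-pca` path stores the raw
4096-dim descriptors unreduced.

## Synthetic phantoms

No clinical data ships with the package; the generator produces the study
conditions instead.  Every phantom shares one deterministic background —
an elliptical "brain" with a soft tissue gradient, a bright skull rim and
two dark ventricle-like lobes — so inter-class image correlation exceeds
0.9 at zero noise, emulating "different diseases, same anatomy".  Disease
classes differ only in a small lesion (under 10% of the brain area, soft
edged, truncated exactly at a recorded boolean mask so tests can compare
backgrounds bit for bit):

* class 0 — a bright compact blob at a random intra-cranial position;
* class 1 — a smaller blob confined to the lower midline;
* class 2 — a larger region with irregular sinusoidal texture.

Classes beyond three reuse these archetypes with a class-specific angular
offset.  Two intensity regimes stand in for CT-vs-MR appearance: `m0` is
the phantom as rendered, `m1` applies a global inversion followed by a 1.6
gamma shift.  Additive Gaussian noise is available; the default study runs
noise free.  All randomness derives from one seed through `SeedSequence`,
so a spec reproduces its image set bit for bit.

What the phantoms do **not** emulate: 3-D structure, slice-angle variation,
scanner artefacts, patient-level correlation between images, anatomical
variability of the background across subjects.  Passing the phantom study
therefore demonstrates that the pipeline's machinery — feature learning,
compression, ranking, evaluation — behaves correctly on data with the
assumed statistical structure; it does not certify clinical performance.

## Standard study and problem sizes

The default end-to-end configuration is 3 classes x 50 images at 48x48
pixels, modality mix 0.5, noise 0, 20 training epochs, PCA to k = 1024
(clipped to the data rank, 149), leave-query-out evaluation with
precision/recall reported at top-10 and AP over the full ranking.  Each
stored image queries the database with its own record excluded, since a
guaranteed self-match at distance zero would inflate every metric.
Relevance means sharing the query's disease label.  These sizes keep a full
run around 1.5 minutes on one CPU core while leaving the task non-trivial
(the two modality regimes must be bridged by the learned features).  Across
seeds 1–5 the study yields MAP between 0.84 and 0.98.

## Numerical and design notes

* Ranking ties are broken by image id, so orderings are deterministic.
* `top_k` larger than the database returns the full ranking with a warning;
  an empty database is an error.
* AP is non-interpolated (precision at relevant ranks).  Relevant items
  never retrieved contribute zero.
* P and R are exact rationals of the counts a, b, c; zero denominators
  raise rather than returning a sentinel.
* Precision/recall for summary tables are computed at a fixed top-10
  cutoff (configurable).
* Descriptors and database vectors are float32; distance computations are
  float64.
* Checkpoints are NumPy `.npz` archives with a JSON config and a format
  version; databases are HDF5 with a schema version.
* The image-level (not patient-level) evaluation split mirrors the absence
  of patient structure in the phantoms.

## Known limitations

* The NumPy implementation targets desk-scale problems; there is no GPU
  path and no approximate nearest-neighbour index, so both training and
  query cost grow linearly with data size.
* Retrieval quality depends on classifier convergence; with very few
  optimizer steps the descriptors revert toward a random projection of the
  pooled features.
* PCA at desk scale always operates rank-clipped; the 1024-dim target is
  only reached with >= 1024 training descriptors.
* Phantom realism limits, as above.
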