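# Methods

## Pipeline overview

`mbhis` classifies histopathology images through a fixed cascade: CNN
global-average-pooling (GAP) embeddings → single-level discrete-Meyer
wavelet detail coefficients → concatenation across backbones → DCT or PCA
reduction → classical classifiers, evaluated by repeated stratified
cross-validation. This note records the conventions, defaults and design
choices behind each stage, and what the synthetic test bed does and does not
establish.

## Preprocessing

Images are decoded as RGB uint8 and resized with bilinear interpolation and
anti-aliasing to 224×224×3 (any multiple of 32 px per side is accepted by
the backbones; the spatial size never affects embedding width). For the
binary level, all normal images are kept and 50 tumor images are drawn
without replacement from the pooled subtypes. The draw is stratified
proportionally across subtypes by largest-remainder apportionment — this
reduces sampling variance relative to a uniform pool draw, which remains
available via `stratified=False`.

Augmentation follows a standard recipe: random x/y flips, translation in
(−30, 30) px, isotropic scaling in (0.9, 1.1), shear in (0, 45)°; 3 copies
per image by default (the multiplicity is a package choice). The transform
order is fixed — flip → scale → shear → translate — with bilinear
interpolation and edge-replication fill, so runs are reproducible from the
policy seed. Augmentation is applied to **training folds only** inside
cross-validation: augmenting before splitting would place near-duplicates of
test images into training sets and inflate every reported accuracy.
Augmented copies carry ids derived from their source (`<id>#aug<k>`), and
the fold-level audit rejects any fitted component whose lineage touches a
test image or a copy of one.

## Backbones

ResNet-50 (bottleneck stages 3/4/6/3), DenseNet-201 (dense blocks
6/12/48/32, growth 32) and MobileNet in its v2 form (inverted residuals,
final 1×1 conv to 1280 channels) are implemented as NumPy inference
networks: im2col convolution, inference-mode batch normalisation, ReLU /
ReLU6, global average pooling. The GAP widths — 2048, 1920, 1280 — are
architectural constants. The classification head is replaced by a
`num_classes` linear layer.

Weights are He-initialised from a seeded generator; batch-norm statistics
are identity at initialisation, and each ResNet residual branch's final
batch-norm gain is scaled to 0.25 (the non-zero cousin of zero-gamma
residual initialisation) so activation variance stays bounded across 16
blocks. Randomly initialised CNNs are structured multiscale random
projections and preserve texture separability well; a local `.npz` weight
cache can supply trained weights, and `pretrained=True` without a cache
fails with an explicit pointer to `pretrained=False`.

"Fine-tuning" is linear probing: the replaced head is trained with momentum
SGD (momentum 0.9) and cross-entropy on the frozen GAP embeddings, using the
recipe epochs = 20, initial learning rate 3×10⁻⁴, mini-batch 4. Because the
trunk is frozen, feature extraction is identical before and after head
training, so scenario II–IV features are extracted once per run — leakage-free
by construction — rather than per fold.

## Wavelet detail stage

Each embedding row is decomposed one level with the discrete Meyer wavelet
and only the detail (highpass) coefficients CD₁ are kept. Conventions:

* **Filter.** `dmey` in the 102-tap convention. The distributed filter has
  62 non-negligible taps; symmetric zero-padding (20 zeros per side)
  preserves every convolution product and the quadrature-mirror relation
  `hi[k] = −(−1)ᵏ lo[L−1−k]` (exact to 1e-12) while fixing the length
  contract.
* **Boundary.** Symmetric half-point extension by L−1 samples per side
  (periodic reflection when the signal is shorter than the filter), full
  convolution, dyadic downsampling. Output length ⌊(N+L−1)/2⌋, hence
  2048→1074, 1920→1010, 1280→690. Other extension modes change these
  lengths and are deliberately not offered.
* **Numerics.** `dmey` is an FIR *approximation* of the Meyer wavelet: its
  highpass taps sum to ≈1.1×10⁻³ (not 0) and the single-level round trip
  reconstructs to ≈10⁻², not machine precision. Truly orthogonal bases
  (Haar, Daubechies) meet 10⁻⁶/10⁻⁸ tolerances, and the test suite asserts
  both regimes separately. Rows are transformed raw, with no per-feature
  standardisation beforehand.

## Fusion and reduction

Detail matrices are concatenated in the fixed order ResNet-50 →
DenseNet-201 → MobileNet (width 2774). Two reductions:

* **DCT**: orthonormal row-wise DCT-II, keeping the first *n*
  (lowest-frequency) coefficients. A `top_energy` mode keeping the *n*
  highest mean-energy indices exists behind a flag for comparison; the
  low-frequency truncation is the default and the standard reading of DCT
  dimensionality reduction.
* **PCA**: centring on the training mean only (no variance scaling), top-*n*
  eigenvectors of the training covariance, computed by full SVD.

PCA is fitted **per training fold**; the fitted model records the ids of its
fitting rows so the leakage audit can verify fold discipline. DCT truncation
has no data-dependent parameters and is exempt by construction.

The retained dimension is chosen by a sequential forward search: candidates
in increasing order, each scored by mean repeated-CV accuracy with the
reduction refitted inside every training fold; the smallest candidate
achieving the maximum wins (parsimony tie-break — a smaller model that
scores the same is preferred). Default grids are 100…2700 step 100 for DCT
and {2, 5, 15, 25, 35, 45, 55, 65, 75, 85, 95} for PCA; infeasible
candidates (exceeding rows−1) are skipped with a warning.

## Classifiers

Five presets behind one fit/predict contract. Where the originating toolbox
conventions are not published, they are fixed here and documented:

| preset | convention |
|---|---|
| linear SVM | C = 1, one-vs-one, per-feature standardisation on training rows |
| cubic SVM | kernel (x·x′/d + 1)³ (γ = 1/d, coef0 = 1), C = 1, standardised |
| 1-NN | Euclidean, brute force; distance ties resolve to the lowest training index |
| LDA | least-squares/pseudo-inverse route (SVD solver); d ≫ n is the normal case |
| ESD | 30 LDA learners, each on a seeded random feature subset of size min(1024, d); posteriors averaged, arg-max |

The subspace size clamps to the feature width because reduced
representations (e.g. 2 principal components) can be far below 1024.

## Evaluation protocol

Stratified 5-fold CV repeated 5 times; the fold seed for repeat *r* is
`base_seed + r`, so any repeat is reproducible in isolation. A class smaller
than *k* is a configuration error naming the class. Metrics come from
one-vs-rest confusion counts per class: accuracy (TP+TN)/(TP+TN+FP+FN),
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP). Zero
denominators yield NaN with a logged note, never a silent 0. Multiclass
summaries are macro-averages (the averaging convention is a package choice
and is stated in the report); fold metrics are averaged across the 25 folds,
and the pooled confusion matrix is emitted alongside for transparency.

## Synthetic test bed

The fixture generator emulates a 5-class image set (normal + four subtypes)
with class-specific texture programs: smooth low-frequency field, Gaussian
blobs on a jittered lattice, oriented stripes, coarse checkerboard,
concentric rings. Pattern scales are relative to the image size, so class
structure survives both CNN embedding and coarse thumbnailing at any
resolution from 32 px up. Class parameters are canonical with small
per-image jitter, all classes share the same mean intensity and RGB
weighting, and all randomness flows from one seeded generator, so identical
specs give bit-identical pixels. Defaults: `signal_strength=0.8`,
`noise_sd=0.05` on the [0, 1] intensity scale.

What passing tests show: every dimension contract, the transform numerics,
fold discipline, and that the cascade recovers designed texture
separability (scenario IV reaches ≈1.0 mean CV accuracy on the fixture).
What they do not show: performance on real H&E tissue — the fixture has no
staining variability, no within-class biological heterogeneity, no shared-
patient correlation between images, and its separability is by construction
far cleaner than subtype histology. Published-accuracy comparisons on the
real dataset additionally require trained backbone weights.

Tests and the acceptance script run the cascade at 32–64 px with 10 images
per class — sizes at which the NumPy backbones evaluate in seconds while
every contract (widths, lengths, protocol) is identical to the 224 px
setting.

## Known limitations

* No backbone backpropagation: scenario I is linear probing of a frozen
  trunk, not full fine-tuning; with random weights its accuracy mainly
  reflects the head and the embedding quality.
* The "validation frequency" of the original training recipe is a
  monitoring cadence; it does not alter optimisation and is not modelled.
* The dmey filter's FIR nature bounds reconstruction checks at ≈10⁻²; this
  is a property of the basis, not of the implementation.
* CSV feature tables round-trip exactly only when re-read with
  round-trip float parsing (`FeatureMatrix.from_csv` does this).
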