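# mbhis

Cascaded histopathology classification for pediatric medulloblastoma (MB).

Medulloblastoma is the most common malignant pediatric brain tumor; its
histological subtypes (classic, desmoplastic, large cell/anaplastic, nodular)
carry different prognoses, and subtype calls from H&E slides are
labor-intensive and subject to inter-pathologist variability. `mbhis`
implements a computer-aided diagnosis cascade for microscopy images at two
levels — binary (normal vs. tumor) and multiclass (four MB subtypes):

1. **Spatial deep features.** Each 224×224×3 image is embedded by three CNN
   backbones (ResNet-50, DenseNet-201, MobileNet), taking the activations of
   the global-average-pooling layer: vectors of width 2048, 1920 and 1280.
2. **Wavelet detail features.** Each embedding x ∈ ℝᴺ is passed through one
   level of the discrete wavelet transform with the discrete Meyer basis
   (`dmey`, 102-tap convention) and only the detail coefficients CD₁ are
   kept: `len(CD₁) = ⌊(N + L − 1)/2⌋`, i.e. 1074, 1010 and 690 coefficients.
3. **Fusion and reduction.** The three detail vectors are concatenated
   (1074 + 1010 + 690 = 2774 columns) and reduced either by truncating an
   orthonormal row-wise DCT-II to its first *n* coefficients or by projecting
   onto the top *n* principal components. *n* is chosen by a sequential
   forward search: score an increasing candidate grid by mean repeated-CV
   accuracy and keep the smallest candidate achieving the maximum.
4. **Classification.** Five classical classifiers — linear SVM, cubic SVM,
   1-NN (Euclidean), LDA, and an ensemble subspace discriminant (30 LDA
   learners on random feature subsets of size min(1024, d)) — evaluated
   under stratified 5-fold cross-validation repeated 5 times, reporting
   accuracy, sensitivity, specificity and precision from one-vs-rest
   confusion counts.

Four scenarios isolate each stage's contribution: (I) backbone used
end-to-end as a classifier, (II) spatial features → classifiers, (III)
wavelet detail features → classifiers, (IV) the fused/reduced cascade.

The backbones are NumPy inference networks. Without a local weight cache
they run with seeded random initialization (a structured multiscale random
projection); every dimension contract and the whole protocol are
weight-independent. A deterministic 5-class synthetic texture generator
(`mbhis.fixtures`) stands in for the histopathology dataset so the full
cascade runs offline; an adapter for a real folder-per-class image tree is
`mbhis.load_folder_dataset`.

## Worked example

Generate a synthetic 5-class set and run the full cascade (scenario IV,
PCA + LDA, retained dimension chosen by the forward search):

```sh
$ mbhis generate-fixture fixture_demo --n-per-class 10 --size 64 --seed 1
normal: 10
classic: 10
desmoplastic: 10
large_cell: 10
nodular: 10
wrote 50 images to fixture_demo
```

```yaml
# runcfg.yaml
scenario: IV
fixture: {n_per_class: 10, image_size: [64, 64], seed: 1}
classifiers: [lda]
fusion: {method: pca}
cv: {k: 5, repeats: 5, base_seed: 0}
```

```sh
$ mbhis run runcfg.yaml --out-dir demo_out --seed 1
scenario IV (multiclass): best fused-pca/lda mean accuracy 1.0000
report written to demo_out/report.json
```

`demo_out/search_lda.csv` holds the search profile — here candidates
2/5/15/25/35 principal components scored 0.968/0.992/0.996/1.000/0.928 mean
CV accuracy, so 25 components were retained — and `report.json` holds the 25
per-fold confusion matrices, the pooled matrix, and macro sensitivity/
specificity/precision. The 1.0 accuracy reflects the fixture's designed
class separability, not a claim about real tissue.

Library use mirrors the CLI:

```python
from mbhis import (FixtureSpec, generate_fixture, ScenarioConfig, CVConfig,
                   ClassifierSpec, run_scenario)

data = generate_fixture(FixtureSpec(n_per_class=10, image_size=(64, 64), seed=1))
report = run_scenario("IV", data, ScenarioConfig(
    cv=CVConfig(k=5, repeats=5, base_seed=0),
    fusion_method="pca",
    classifiers=[ClassifierSpec("lda")],
))
print(report.best().mean_accuracy)
```

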