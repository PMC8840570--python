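# glcmtex

Multi-scale 3D co-occurrence texture descriptors and adaptive group-wise
feature integration for binary lesion classification.

## The problem

Radiologists reading CT colonography cannot reliably tell malignant from
benign large polyps by eye; second-order texture — how gray levels co-occur
across space — carries much of the discriminative signal. The classical
pipeline computes a gray-level co-occurrence matrix (GLCM) per displacement
direction and pools Haralick-type measures across directions, discarding the
fact that the 13 first-ring directions of a 3D grid sample the lesion at
three different geometric scales (distance 1, √2, √3). This package keeps
the scales separate and integrates them adaptively.

## The method

For a masked, cleansed (voxels < −450 HU removed) and 32-level quantized
ROI, the 13 canonical direction GLCMs are computed and 28 statistical
measures evaluated per matrix, giving the descriptor

D = (d₁, …, d₃₆₄),  split by scale into D1 (84), D2 (168), D3 (112).

The hybrid selection model ("multi-group hybrid", MGHM) then works in two
stages:

1. per group: rank features by random-forest Gini importance and reduce by
   forward-stepwise selection (FSFS) — keep a candidate only if the mean
   cross-validated AUC of a cubic-polynomial-kernel SVM strictly improves —
   splitting each Dᵢ into baseline Dᵢᵇ and complement Dᵢᶜ;
2. hierarchy: seed with the best baseline, then integrate the remaining
   whole groups (descending group AUC) and finally the seed's complement,
   one FSFS level each. Strict-improvement acceptance makes the per-level
   AUC trace monotonically non-decreasing; three groups give four levels.

A CNN variant ("MG-CNN") consumes stacked normalized GLCM channels
(32×32×c) through a small two-conv-block network and applies the same
forward-stepwise logic at the level of whole scale groups.

Evaluation is repeated stratified two-fold cross-validation (mean test AUC ±
STD). The default `nested` mode re-fits the entire selection inside each
outer training half, so reported AUC is honest; `paper` mode runs selection
once on the reporting splits for comparability with the original two-stage
protocol. Since no public lesion cohort accompanies the method, the package
ships a phantom generator: correlated Gaussian random fields in irregular
ellipsoidal masks whose two classes differ only in spatial correlation
structure (first-order statistics are matched exactly), plus grouped feature
tables with planted effect sizes.

## Worked example

```sh
glcmtex simulate --preset textured --n-per-class 20 --seed 7 --out scratch/ph
glcmtex extract scratch/ph --out scratch/features.csv --seed 7
glcmtex mghm scratch/features.csv --mode nested --n-repeats 5 --seed 7 \
    --out scratch/report.json
```

prints (timings vary):

```
wrote 40 phantoms to scratch/ph
wrote 40 x 364 feature table to scratch/features.csv
mean AUC 0.948 +/- 0.048 -> scratch/report.json
```

The 40 phantoms are 32³ HU-scaled volumes; benign lesions carry isotropic
texture at correlation length 1 voxel, malignant ones length 4 along one
axis, with identical in-mask mean/STD — so the near-perfect held-out AUC is
recovered purely from second-order texture, exactly the signal the
multi-scale descriptor groups encode (at 40 lesions per class the same
pipeline reaches 1.000). On null phantoms (`--preset null`,
both classes at length 1) the same pipeline reports a mean AUC near 0.5,
confirming that nested selection does not manufacture signal.

The same machinery is available as sklearn-style estimators:

```python
from glcmtex import GLCMFeatureExtractor, MultiGroupHybridSelector

ext = GLCMFeatureExtractor().fit(pairs)          # pairs = [(volume, mask), ...]
X = ext.transform(pairs)                          # (n_samples, 364)
sel = MultiGroupHybridSelector(group_assignment=ext.group_assignment_,
                               n_trees=500, n_repeats=10, seed=0).fit(X, y)
X_small = sel.transform(X)                        # the integrated feature set
```

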