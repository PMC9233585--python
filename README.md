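# gapfcm

Spatially penalized fuzzy C-means segmentation of grayscale medical
images, with genetic-algorithm selection of the initial cluster centers
— plus the fuzzy cluster validity indices and diagnostic-accuracy
arithmetic needed to evaluate such a segmenter in a clinical imaging
study.

## Who this is for

Researchers segmenting MRI-like grayscale images (e.g. breast DCE-MRI
slices) into tissue classes, who need: a fuzzy segmenter that is robust
to pixel noise, a principled way to initialize it, quantitative indices
to compare partitions, and standard 2×2-table diagnostic metrics — all
validated on synthetic phantoms with known ground truth.

## The model

Fuzzy C-means assigns every pixel `k` a membership `u_ik ∈ [0, 1]` in
each of `x` classes (columns of `U` sum to 1) and alternately minimizes

```
A(U, V) = Σ_i Σ_k u_ik^w d_ik²  +  σ Σ_i Σ_k u_ik^w (1 − P_ik)^w
```

where `d_ik²` is the squared Euclidean distance from pixel `k` to
center `v_i`, `w > 1` is the fuzzifier, and `P_ik` is the mean
membership of class `i` over pixel `k`'s 8-connected neighborhood — a
Markov-neighborhood prior. The penalty weight `σ ≥ 0` makes memberships
that disagree with their neighborhood expensive, so isolated noisy
pixels are pulled toward the local majority; `σ = 0` recovers plain
FCM exactly. Because the clustering objective is highly non-convex, the
starting centers are chosen by a small real-coded genetic algorithm
whose fitness is `1 / A(U, V)` — crucial when a class is rare (a small
lesion) and random starts tend to miss it.

Partitions are scored with the partition coefficient
`F = (1/n) Σ u²` (1 = crisp), partition entropy
`H = −(1/n) Σ u log u` (0 = crisp), and a compactness/separation ratio
`S`. Diagnostic performance against pathology uses sensitivity,
specificity, accuracy, PPV and NPV from the 2×2 confusion table, with a
solver that reconstructs the joint table when a study publishes only
the marginals and the rounded percentages.

## Worked example

```python
import numpy as np
from gapfcm import SpatialFuzzyCMeans, GaConfig, halves_phantom, misclassification_rate

ph = halves_phantom(64, 64, intensities=(0.2, 0.8), noise_sd=0.1, seed=0)
est = SpatialFuzzyCMeans(n_clusters=2, sigma=1.0, init="ga",
                         ga_config=GaConfig(seed=0)).fit(ph.image)
print("centers:", np.sort(est.cluster_centers_.ravel()))
print("error  :", misclassification_rate(est.labels_image_, ph.truth))
```

prints

```
centers: [0.19911348 0.79736236]
error  : 0.0
```

— the two recovered class means sit on the generating intensities
(0.2 and 0.8) to ~2×10⁻³ despite 0.1 Gaussian noise, and every one of
the 4096 pixels is assigned to its true region: the spatial penalty has
absorbed the noise that plain FCM would scatter across the midline.

The diagnostic side, from a published study's marginals (121/38 test
positive/negative, 128/31 pathology positive/negative) and its five
rounded percentages:

```python
from gapfcm import solve_table, dx_metrics
t = solve_table(121, 38, 128, 31, (91.41, 87.1, 90.57, 96.69, 71.05))
print(t)                       # ConfusionTable(tp=117, fp=4, fn=11, tn=27)
print(dx_metrics(t).rounded()) # {'sensitivity': 91.41, 'specificity': 87.1,
                               #  'accuracy': 90.57, 'ppv': 96.69, 'npv': 71.05}
```

The joint table is the unique one consistent with all five percentages.

A command-line interface mirrors the library:

```bash
gapfcm phantom -o ph.png --noise-sd 0.1 --truth-out truth.png
gapfcm segment ph.png -o labels.png          # GA init + penalized FCM
gapfcm compare ph.png -o indices.csv --seeds 0,1,2,3,4
gapfcm dx --cells 117 4 11 27
```

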