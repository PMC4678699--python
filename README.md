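# stisodata

Spatially and temporally adjusted ISODATA (ST-ISODATA) tissue-signature
analysis of serial multiparametric stroke MRI.

## The problem

After an ischemic stroke, brain tissue evolves heterogeneously: some regions
are irreversibly infarcted from the first hour, others are recruited into the
lesion over days, others swell transiently and recover. Single-timepoint,
single-parameter MRI (an acute ADC map, a follow-up T2 map) cannot separate
these fates. This package implements a voxel-wise, fully unsupervised
alternative: quantitative ADC, FA and T2 maps acquired serially (1 h to 10
days post-occlusion) are combined into one feature vector per voxel and
clustered, so that each cluster is a *temporal tissue signature* — a distinct
spatiotemporal MRI evolution pattern — rather than a snapshot intensity
class. It is aimed at researchers running serial preclinical or clinical
stroke imaging studies who want operator-independent lesion characterization
and a quantitative way to choose the MRI inputs that segment best.

## The method

For each voxel v inside the analysis mask (brain minus voxels with
first-timepoint ADC > 1.2x10^-3 mm^2/s, i.e. CSF and large vessels), the
relative maps rADC, rFA, rT2 — each map divided by its mean contralateral
hemispheric value — at t timepoints and f parameters are concatenated into a
t x f feature vector, after a distance-weighted neighbourhood smoothing that
enforces spatial contiguity. The vectors are clustered with ISODATA, a
k-means-like algorithm whose cluster count adapts to the data:

- voxels are assigned to the centroid µ_j with smallest Mahalanobis distance;
- clusters with fewer than Φ_N voxels are discarded and their voxels
  redistributed;
- a cluster whose intra-cluster dispersion D_intra (mean Mahalanobis distance
  to the centroid) exceeds Φ_S is split; a cluster pair whose inter-centroid
  distance D_inter falls below Φ_C is merged (at most L merges per
  iteration);
- the live cluster count is confined to (0.5 K, 2 K + 1) around the anchor K;
- iteration stops on convergence (relative centroid displacement < ε_r) or
  after I iterations.

Φ_C is derived from the data as the Mahalanobis distance between
contralateral white- and grey-matter mean feature vectors; Φ_S as the pooled
standard deviation of white-matter feature values. Clusters whose centroid
trajectory is temporally flat (coefficient of variation ≤ 0.05) are merged
into a single normal-tissue cluster; the survivors are placed on a
reproducible 1–100 scale (contralateral-WM-matching cluster → 1,
CSF-matching cluster → 100) and binned in tens into named signatures
(N, I–V). Segmentation quality is the Dice similarity index
DSI = 2·TP / (2·TP + FP + FN) between the pruned abnormal region and the
reference "Maximal Lesion" ROI, swept over six MRI input combinations
(ADC, FA, T2, ADC+FA, ADC+T2, ADC+FA+T2) and CoV thresholds 0.10…0.01.

Voxels are independently classified into operational tissue classes from the
acute (1-h ADC), maximal and chronic (17-day T2) lesion ROIs:
Core = acute ∩ chronic, Growth = chronic \ acute, Recovery = acute \ chronic,
Edema = maximal \ (acute ∪ chronic).

Because no imaging data ships with the package, a synthetic serial stroke
phantom (`stisodata.phantom`) generates aligned ADC/FA/T2 volumes with
planted lesion regions following configurable relative time-courses, plus
ground-truth labels, lesion ROIs and tissue classes, so the entire pipeline
is testable end to end. See `docs/methods.md` for the model details and its
limitations.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from stisodata import (
    PhantomConfig, generate_phantom, preprocess_study,
    derive_dispersion_params, IsodataParams, run_isodata,
    prune_by_cov, dice,
)

dataset = generate_phantom(PhantomConfig(seed=1))
prep, features = preprocess_study(dataset.study)
phi_c, phi_s = derive_dispersion_params(
    features, prep.ref_rois["WM"], prep.ref_rois["GM"]
)
model = run_isodata(features, IsodataParams(phi_c=phi_c, phi_s=phi_s), seed=1)

x, y, z = features.voxel_index.T
ari = adjusted_rand_score(dataset.generative_labels[x, y, z], model.assignments)
pruned = prune_by_cov(model, threshold=0.05)
region = prep.ipsilateral_region()
overlap = dice(pruned.abnormal_mask() & region, dataset.truth_rois.maximal, region)

print(f"voxels clustered : {features.n_voxels}")
print(f"phi_C, phi_S     : {phi_c:.2f}, {phi_s:.2f}")
print(f"clusters found   : {model.n_clusters} (converged: {model.converged})")
print(f"abnormal clusters: {pruned.n_abnormal}")
print(f"ARI vs truth     : {ari:.3f}")
print(f"DSI vs maximal   : {overlap.dsi:.3f}")
```

Output:

```
voxels clustered : 37176
phi_C, phi_S     : 7.61, 1.16
clusters found   : 6 (converged: True)
abnormal clusters: 4
ARI vs truth     : 0.974
DSI vs maximal   : 0.872
```

The default 64x64x24 phantom carries three planted abnormal signatures
(II, IV, V). ISODATA finds six clusters — white matter, grey matter, the
three lesions and a lesion-border gradient cluster; CoV pruning keeps the
four temporally dynamic ones as abnormal. The adjusted Rand index of 0.974
against the generative labels means the partition almost perfectly recovers
the planted tissue classes, and the pruned abnormal region overlaps the
planted Maximal-Lesion ROI with a Dice index of 0.872.

The same run is available from the shell:

```sh
stisodata phantom --out phantom/ --seed 1
stisodata run --manifest phantom/study.yaml --out run/ --seed 1
stisodata sweep --manifest phantom/study.yaml --seed 1 --out sweep.csv
```

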