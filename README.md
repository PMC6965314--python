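# gfcpipe

Voxel-wise **global-brain functional connectivity (GFC)** analysis of
resting-state fMRI, packaged as a tested, reusable pipeline: per-subject
preprocessing of already-aligned 4D BOLD volumes, GFC map computation,
covariate-adjusted group inference with permutation-based family-wise error
(FWE) control, clinical-score correlation, and SVM-based patient/control
discrimination. A first-class synthetic cohort generator plants known group
effects so every stage is testable end to end without any imaging download.

## Who this is for

Researchers studying group differences in intrinsic brain connectivity —
for example reduced motor-network coupling in movement disorders such as
cervical dystonia — who want a seed-free, whole-brain connectivity statistic
with assumption-light inference, and a way to validate the full analysis
chain against data with known ground truth.

## The statistic

For gray-matter voxels i = 1..V (gray matter: tissue probability > 0.2),
with standardized time series x_i over T kept volumes, the GFC of voxel i is
the average correlation with every other gray-matter voxel,

    GFC_i = (1 / (V − 1)) · Σ_{j≠i} r_ij,      z_i = atanh(GFC_i),

computed in O(V·T) via GFC_i = ((x_i · Σ_j x_j)/T − 1)/(V − 1) and checked
against the literal O(V²·T) pairwise definition. Group inference fits
z ~ intercept + group + mean FD + age at each voxel and controls FWE with
the maxT permutation method under Freedman–Lane covariate handling.

Preprocessing follows the standard resting-state chain: discard 10 volumes →
4 mm FWHM smoothing → linear detrend → 0.01–0.08 Hz band-pass →
nuisance regression (Friston-24 motion expansion + white-matter + CSF mean
signals; the global signal is *not* removed) → scrubbing of frames with
framewise displacement (FD) > 0.2 mm; subjects exceeding 2 mm translation or
2° rotation are excluded.

## Worked example

```python
import dataclasses, numpy as np
from gfcpipe import SimConfig, generate_cohort, gray_matter_mask
from gfcpipe import cohort_zmaps, permutation_fwe, extract_clusters
from gfcpipe import cluster_mean_feature, pearson_r_p
from gfcpipe.pipeline import cohort_design

# a 19 patient / 21 control cohort with two planted low-coupling clusters
subjects, truth = generate_cohort(SimConfig(seed=42))
gm = gray_matter_mask(truth.gm_prob, threshold=0.2)
maps = cohort_zmaps(subjects, gm)                  # subjects x V Fisher-z GFC
design, _ = cohort_design(subjects)                # [1, group, mean FD, age]
res = permutation_fwe(maps, design, n_perm=500, seed=1)
clusters = extract_clusters(res.t, res.fwe_p, gm, alpha=0.05)
print([(c.n_voxels, round(c.peak_t, 2), c.sign) for c in clusters])

feat = cluster_mean_feature(maps, gm, clusters[0])
patients = np.array([s.group == "patient" for s in subjects])
scores = np.array([s.score for s in subjects])
print(pearson_r_p(feat[patients], scores[patients]))
```

Output:

```
[(17, -13.66, -1), (17, -12.53, -1)]
(-0.693453202697195, 0.0009931019604581524)
```

Both planted 17-voxel clusters are recovered with strongly negative group
t-statistics (patients lower), and the cluster-mean GFC of patients
correlates negatively with the planted severity score (r = −0.69,
p = 0.001) — the planted effect signature.

The same experiment runs from the shell:

```bash
gfcpipe show-config > config.yaml   # edit paths / parameters
gfcpipe run-all -c config.yaml --seed 7
```

writing preprocessed volumes, GFC z-maps, the t / FWE-p maps, a cluster
table (TSV), per-cluster scatter data, correlation and classifier reports
(JSON), and a provenance log with the config hash and seed.

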