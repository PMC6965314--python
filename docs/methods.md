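# Methods

## Overview

gfcpipe implements a voxel-wise global-brain functional connectivity (GFC)
analysis for resting-state fMRI at the group level. The pipeline consumes
per-subject 4D BOLD volumes that are already motion-corrected and spatially
aligned across subjects, plus the six rigid-body motion parameter series and
gray/white/CSF tissue probability volumes; slice-timing correction,
realignment estimation and nonlinear spatial normalization are out of scope.
Every stage is exercised on synthetic cohorts with planted ground truth, so
the statistical behaviour of the whole chain (error calibration, effect
recovery) is verified by simulation rather than asserted.

## The GFC statistic

For each voxel i in the gray-matter mask (tissue probability strictly
greater than 0.2; a single template mask shared by all subjects), GFC_i is
the mean Pearson correlation between voxel i's time series and every other
gray-matter voxel's series, computed over scrubbed-surviving volumes only.
The Fisher transform z_i = atanh(GFC_i) is applied *after* averaging; the
alternative (transforming each pairwise r before averaging) is monotonically
related, so group-difference directions are unaffected, but values differ —
the post-averaging convention is fixed here. With rows standardized to
population SD 1 the map is computed in O(V·T) as
((x_i·S)/T − 1)/(V − 1), S = Σ_j x_j; the literal O(V²·T) pairwise
definition is kept in the API (`gfc_bruteforce`) as a permanent oracle, and
the two paths must agree within 1e−10.

Edge conventions: |r| = 1 is clipped to 1 − 1e−7 before atanh (with a
warning); zero-variance voxels are dropped from the mask with a warning;
off-mask voxels are NaN in volume-space outputs; every computed map is
checked against the positive-semidefiniteness bound mean_i(GFC_i) ≥
−1/(V−1).

## Preprocessing

Fixed order: discard the first 10 volumes → isotropic Gaussian smoothing
(4 mm FWHM, σ = FWHM/(2√(2 ln 2)) converted to voxels, reflective
boundaries) → per-voxel linear detrend → zero-phase band-pass
0.01–0.08 Hz → nuisance regression → scrubbing. Choices made where the
procedure was genuinely open:

- **Band-pass** is frequency-domain masking with raised-cosine transition
  edges (default width 0.002 Hz). The contract is behavioural: passband
  amplitude preserved within 5%, amplitude at ≥ 2× the upper edge attenuated
  by ≥ 95%, and no phase shift.
- **Detrending precedes filtering**; the two nearly commute for this band,
  but the order is fixed and logged.
- **Nuisance design**: the Friston 24-parameter motion expansion
  [p(t), p(t−1), p(t)², p(t−1)²] with the first lagged row zero-filled (T is
  preserved), plus white-matter and CSF mean signals. The global signal is
  deliberately not removed. Tissue mean signals are extracted from the
  *unsmoothed* (but detrended and band-passed) data: on small grids the
  smoothing kernel smears gray-matter signal into the thin WM/CSF
  compartments, and regressors built from smoothed data measurably remove
  true connectivity signal. WM and CSF masks threshold the respective
  probability maps at 0.8. All-zero design columns are inert; collinear
  columns raise an error naming the culprits, and residuals are checked to
  be orthogonal to the design within 1e−8.
- **Framewise displacement** uses the displacement formula
  FD_t = Σ|Δtranslation| + r·Σ|Δrotation|, rotations converted to arc
  length on an r = 50 mm sphere; FD_0 = 0. Scrubbing censors frames with
  FD strictly above 0.2 mm *after* nuisance regression (censored frames are
  excluded from correlation, never interpolated). Subjects with fewer than
  50 surviving volumes (configurable) are flagged unusable.
- **Motion QC**: subjects whose raw trace strictly exceeds 2 mm translation
  or 2° rotation in any direction are excluded before group analysis.

## Group inference

At each gray-matter voxel the Fisher-z GFC is modeled as
z = β₀ + β₁·group + β₂·meanFD + β₃·age + ε (patient = 1), and the test
statistic is t = β̂₁/SE(β̂₁) with df = n − 4. With no covariates this reduces
exactly to the pooled two-sample t-test. Family-wise error over voxels is
controlled by **permutation maxT with Freedman–Lane covariate handling**:
the nuisance covariates are fitted, their residuals permuted, the covariate
fit re-added, the full model refitted, and the maximum |t| recorded per
permutation; FWE p_i = (1 + #{max-t ≥ |t_i|})/(n_perm + 1). This estimator
never returns zero and is slightly conservative at small n_perm. Voxel-level
FWE plus cluster-extent reporting is exposed; random-field-theory FWE, FDR
and cluster-mass inference are non-goals. Suprathreshold voxels are grouped
into connected components separately per t sign (26-connectivity by
default, configurable 6/18/26), sorted by |peak t| with lexicographic
tie-breaks.

Clinical correlation extracts each significant cluster's mean z per subject
and computes the Pearson correlation with the patients' severity scores;
p comes from the exact t(n−2) transform, with Bonferroni division by the
number of clusters. A Shapiro–Wilk statistic is reported alongside as a
normality gate, without any claim that the original analyses used the same
check. Group demographic comparisons use the pooled-variance Student t-test
(reconstructable from group means/SDs/sizes) and the Pearson chi-square
without continuity correction — both choices reproduce the conventional
printed two-decimal p-values for such tables. A region-pair (ROI–ROI)
connectivity test — Fisher-z of the correlation between two region-mean
series, compared across groups by pooled t — covers motor-network
(M1–SMA-style) coupling questions.

## Classification

A soft-margin RBF-kernel SVM (C = 1, γ = 1/n_features — the classical
library defaults) discriminates patients from controls from GFC-derived
features. Validation logic is implemented in the package, not delegated:
leave-one-out (n iterations, each training on n−1), stratified k-fold as a
full rotation (every fold is tested once, rather than a single 4-train /
1-test split), and a label-permutation test of the LOO accuracy with
p = (1 + #{null ≥ observed})/(n_perm + 1). Patients are the positive class;
sensitivity is computed on patients, specificity on controls, and balanced
accuracy is their mean. Multi-feature inputs are z-scored with training-fold
statistics only. Atlas-region feature extraction takes any integer-labeled
volume and returns region-mean z per subject (empty regions are dropped
with a warning); no anatomical template is bundled — tests use synthetic
atlases over the simulated grid.

## Synthetic cohorts

The generator emulates the target study conditions: 19 patients vs 21
controls, 250 volumes at TR = 2 s, 3 mm voxels, ages from N(39, 9²)
truncated to [18, 60] in both groups, sexes drawn with equal rates across
groups, and patient severity scores centered at 16.32 with SD 4.45. The
default grid is 12×12×12 voxels with concentric WM-core / GM-shell /
CSF-rim compartments; the pipeline is grid-size agnostic.

BOLD model: `n_latents` band-limited (0.01–0.08 Hz) unit-variance latent
signals are synthesized in the frequency domain with random phases, so the
band-pass stage leaves them nearly untouched by construction. Latent 1 loads
on all gray-matter voxels with weight `baseline_coupling` (default 0.6);
the remaining latents load on disjoint angular sectors (weight 0.3) to give
network-like structure; WM and CSF carry their own compartment signals
(weight 0.5) so nuisance regression has real work. Voxel noise is N(0, 1)
by default, plus a per-voxel linear drift (SD 0.3 over the scan) and a
constant intensity offset inside the head. In one or two compact spherical
clusters (~17 gray voxels each, comparable to the reported cluster sizes)
the global-latent weight is replaced by the subject's coupling c_s:
controls draw c_s around `baseline_coupling`, patients around
`baseline_coupling − effect_delta` (default delta 0.3), both jittered with
SD `coupling_jitter_sd` = 0.08 so coupling varies across subjects. The
severity score is score_mean + score_slope·(c_s − E[c_s]) + noise with
slope −50 score-units per unit coupling and noise SD 4.45, planting a
negative coupling–score correlation of realistic magnitude (|r| ≈ 0.5–0.7
at n = 19). Motion traces are slow random walks (mean FD ≈ 0.02 mm,
matching the reported cohort) with Bernoulli single-frame spikes (rate 0.02)
of 0.3 mm, guaranteed to trip the 0.2 mm scrubbing threshold.

What the generator does **not** emulate: hemodynamic response convolution,
cardiac/respiratory physiological noise, motion-correlated signal artifacts
(motion traces are independent of the BOLD model), scanner drift beyond a
linear trend, multi-site effects, and the true spatial covariance of real
gray matter. Passing tests therefore demonstrate the *statistical
machinery* — calibration, recovery, invariances — not fidelity to any real
dataset; the reported real-data peak coordinates, t-values and classifier
accuracies are not reproducible without the original (unavailable) data.

## Simulation studies and problem sizes

- **FWE calibration**: 200 replicate null cohorts (effect_delta = 0, 20
  subjects, 12³ grid, 500 permutations); the family-wise false-positive
  rate at α = 0.05 must fall in [0.02, 0.09], the binomial band around 0.05
  (the +1-corrected permutation estimator sits slightly below 0.05 by
  construction).
- **Recovery**: 50 replicate cohorts at effect_delta = 0.4, n = 19/21;
  cluster detection at FWE p < 0.05, patient-lower feature direction, and
  the negative feature–score correlation sign must each hold in ≥ 95% of
  replicates.
- **Classifier sanity**: perfect LOO metrics on a wide-margin 1-D feature;
  mean LOO accuracy within 3 SE of 50% over 200 label-randomized noise
  datasets (labels are iid fair coin flips: forcing exact class balance
  makes LOO accuracy drop measurably *below* chance through the well-known
  held-out majority-shift effect, which is a property of LOO, not of the
  classifier); permutation p < 0.01 for the separable case.

These studies compute GFC maps from the generated series via the reduced
detrend + standardize route rather than the full preprocessing chain — the
planted signals are band-limited by construction and no motion artifact is
injected into the BOLD model, so the full chain adds cost but no
discriminating information at replicate scale. The full chain is itself
validated by the latent-survival property (a planted latent survives
discard → smooth → detrend → band-pass → nuisance regression → scrubbing
with amplitude correlation ≥ 0.9 under a no-motion, low-noise
configuration) and by the end-to-end experiment test, which runs simulate →
preprocess → GFC → group → correlate → classify through the on-disk
artifact interfaces.

## Numerical and interface conventions

- Determinism: every stochastic step takes a seed; cohort generation is
  byte-identical for identical configurations; spawned child seeds come
  from numpy SeedSequence.
- Volume outputs use 0-based voxel indices internally; mm coordinates are
  emitted only when an affine is available (synthetic fixtures use an
  identity-scaled 3 mm affine).
- All artifacts embed the run-configuration hash and seed; configurations
  serialize losslessly to YAML and unknown keys are rejected.
- Degenerate inputs: zero residual variance yields t = 0 with a warning
  (threshold relative to the data's own scale); all-equal maps yield FWE
  p = 1; empty cluster lists are valid results.

## Known limitations

The simulated grid is far smaller than a real brain (hundreds rather than
tens of thousands of gray voxels), so multiple-comparison severity is
correspondingly milder; motion parameters do not corrupt the BOLD signal,
so motion regression is exercised only as a degrees-of-freedom cost; the
Tsui-like severity score is a truncated normal — the true score
distribution is unknown beyond its first two moments; and anatomical
labeling of clusters requires external templates and is out of scope.
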