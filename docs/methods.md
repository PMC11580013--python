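# Methods

`netstates` implements a resting-state network analysis for multivariate
component time series: group ICA with stability analysis, time-course
cleaning, static and window-free dynamic inter-network connectivity,
k-means connectivity states with per-subject temporal properties,
covariate-adjusted group statistics, and a leave-one-out SVM prognosis
classifier.  This note records the models, the tunable parameters, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## The synthetic cohort model

No public data accompany the analysis, so every stage is exercised on
seeded synthetic cohorts with planted ground truth.

**Network dynamics.**  Each subject's inter-network signal follows a
hidden-Markov Gaussian switching-covariance model: a two-state Markov
chain (frame resolution = one TR) selects, per frame, one of two network
covariance matrices; the observation is a zero-mean multivariate normal
draw under that covariance.  State 1 is the strongly connected state
(mean off-diagonal correlation 0.55 by default), state 2 the sparsely
connected one (0.10).  Default transition probabilities (leave-strong
0.06, enter-strong 0.03) put the stationary occupancy of state 1 at 1/3
— the strongly connected state is the less frequent one — with mean
dwell times of roughly 13 s and 27 s at TR 0.8 s.  A hidden-Markov model
was chosen because it yields an exactly analyzable ground truth (planted
state sequences, occupancies, switch counts) while reproducing the
qualitative two-state structure that k-means recovers from the dynamic
connectivity frames.

**Group effects.**  Patients differ from controls in two planted ways:
(a) a transition-probability shift (default 0.015) biasing their chain
toward state 1, and (b) an additive increment (default 0.12) on the
correlations of three configured network pairs in every state.  Both
effects are configurable and can be zeroed for null calibration.

**Scan geometry.**  Defaults mirror a 6-minute acquisition: TR 0.8 s,
450 volumes of which the first 10 are discarded, 11 networks; the
analyzed series is therefore 440 frames, and any dynamic-connectivity
tensor is 440 frames x 121 ordered connections.

**Clinical table.**  Demographics are drawn from the study moments
(patients age 54.0 +- 10.7 y, controls 53.7 +- 8.3 y; education ~11 y;
balanced sex; symptom duration 4.0 +- 2.1 y).  The pre-operative
myelopathy score is truncated-normal 11.4 +- 2.1 on the 0-17 scale.  The
surgical recovery rate (post - pre)/(17 - pre) is built as
0.74 + beta * 0.16 * z + noise, where z is the patient's standardized
planted state-1 fraction time and beta (default 0.6) is the outcome
coupling; noise is scaled so the marginal SD stays at 0.16.  A linear
coupling is the simplest mechanism that lets classification performance
be tuned continuously from chance to near-perfect.  The paper-level
coupling strength is unknown (only mean +- SD of the recovery rate is
reported), so beta is an explicit free parameter, not an estimate.

**Motion.**  Six rigid-body parameters follow AR(1) drift (coefficient
0.95; marginal SD 0.05 mm translations, 0.001 rad rotations) — slow,
small drifts adequate for exercising the Friston-24 regression and the
three framewise-displacement variants.

**Randomness.**  All draws flow from one root seed through named
per-subject substreams (SHA-256 of the subject key folded into a
`SeedSequence`), so cohorts are bit-for-bit reproducible and stable
under partial regeneration.

**What the generator does not emulate:** hemodynamic-response
convolution, scanner drift and physiological noise spectra, spatial
autocorrelation of real maps, site/scanner effects, and non-Gaussian
tails of real BOLD series.  Passing tests therefore demonstrate the
estimators' correctness under the stated model, not their behavior on
real acquisitions.

## Time-course post-processing

Fixed order: polynomial detrending -> despiking -> low-pass -> motion
regression; every stage preserves the frame count.

* Detrending fits intercept plus polynomial orders {1,2,3} jointly on a
  centered, [-1,1]-scaled time index (joint and sequential fits coincide
  for nested polynomial bases).
* Despiking follows the AFNI scheme: smooth baseline (order-2
  polynomial + Fourier pairs up to 3 cycles), robust sigma MAD/0.6745,
  and soft compression of samples beyond c1 = 2.5 sigmas toward the
  baseline with asymptote c2 = 4 sigmas.
* The low-pass is a 4th-order Butterworth at 0.08 Hz applied
  forward-backward (zero phase) with even-reflection padding.
* Motion regression projects out the 24 Friston regressors
  [R(t), R(t-1), R(t)^2, R(t-1)^2]; collinear columns are dropped with a
  warning, and no intercept is added (series are already detrended).
* Framewise displacement: Power (50 mm rotation radius), Jenkinson
  (RMS of the differential rigid transform over an 80 mm sphere), and
  Van Dijk (translation norm); radii follow the literature conventions.

## Connectivity estimators

**Static.**  Pairwise Pearson correlation, Fisher-Z transformed with |r|
clipped at 1 - 1e-7; the diagonal is stored as 0.

**DCC.**  Stage 1 fits GARCH(1,1) per series by Gaussian
quasi-maximum-likelihood; the variance recursion is initialized at the
sample variance and evaluated as an IIR filter.  Optimization runs in an
unconstrained parameterization (log omega, logit persistence, logit
alpha share) enforcing positivity and alpha + beta < 1; failures fall
back to the constant-variance model.  Stage 2 maximizes the DCC(1,1)
correlation pseudo-likelihood over (a, b) with a logit parameterization
of (a + b, a/(a+b)), three fixed starts, and a coarse grid fallback.
Q-bar is the sample correlation of the standardized residuals.  Every
frame's R_t is a correlation matrix by construction (convex combination
of PSD terms).

**FLS.**  For each ordered pair of standardized series the time-varying
slope minimizes the squared measurement residuals plus mu (default 100,
the DynamicBC convention) times the squared frame-to-frame slope
changes; the exact solution comes from one symmetric tridiagonal solve
per pair.  The two directed slopes are averaged into a symmetric value.
FLS values are regression slopes and may leave (-1, 1); they are clipped
before the Fisher-Z transform and the clip count is kept on the tensor.
As mu -> infinity the estimate converges to the static OLS slope
(asserted at mu = 1e12 within 1e-4).

Temporal summaries are the elementwise mean and sample SD (ddof = 1) of
the Fisher-Z series.

## Connectivity states

Frames from all subjects of both groups are pooled before clustering —
states must be shared objects for group occupancy comparisons to be
meaningful.  Clustering is Lloyd-style with cityblock (L1) assignment
and the exact L1 centroid update, the coordinatewise median (a
documented departure from mean-update k-means, since the upstream
toolbox is unspecified); the best of 20 random initializations by total
L1 cost is kept, and an emptied cluster is reseeded at the farthest
point.  The state count is scanned over k in 2..8: the mean silhouette
width under cityblock distances decides, the Calinski-Harabasz index is
recorded, and a disagreement between the two is logged.  A best
silhouette below 0.3 triggers a weak-structure warning — smooth dynamic
estimators produce many transition frames, so absolute silhouettes are
modest even when the planted k is recovered cleanly.  States are
renumbered by decreasing mean off-diagonal centroid connectivity, so
state 1 is always the strongly connected state.  Per subject: fraction
time, mean dwell time in frames (0 for an absent state; multiply by TR
for seconds), and the count of adjacent-frame label changes (total
transitions, not per-state).

## Group statistics

Feature-wise group differences use OLS on [1, group, age, sex,
education] with the t-test on the group coefficient (identical to the
pooled-variance two-sample t without covariates).  Degenerate inputs
are flagged, not raised: constant responses report p = 1, perfect fits
report p at the machine floor.  Families of tests (static pairs, dynamic
means, dynamic SDs, temporal properties, correlations) are corrected
separately by Benjamini-Hochberg FDR.  Voxelwise map comparisons use a
permutation max-cluster-extent scheme — observed |t| thresholded at the
voxel level, face-adjacency clusters, and a null of maximum cluster
extents from Freedman-Lane residual permutations (the nuisance fit is
retained, its residuals permuted) — in place of parametric random-field
FWE, at the same nominal voxel (0.001) and cluster (0.05) levels.
Correlation analyses with clinical scores default to patients only,
since outcome scores exist only for patients.

## Prognosis classification

Patients are labeled good/poor at a recovery-rate cutoff of 0.75
(boundary counts as good).  Feature sets: 55 static upper-triangle
Fisher-Z values; 115 dynamic features (55 temporal means + 55 temporal
SDs + 2k+1 = 5 temporal properties at k = 2); 170 for the fusion.  LOOCV
keeps all data-dependent steps inside the training fold:
standardization statistics, LASSO selection (inner 5-fold CV over a
fixed log-spaced grid by default; a fixed penalty is available for
reproducibility studies), and the sigmoid-kernel SVM (C = 1, gamma =
0.1, coef0 = 0, uniform class weights).  A fold whose LASSO selects
nothing falls back to all features (logged).  AUC is the tie-aware
Mann-Whitney probability; the permutation p is the literal proportion
of label-shuffled LOOCV accuracies at or above the observed one, with
1/n_permutations as the smallest reportable value.

A note on null behavior: LOOCV accuracy under shuffled labels is
pessimistically biased below the majority rate at small n (holding out a
subject tilts the training balance against its class); at n = 40 the
bias is within a few points of chance.  Null-calibration checks are
therefore run at the study-scale n, and the permutation p remains valid
at any n because observed and null accuracies share the bias.

## Group ICA

Spatial ICA on voxels x time data: PCA along the time dimension, then
natural-gradient infomax with the logistic nonlinearity on the whitened
reduced data (mini-batch passes of ~sqrt(n) samples, base learning rate
0.001 per component, annealing by 0.9 on oscillation, stop when the
relative weight change per pass falls below 1e-6, at most 500 passes).
Model order can be estimated by the Wax-Kailath MDL criterion on the
covariance eigenvalues; no correction for the spatial-correlation
violation of the i.i.d. sample assumption is applied, so on real
smoothed data the criterion will overestimate less conservatively than
toolbox variants that subsample.  Stability analysis repeats infomax
with independent random initializations (no bootstrap resampling),
clusters the pooled estimates by average-linkage agglomeration under
1 - |corr| dissimilarity, and reports each cluster's centrotype and
quality index Iq (mean within- minus mean between-cluster |corr|).
Components are sign-oriented to positive skewness.  Subject maps and
time courses come from two-stage least squares (dual regression).
Component selection retains, per component, the best-Dice template label
when Dice >= threshold and the sub-0.10 Hz fraction of time-course power
passes; visual artifact criteria used in manual practice are not
encoded.  The empty-vs-empty Dice is defined as 0 with a warning.

## Problem sizes in tests and the acceptance script

Simulation-based checks run at reduced but honest sizes chosen for desk
reproduction: state-count recovery uses 12 + 12 subjects at 200 analyzed
frames over 10 seeds; null calibrations use 200 reduced cohorts
(group-test level), 50 replicates at 199 permutations (permutation-p
uniformity), and study-scale n = 40 for LOOCV chance checks; the fusion
comparison uses 50 replicate feature cohorts at the study's 44-patient
size.  These sizes are statements of the test design, recorded here so
the numbers in the suite can be read unambiguously.

## Known limitations

* The generator's Gaussian switching model cannot probe robustness to
  hemodynamics, artifacts, or non-stationary noise.
* DCC standard errors are not computed; only point paths are used.
* FLS symmetrization (averaging directed slopes) is one of several
  defensible conventions; values are not bounded by 1.
* The MDL order estimate ignores spatial autocorrelation (see above).
* The permutation-FWE map test assumes exchangeable residuals under the
  reduced model; heavy-tailed voxel noise is not specifically handled.
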