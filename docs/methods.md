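# Methods

`painpattern` re-creates, end to end, a between-subject multivariate
decoding analysis of evoked fMRI responses: building "pain matrix" region
masks, equating stimulus saliency/intensity between conditions, reducing
each subject's runs to per-modality activation patterns, and asking whether
a linear classifier trained on some subjects' patterns predicts stimulus
modality (or intensity class) in a held-out subject. Because no suitable
public recording exists for the two experimental designs involved, the
package ships a synthetic BOLD generator whose cohorts exercise every stage
under known ground truth.

## Synthetic cohorts

Two designs are emulated.

* **Event-related, four modalities.** 14 subjects, 4 runs, 32 stimuli per
  run (8 each of pain, touch, audition, vision) in pseudo-random order with
  fewer than 3 consecutive same-modality stimuli, inter-stimulus intervals
  uniform on 10–19 s, TR 3 s. Each stimulus carries a saliency rating on a
  0–10 scale (default mean 5.5, SD 2.2 for every modality — the published
  group statistics constrain only these moments, so per-subject rating
  distributions are free parameters of the generator and documented as
  such).
* **Blocked, two modalities.** 51 subjects, 2 sessions, each session 3 pain
  and 3 touch blocks of 4 trials (25 s per trial, stimulus at a uniform
  2–12 s offset), two intensity levels calibrated so ratings center on 3
  (low) and 6 (high) with SD 1, TR 0.8 s. Optional saliency and valence
  columns are drawn from a Gaussian copula against the realized intensity
  ratings (default targets +0.86 and −0.49).

**Signal model.** Each modality owns a compact cluster of ROI voxels
(~8 % of the ROI, pairwise disjoint, including a cluster for the shared
intensity-graded pattern); an event contributes
`pattern(v) · (A_m + j_{s,m}) + shared(v) · A_r · rating` at its onset,
convolved with a canonical double-gamma HRF (gamma shapes 6 and 16,
undershoot ratio 1/6, peak normalized to 1 so amplitudes are in signal
units). `j_{s,m}` is an additive per-subject Gaussian jitter on the
amplitude, not the geometry: between-subject decoding presumes coarse,
spatially aligned patterns, and amplitude variability is the part that
stresses it. The jitter is deliberately *not* rectified at zero — a zero
base amplitude must stay signal-free in expectation, which a
`max(·, 0)` would silently break.

**Noise.** An AR(1) process (coefficient 0.3) plus white noise, each
carrying half of `noise_sd²` so that `noise_sd` is the total marginal SD;
spatially independent. This is the simplest model that gives detrending,
z-scoring and the AR-blind OLS stages something real to do. Motion tables
are random walks (rotations scaled to comparable displacement at a 50 mm
radius) with an optional HRF-shaped stimulus-locked bump and an optional
coupling of the motion trace into voxel signals through random loadings.

**What the generator does not emulate** — anatomical structure, spatially
correlated noise, physiological (cardiac/respiratory) fluctuations,
inter-subject misalignment of pattern geometry, nonlinear HRF variation.
Passing tests therefore demonstrate correctness of the *pipeline
machinery* and its statistical calibration, not performance on real
recordings.

## Masks

A `Mask` is a boolean grid plus voxel-to-world affine; the canonical voxel
ordering (C-order over true voxels) defines pattern-vector layout
everywhere. Union/intersection require identical grids. Erosion is
iterated morphological erosion with selectable neighborhood — 6
(faces, the default: it has a crisp analytic oracle), 18, or 26 (the
3×3×3 box used by FSL); outputs state which was used, since the original
construction named the software but not the kernel. Outside-grid voxels
count as background. Left/right splitting assigns world `x ≤ 0` to the
left, exactly as printed, so voxel centers at `x = 0` go left. Random
subsampling to a target voxel count is uniform without replacement and
seed-reproducible. Resampling to a new voxel size maps each target voxel
center to its nearest source voxel (axis-aligned affines; the synthetic
grids never need oblique support).

## Preprocessing

The decoding path is: regress out the 6 motion parameters (per voxel, with
intercept; collinear columns dropped with a warning) → per-run linear
detrend and z-score (zero-variance voxels map to all-zero rather than NaN)
→ extract the peak volume of each stimulus → average per modality and run,
then across runs → optionally normalize each pattern across ROI voxels
(mean 0, SD 1), which removes overall-amplitude information and is
mandatory for cross-cohort transfer. Motion-before-detrend is the default
order (the source pipeline does not fully fix it); both orders are
supported via the `order` argument.

Volume indexing: volume *i* covers `[i·TR, (i+1)·TR)`; the *k*-th volume
after onset is `floor(onset/TR) + k` (with a 1 ns epsilon guarding exact
boundaries). The peak offset defaults to `round(6 s / TR)`: 2 volumes at
TR 3 s, 8 volumes at TR 0.8 s.

The first-level GLM regresses each voxel on HRF-convolved per-condition
stick functions, their temporal derivatives, the 6 motion parameters, an
intercept and a linear drift (the drift regressor stands in for high-pass
filtering, which is out of scope). Because generator and design builder
share one HRF, noise-free amplitude recovery is exact — a deliberate
property used by the tests. Rank-deficient designs raise an error naming
the collinear columns.

Head motion is summarized as mean framewise displacement (sum of absolute
backward differences of translations plus rotations × 50 mm) over the
stimulation windows of a modality.

## Matching

* **Subject counterbalancing** keeps all subjects of the minority sign of
  the per-subject rating difference plus an equal-sized majority-sign
  subset minimizing |sum of selected differences| (exhaustive to 20
  majority subjects, greedy beyond; ties → smaller variance, then lowest
  ids). Since the subgroup size is fixed, this is exactly the admissible
  subgroup with the smallest |mean difference|. Note that no admissible
  subgroup need beat the *full* cohort's |mean| in adversarial instances
  (e.g. one extreme minority subject); the tests assert optimality over
  admissible subgroups, which is the guarantee the procedure actually has.
* **Greedy trial matching** processes pain trials in descending rating
  order; each takes the closest unused touch trial within ±0.5 rating
  units (ties → lower trial id); unmatched pain trials are discarded. On
  continuous, overlapping rating distributions this ordering leaves a
  small positive pain-minus-touch residual (~0.13 rating units in the
  blocked cohort) because high-rated touch trials are consumed early; the
  assignment-based matcher (`match_trials_optimal`, maximum pairs then
  minimum total difference) is unbiased and is reported alongside as a
  sensitivity check. The greedy form remains the default because it is the
  documented procedure being reproduced.
* **Match certification**: two-tailed paired *t* plus the JZS Bayes factor
  BF01, computed by adaptive quadrature of the Jeffreys-Zellner-Siow
  integral (zero-centered Cauchy prior on standardized effect size).
  The prior scale defaults to **1.0** — this is the value under which the
  published matching Bayes factors reproduce from their printed (t, n);
  the now-common 0.707 default does not, and is available via parameter.

## Univariate ROI family

Per-ROI paired *t* across subjects; family-wise correction by the max-|t|
distribution over sign flips of the subject difference vectors (the
standard FWE-controlling choice; the source names neither pooling nor flip
scheme, so the implemented scheme is declared in the output metadata). All
2ⁿ flips are enumerated when 2ⁿ ≤ n_perm (giving exact discrete p-values,
e.g. ≥ 0.25 at n = 2); otherwise Monte Carlo with the (k+1)/(n+1)
estimator. Corrected p is floored at the parametric uncorrected p so the
monotonicity contract holds even in the discrete tail. ROIs whose
difference variance is zero (to a 1e-10 relative guard) are excluded from
the max statistic and flagged.

## Decoding

Classifier: soft-margin linear SVM, C = 1, bias term, no feature scaling
beyond the stated ROI normalization. All fits run on a precomputed linear
Gram matrix; when available, libsvm's solver is called directly (the
estimator-level validation around each fit would otherwise dominate the
permutation loops), and the test suite asserts prediction-level equality
with `sklearn.svm.SVC` on random instances as well as with an independent
quadratic-program reference on tiny instances.

* **LOSO**: one fold per subject; train on the rest, test on the held-out
  subject; overall accuracy is the mean fold accuracy; fold weight vectors
  are retained.
* **Permutation null**: per permutation, each fold's *training* labels are
  randomly permuted (class counts preserved; iid relabeling behind a
  flag), the model retrained and tested against the held-out subject's
  true labels; the mean fold accuracy is one null draw. p = (#null ≥
  observed)/n_perm, reported as "< 1/n_perm" when the count is zero (the
  (k+1)/(n+1) estimator is available but non-default, matching the
  reporting convention being reproduced).
* **Sensitivity maps**: mean of fold weight vectors mapped back to ROI
  voxels; positive = higher signal for the first-named (pain) class.
  Fold-mean is chosen over a full-data refit for determinism and zero
  leakage. Consistent-sign maps keep voxels whose sign agrees across all
  input maps, valued at the across-map mean.
* **Median split**: pooled sort of rated samples; strictly above the
  pooled median → "high", at-or-below → "low" (ties to low, a fixed
  convention). Per-modality balancing keeps min(high, low) samples per
  modality, removing from the larger class the samples nearest the
  boundary (lowest-rated from high, highest-rated from low). The blocked
  variant discards participants whose trials all fall in one class, then
  averages per modality × participant × class.
* **Cross-cohort transfer** trains one model on an entire cohort and tests
  on the other; both sides must be ROI-normalized (scanner amplitude
  scales do not transfer), enforced as a hard error.

## Problem sizes and numerical choices

Calibration and recovery experiments run on a 14×13×13 grid of 3 mm voxels
(506-voxel ROI), 12 subjects, one run of 4 stimuli per modality — small
enough to repeat hundreds of times, large enough for every stage to behave
generically. The chance-level baseline uses 200 signal-free replicates;
null-calibration additionally uses 200-permutation nulls per replicate.
Signal-recovery experiments inject a pain-specific cluster at
amplitude/noise = 5. The analysis drivers run the full cohort sizes
(14 and 51 subjects) with 5000-permutation nulls; the 51-subject blocked
cohort is generated and preprocessed one subject at a time so volumes
never accumulate in memory.

Quadrature failures in the Bayes factor raise rather than return garbage;
the trapezoid cross-check in the tests agrees to 1e-4 relative. Erosion,
resampling and subsampling preserve grid shape and affine. All randomness
flows through `numpy` `SeedSequence`s spawned from a single seed, so every
dataset, null distribution and map is bit-reproducible.

## Known limitations

* Noise is spatially independent; spatially smooth noise would make
  sensitivity maps noisier than observed here.
* Pattern geometry is identical across subjects; real between-subject
  decoding also fights anatomical misalignment.
* The GLM shares its HRF with the generator, so beta recovery is
  optimistic relative to real HRF variability.
* The high/low (intensity/saliency) decoding depends on the shared-pattern
  amplitude (default 0.08 signal units per rating unit); in the
  event-related cohort's 44-sample regime that default is below the
  detection threshold, which the drivers report as-is — mirroring the
  general observation that intensity decoding is harder than modality
  decoding — rather than the generator being adjusted to force a positive
  result.
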