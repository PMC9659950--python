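# Methods

This note documents the models, parameter choices and numerical decisions
behind `rehoflow`, and what the synthetic-data experiments do and do not show.

## Regional homogeneity

ReHo at a voxel is Kendall's coefficient of concordance *W* over the ranked
time series of the voxel and its in-mask neighbors (27-voxel cubic
neighborhood by default; 7- and 19-voxel variants available). The statistic is
computed with the plain concordance formula, without a tie correction:
continuous BOLD series have ties only through floating-point coincidence, and
the midrank assignment handles those exactly. A `tie_correction` flag on
`kendall_w` provides the corrected denominator for genuinely discrete data.
Vectorization: ranks are assigned by one sort per voxel with tie runs averaged
via running extrema (bit-identical to average-method ranking, asserted against
`scipy.stats.rankdata`), and the 27-neighborhood rank sums are three
separable box filters. The vectorized map is tested to 1e-12 against a
per-voxel brute-force loop.

Edge policy: neighborhoods are restricted to the mask; voxels with fewer than
7 in-mask members are zeroed and removed from the map's mask, which keeps *W*
defined while retaining near-complete coverage at the mask boundary.

Map normalization follows the common szReHo convention: divide by the in-mask
global mean, smooth (6 mm FWHM), then z-standardize within the mask. *W* is
not a correlation coefficient, so an `atanh` transform of the raw map is
offered only as an explicit alternative (`atanh_transform`), not the default.

A consequence of global-mean division and z-standardization worth knowing: a
genuine group difference confined to one region slightly shifts the rest of
the map in the opposite direction (the normalizers are computed per subject).
Where between-subject variance is very small — the synthetic WM/CSF blocks are
the extreme case — this offset can itself reach significance. The recovery
analyses therefore score the planted region by the best-overlap Dice rather
than by counting clusters.

## Preprocessing

Stage order: discard the first 10 volumes → motion QC → ideal (rectangular
frequency-domain) band-pass 0.01–0.08 Hz with the temporal mean removed →
linear nuisance regression. The confounds (Friston-24 motion expansion plus WM
and CSF mean signals, 26 columns) are band-passed with the same filter before
regression so the residuals cannot reacquire out-of-band nuisance energy; the
rank check applies to the confounds as provided, while the band-limited design
is solved by SVD least squares (band-limiting legitimately lowers rank when
the series is short). Smoothing is applied to mReHo maps (before
z-standardization) and, by default, to the FC input data — whether FC should
use smoothed input is a convention choice, so a toggle (`fc_on_smoothed`) is
provided.

Framewise displacement uses the Power formulation (sum of absolute backward
differences, rotations scaled by a 50 mm head radius; radius configurable).
The exclusion rule is subject-level: mean FD above the cohort mean + 2.5 SD.
Per-volume scrubbing is deliberately not implemented.

## Synthetic cohorts

The generator emulates a two-group resting-state acquisition: 240 volumes at
TR = 2 s on a 24³ grid of 3 mm voxels, groups of 48 and 47 subjects by
default, inside a spherical brain mask. Each voxel's series mixes:

* spatially smoothed (4 mm FWHM) AR(1) noise (φ = 0.3) — resting BOLD has
  temporal autocorrelation and intrinsic spatial smoothness;
* a shared local latent AR(1) signal in designated regions with weight
  √s, where the shared-variance fraction s (default 0.5 in group 2) is the
  quantity Kendall's W responds to; the group effect multiplies s by
  (1 − synchrony_drop) in group 1;
* a seed→target coupling: target voxels are r·g + √(1−r²)·residual with g the
  seed latent, so the planted voxelwise correlation equals r exactly
  (defaults r = 0.6 in group 2 vs 0.2 in group 1);
* linear drift, leakage of the subject's own motion trace through smooth
  spatial patterns, and WM/CSF-like global components — all of which the
  preprocessing stage is expected to remove;
* a baseline of 100 arbitrary units.

Motion traces are smoothed random walks, zero at t = 0, linear in their
amplitude parameter (so mean FD scales proportionally). Clinical covariates
are truncated-Gaussian draws at the reference cohort's per-group means and SDs
(AHI floored at 15 events/h to match the severe-OSA inclusion criterion; SaO₂
and percentage variables truncated to [0, 100]); variables are drawn
independently because only marginal summaries are available. MoCA scores are
drawn truncated at the diagnostic cutoff so group labels are consistent with
the score that defines them. Respiratory traces are an amplitude-modulated
0.25 Hz breathing oscillation with Poisson-planted events (apneas at 95 %
amplitude reduction, hypopneas at 50 % with a lagged SpO₂ dip of ≥ 4.5 %),
2 s raised-cosine ramps, and non-overlapping placement (events that cannot be
placed are dropped — Poisson thinning).

What the generator does **not** model: scanner physics and artifacts,
physiological (cardiac/respiratory) BOLD components, realistic anatomy or
tissue geometry, distance-dependent motion artifacts, and any covariance
between clinical variables. Passing tests demonstrate internal correctness and
statistical calibration of the pipeline, not performance on real MRI data.

## Group inference

Voxelwise pooled-variance two-sample t (Welch available), contrast group 1 −
group 2. Smoothness is estimated from the standardized residuals of the group
model: per axis, the variance of spatial first differences gives the lag-1
autocorrelation ρ, inverted through the Gaussian autocorrelation model
σ² = −1/(4 ln ρ); the FWHM is floored at one voxel, where a discrete field
carries no resolvable smoothness. Resel counts use the standard lattice
formula (points/edges/faces/cubes of the mask).

Cluster-level p follows the classical formulation: the t-field is thresholded
at the voxel-level quantile (two-tailed by default, voxel p split evenly over
the tails; one-tailed flags available), the threshold is mapped to a Gaussian
height u by probability transform, and for a cluster of k voxels

    p = 1 − exp( − m · E[m] · exp(−β k_r^{2/3}) ),

with E[m] the expected cluster count (EC densities × resel counts), k_r the
extent in resels, β from the expected cluster size, and m the number of tails
searched. Clusters with p below 0.05 survive.

Calibration. On a 24³ lattice the continuum approximations are only
approximate. Monte-Carlo nulls (Gaussian noise fields, two groups of 10,
voxel p = 0.005) put the realized family-wise error of this implementation at
≈ 0.026 at the pipeline's operating smoothness (measured at ~2.75 voxels FWHM
on synthetic szReHo cohorts: 4 mm intrinsic noise smoothness, the 27-voxel
ReHo neighborhood, and the 6 mm kernel) — mildly conservative, and degrading
toward ≈ 0.01 when the field smoothness falls to 2 voxels. The variant using
t-field EC densities in place of Gaussianization was evaluated and found
anticonservative on this lattice (FWE ≈ 0.09); the Gaussianized form is kept.
A nonparametric fallback (`permutation_cluster_threshold`) assigns cluster
FWE p-values from the max-extent distribution over group-label permutations
at the same cluster-forming threshold, for settings where the lattice
assumptions of the parametric correction are in doubt.

## Classification

Features are per-subject means of szReHo over each significant ReHo cluster
and of z-FC over each significant FC cluster. Collinearity pruning removes,
for the worst offending pair above |r| = 0.75, the feature with the larger
mean absolute correlation to all others (ties drop the later column), until no
pair exceeds the threshold. The classifier is standardized L2 logistic
regression; the regularization strength is grid-searched (default 7 points,
log-spaced over 10⁻²…10¹) by leave-one-out accuracy with ties broken toward
stronger regularization.

Feature selection here happens on whole-sample group differences *before*
cross-validation — the design being reproduced is circular in this respect,
and the LOOCV estimates are therefore optimistic for real data. An `honest`
mode nests pruning and grid search inside every LOOCV fold; nesting the
cluster selection itself would require re-running the imaging stage per fold
and is out of scope.

The permutation test re-runs the full prune + grid-search + LOOCV procedure on
shuffled labels, p = (1 + #{permuted ≥ observed}) / (B + 1), statistic LOOCV
accuracy by default (AUC available). The inner loops use a compact
Newton-IRLS solver for the identical L2 objective (agreement with
scikit-learn asserted to 1e-6 in the tests); the user-facing estimator
delegates to scikit-learn. Calibration tests use a single-point grid inside
permutations to keep tens of thousands of refits tractable.

LOOCV quirk worth knowing: under the null, held-out scores are anti-correlated
with the left-out label, so null LOOCV AUC falls well below 0.5. The
two-Gaussian benchmark (expected AUC Φ(d/√2)) is therefore asserted at d = 1
and d = 2, and only as "at or below chance" at d = 0.

## Clinical statistics

Sample size for a two-sample two-tailed t-test is the smallest n per group
whose noncentral-t power reaches the target (d = 0.8, α = 0.05, power = 0.8
gives 26/group, 52 total). Normality testing defaults to the Lilliefors
variant (parameters estimated from the sample, as SPSS-style workflows do; the
plain KS with plug-in parameters is behind a flag). Group comparisons use the
pooled t for variables passing normality in both groups and the asymptotic
tie-corrected Mann–Whitney U otherwise. Whether the reference analysis pooled
variances is not stated; pooled is the default because it reproduces the
reference Age and AHI p-values (0.100, 0.349), with Welch behind a flag.

AHI severity bands are half-open ([5, 15), [15, 30), [30, ∞)), resolving the
overlapping printed boundaries by the scoring-manual convention. The event
scorer uses a Hilbert amplitude envelope against a record-wide median baseline
(valid while events occupy a minority of the record), a 10 s minimum duration,
a 90 % reduction bound for apneas and a 30 % bound plus ≥ 4 % desaturation
within a 30 s lag window for hypopneas (the lag window is a choice; nothing in
the defining rules fixes it).

## Problem sizes of the heavy checks

Chosen to exercise each property at meaningful scale on one CPU: GRF null
calibration, 200–400 cohorts of 2×10 maps on 24³ (the 400-cohort test run
halves the Monte-Carlo error of the rate estimate); permutation-test null, 50
replicates at B = 99 with a single-point grid; planted-effect recovery, 20
cohorts of 2×20 subjects, 240 volumes, 24³ grid, synchrony drop 0.8 and
coupling 0.6 vs 0.2; two-Gaussian classifier, 12 replicates of 48 + 47
subjects.

## Known limitations

* GRF cluster correction is conservative on coarse lattices (see above); at
  FWHM ≈ 2 voxels the realized FWE is ~0.01 at nominal 0.05.
* The full-pipeline FC example values (e.g. group z-difference equal to
  atanh differences of planted couplings) hold exactly only on unsmoothed
  input; smoothing attenuates edge voxels of the target region.
* The synthetic respiratory scorer and generator share event definitions;
  recovery rates measure implementation consistency, not clinical scoring
  performance.
* Clinical covariates are independent by construction; any analysis of their
  joint structure on synthetic tables is uninformative.
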