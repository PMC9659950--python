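# rehoflow

Resting-state fMRI analysis of **regional homogeneity (ReHo)** and **seed-based
functional connectivity (FC)**, built to study how obstructive sleep apnea (OSA)
patients *with* mild cognitive impairment (MoCA < 26) differ from OSA patients
*without* it. The package implements the complete analysis as a tested,
reusable pipeline — from 4D BOLD volumes to group cluster statistics and a
validated classifier — together with a synthetic-cohort generator with known
ground truth, so every stage can be exercised and calibrated without access to
clinical MRI data.

Intended users: neuroimaging researchers and methodologists who want a
transparent, scriptable implementation of this analysis family (the kind of
workflow usually run through DPABI/SPM) with explicit statistical calibration.

## The methods

**ReHo.** For each voxel, Kendall's coefficient of concordance *W* is computed
over the ranked time series of the voxel and its 26 neighbors. With K series
of length n, R_i the total rank at timepoint i and R̄ = K(n+1)/2,

    W = 12 ( Σ_i R_i² − n R̄² ) / ( K² (n³ − n) )

W ∈ [0, 1]; W = 1 for perfectly concordant rankings, E[W] = 1/K for
independent series. Maps are divided by the in-mask global mean (mReHo),
smoothed with a 6 mm FWHM Gaussian and z-standardized (szReHo).

**Preprocessing.** Discard of the first 10 volumes; framewise displacement
(Power formulation, 50 mm rotation radius) with subject exclusion at mean FD >
cohort mean + 2.5 SD; ideal frequency-domain band-pass 0.01–0.08 Hz; linear
regression of the Friston-24 motion expansion plus WM and CSF mean signals
(confounds band-passed with the same filter).

**Seed-based FC.** Significant ReHo clusters define ROIs; each ROI's mean time
series is correlated with every voxel (Pearson), and maps are transformed with
Fisher's z = atanh(r) before group testing.

**Group inference.** Voxelwise pooled-variance two-sample t-tests with
Gaussian-random-field cluster-level correction (voxel p < 0.005 two-tailed,
cluster p < 0.05): field smoothness estimated from standardized group
residuals, resel counts on the mask lattice, expected cluster counts from
Euler-characteristic densities and the classical cluster-extent approximation.

**Classification.** Cluster-mean szReHo and z-FC features; collinearity
pruning at |r| > 0.75 (dropping the member with the larger mean absolute
correlation); L2 logistic regression with grid-searched regularization;
leave-one-out cross-validation; label-permutation test for the whole
procedure. Reports AUC, accuracy, sensitivity, specificity, Cohen's kappa.

**Clinical statistics.** Noncentral-t power analysis, Lilliefors/KS normality
testing, pooled t and Mann–Whitney U group comparisons, Pearson correlation
tests, Bonferroni adjustment, MoCA grouping at the < 26 cutoff, and
apnea–hypopnea scoring of airflow/SpO₂ traces (apnea: ≥ 90 % airflow reduction
≥ 10 s; hypopnea: ≥ 30 % reduction ≥ 10 s with ≥ 4 % desaturation) with AHI
severity bands.

## Worked example

```python
import numpy as np
from rehoflow import synthetic
from rehoflow.pipeline import AnalysisParams, analyze_cohort, dice

# two groups of 20 subjects, 240 volumes at TR = 2 s on a 24^3 grid (3 mm);
# group 1 loses 80% of local synchrony in a 125-voxel cube, and its
# seed-target coupling drops from r = 0.6 to r = 0.2
cube = np.zeros((24, 24, 24), bool)
cube[6:11, 6:11, 6:11] = True
spec = synthetic.CohortSpec(n_group1=20, n_group2=20, rng_seed=7000,
                            effect_regions=[synthetic.EffectRegion(cube, 0.8)])
volumes, motions, clinical_table, truth = synthetic.generate_cohort(spec)

res = analyze_cohort(volumes, motions, truth.labels,
                     AnalysisParams(run_classifier=False),
                     clinical_table=clinical_table)
best = max(res.reho_clusters, key=lambda c: dice(c.mask(spec.grid_shape), cube))
print(f"ReHo clusters: {len(res.reho_clusters)}")
print(f"best cluster: extent {best.extent} voxels, peak t {best.peak_stat:.2f}, "
      f"cluster p {best.p_cluster:.2g}, Dice vs truth "
      f"{dice(best.mask(spec.grid_shape), cube):.2f}")
print(f"FC clusters per ROI: { {k: len(v) for k, v in res.fc_clusters.items()} }")
```

Output from this exact script:

```
ReHo clusters: 5
best cluster: extent 203 voxels, peak t -26.93, cluster p 5.9e-10, Dice vs truth 0.76
FC clusters per ROI: {'reho_c1': 6, 'reho_c2': 4, 'reho_c3': 0, 'reho_c4': 0, 'reho_c5': 0}
```

The planted cube is recovered as a negative-t cluster (group 1 below group 2,
Dice 0.76); the coupling target appears among the FC clusters of the first two
ROIs. The extra ReHo clusters are the global-normalization side effect
discussed in `docs/methods.md`.

The same pipeline is available from the shell:

```bash
rehoflow simulate --seed 42 --out cohort/
rehoflow run --config run.yaml --seed 42 --out results/
rehoflow clinstats --table cohort/clinical.tsv --out stats.csv
```

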