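# tremornet

A tested, reusable pipeline for resting-state fMRI "discoordination"
analysis: locating abnormally connected brain sites with voxel-wise
**weighted degree centrality (WDC)**, tracing their connections with
**seed-based Fisher-z functional connectivity**, characterising the
resulting ROI network with **sparsity-swept weighted efficiency**
against degree-preserving null models, and quantifying group
differences, brain–behaviour coupling, and diagnostic power with
**permutation statistics, FDR, partial Spearman correlation, and ROC
analysis**.

The intended users are neuroimaging methodologists studying small
case-control cohorts (the motivating regime is tremor-dominant
Parkinson's disease: 16 patients vs 20 controls, 180 BOLD volumes at
TR = 2 s, 0.01–0.1 Hz). Because such patient data are rarely deposited,
the package includes a first-class **synthetic cohort generator** with
planted ground truth — region covariance, a patient-group connectivity
increment, hub voxels, bounded motion, and clinical scores coupled to
connectivity strength — so every stage of the pipeline has a
recoverable target.

## The statistics at the core

For grey-matter voxel *i* with *N* mask voxels, centrality is the
positive thresholded correlation sum

    S_i = Σ_{j≠i} r_ij,   keeping r_ij ≥ r_crit (Bonferroni P < 0.05),

with negative correlations excluded. ROI networks are thresholded at
sparsity *s* ∈ {0.08, 0.10, …, 0.60} (strongest positive correlations
kept as weights), and each weighted graph *G* is summarised by

    E_glob(G) = 1/(N(N−1)) Σ_{i≠j} 1/d_ij,
    E_loc(G)  = 1/N Σ_i E_glob(G_i),

where d_ij is the shortest path under edge length 1/weight and G_i is
node *i*'s neighbour-induced subgraph. Curves are normalised by the
mean of 100 Maslov–Sneppen degree-preserving surrogates (small-world:
normalised E_loc > 1 with normalised E_glob ≈ 1) and reduced to
trapezoidal AUCs, which are compared between groups by covariate-aware
(Freedman–Lane) permutation tests with Benjamini–Hochberg correction
across sparsities. See `docs/methods.md` for the full model, defaults,
and conventions.

## Worked example

Simulate a study-sized cohort (16 patient-analogs vs 20 controls,
180 volumes), compute each subject's global-efficiency AUC over the
sparsity grid, and test the planted group difference:

```python
import numpy as np
from tremornet import (SyntheticConfig, generate_cohort, roi_correlation_matrix,
                       efficiency_curve, permutation_test_metric, roc_analysis)

cfg = SyntheticConfig(grid_shape=(8, 8, 8), seed=42)
runs, truth = generate_cohort(cfg)
labels = truth.region_labels

aucs = []
for run in runs:
    series = np.vstack([run.data[labels == k].mean(axis=0)
                        for k in range(cfg.n_regions)])
    curve = efficiency_curve(roi_correlation_matrix(series), n_null=0)
    aucs.append(curve.auc_glob)

aucs = np.array(aucs)
is_pat = truth.group_labels == 1
p = permutation_test_metric(aucs[~is_pat], aucs[is_pat], n_perm=9999, seed=0)
roc = roc_analysis(aucs[is_pat], aucs[~is_pat], n_boot=2000, seed=0)
```

Output:

```
control mean E_glob AUC: 0.1072
patient mean E_glob AUC: 0.1383
permutation p (10,000 permutations): 0.0001
ROC AUC: 0.922  95% CI (0.822, 0.991)
sensitivity 81.2%  specificity 90.0%
```

The planted covariance increment (+0.15 correlation in the
patient-analog group) raises the patients' efficiency AUC, the
permutation test detects it at its minimum attainable p, and the AUC
score separates the groups with high — but not perfect — diagnostic
accuracy, as expected at these sample sizes.

The same analysis runs end to end from the shell, writing NIfTI maps,
motion text files, TSV tables, and a run log:

```sh
tremornet pipeline --out run1 --seed 42
```

Individual stages are also exposed (`tremornet simulate | preproc |
wdc | seedfc | neteff | roc`); run `tremornet --help`.

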