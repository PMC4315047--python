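# Methods

`tremornet` implements a resting-state fMRI "discoordination" analysis
of the kind used to characterise tremor-dominant Parkinson's disease
against healthy controls: voxel-level weighted degree centrality to
locate abnormally connected sites, seed-based connectivity to trace
where those sites link, weighted graph efficiency of the resulting ROI
network, and group statistics, brain–behaviour correlation, and ROC
discrimination on top. Because no patient data of this kind are
publicly deposited, the package is driven by a synthetic cohort
generator with known ground truth; every downstream stage therefore has
a recoverable target.

## Synthetic cohort model

Each subject carries a latent connectivity strength `c_s`: 0 for
control-analog subjects, `|Normal(1, latent_sd)|` (default
`latent_sd = 0.2`) for patient-analogs. Region signals are drawn from a
multivariate normal with covariance

    Sigma_s = base_cov + c_s * effect_delta,

broadcast to all voxels of the region, and perturbed by independent
Gaussian voxel noise (`noise_sd = 1`). Both the latents and the voxel
noise are shaped by the same ideal band-pass filter used in
preprocessing and rescaled to preserve variance, so generated series
are band-limited (0.01–0.1 Hz at TR = 2 s) and realised region-level
correlations stay at their nominal values (filtering independent
streams preserves independence). Defaults emulate the emulated study
regime: 20 controls vs 16 patients, 180 volumes, a 12×12×12 grid of
3-mm voxels partitioned into 8 rectangular blocks with within-cohort
correlation 0.3.

The patient-group increment defaults to +0.15 on every off-diagonal
covariance. The literature this design emulates reports no effect-size
estimates for its group differences, so this is a free parameter of the
generator, chosen once as a moderate-to-large connectivity increment
that a 16-vs-20 design can detect; it is deliberately not tuned to any
reported statistic.

Hub voxels (default: the grid centre) carry the standardised mean of
all region latents with reduced noise (`hub_noise_sd = 0.3`), which
makes them the strongest correlation aggregators on the grid — the
ground truth for centrality recovery.

Motion traces are bounded reflecting random walks (3 translations in
mm, 3 rotations in radians, SPM `rp_*.txt` column order), with default
step sizes keeping every subject far inside the conventional
3 mm / 3° exclusion limits. Clinical scores are affine functions of
`c_s` plus noise, clipped to plausible ranges (tremor item 1–4,
Hoehn–Yahr 1–3, UPDRS 4–49, duration 0.42–6 y); controls carry missing
(NA) disease scores, matching the "–" convention of clinical tables.
`slope_for_correlation` converts a target score–latent correlation into
a slope. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawn keys (separate streams for latents,
noise, motion, clinical scores, demographics), so identical configs are
bit-identical.

What the generator does **not** emulate: scanner artefacts,
physiological noise, spatial autocorrelation beyond block structure,
anatomically realistic geometry, or genuine haemodynamics. Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under a controlled regime, not performance on real data.

## Preprocessing

Temporal cleaning follows a fixed, logged order: drop the first 5
volumes (configurable) → per-voxel linear detrend → band-pass →
nuisance regression. The default band-pass is an ideal spectral
projection (rfft bins outside 0.01–0.1 Hz zeroed), matching the
rectangular-band convention of the common resting-state toolboxes; it
is exactly idempotent. The composite detrend+band-pass is only
approximately idempotent (re-fitting a line to a band-limited series
moves it by ~1% rms at 180 volumes), which the test suite asserts at a
5% tolerance. A zero-phase Butterworth is available as an option.
Nuisance regression projects each voxel series onto the orthogonal
complement of intercept + Friston-24 motion expansion (6 parameters,
their one-volume lag, both squared) + mean WM and CSF series; collinear
columns are dropped with a warning. No spatial smoothing is offered at
this stage: smoothing before voxel-level centrality induces spurious
local correlations.

Motion summaries: `max_disp` and `rms_disp` are the max/RMS of the
per-volume translation norm; `mean_fd` is Power-style frame-wise
displacement — the mean of summed absolute backward differences of the
6 parameters, rotations converted to arc length on a 50-mm sphere. The
FD formula and the rotation convention are not standardised across
toolboxes; both are explicit, documented decisions here.

## Weighted degree centrality

For grey-matter voxel i, `S_i = sum_{j != i} r_ij` over positive
correlations surviving a Bonferroni-corrected floor; sub-threshold and
negative values contribute 0 (negative resting-state correlations have
ambiguous interpretation and poor test–retest reliability). The floor
is the r whose two-sided Pearson p (t transform, df = T − 2) equals
`alpha / n_tests`. The Bonferroni denominator defaults to N − 1 tests
per seed voxel, matching the per-row framing of the centrality sum; the
whole-brain pairwise total N(N−1)/2 is available via
`bonferroni_scope="pairwise"`. The correlation matrix is processed in
row blocks (default 1024), so memory stays bounded; block results are
bit-identical to the naive full-matrix computation. Constant voxels
are removed from the mask with a warning. Grey matter is expected as a
probability map thresholded at 0.2 when run from the CLI.

## Seed-based connectivity

Seeds are spheres (default radius 6 mm) around peak coordinates, taken
centre-to-centre in mm via the image affine: a voxel belongs to the ROI
when its centre lies within the radius. The ROI's unweighted mean
series is Pearson-correlated with every in-mask voxel and transformed
with Fisher's z = arctanh(r); r is clipped to ±(1 − 1e-7) first so z is
finite even at numerically perfect correlation, and constant voxels get
z = 0 with a flagged count. Overlapping ROIs are resolved greedily:
walking the list in order, any ROI sharing a voxel with an earlier kept
ROI is dropped (the drop rule for overlap is a convention; it is logged).

## Network efficiency

Per subject, the ROI × ROI Pearson matrix is thresholded over the
sparsity grid 0.08–0.60 in steps of 0.02 (27 points): the
`round(s·N(N−1)/2)` strongest positive correlations are kept as
weighted edges, ties broken by lexicographic node-pair order, so edge
sets are nested across the grid and results are deterministic. If fewer
positive correlations exist than requested, all positives are kept and
the achieved sparsity recorded.

Edge length is the reciprocal of the weight (high correlation = short
functional distance). Weighted global efficiency is the mean of
`1/d_ij` over ordered pairs, with disconnected pairs contributing 0;
local efficiency is the mean over nodes of the global efficiency of the
neighbour-induced subgraph (original weights; nodes with < 2 neighbours
contribute 0). Shortest paths are computed by a dense Floyd–Warshall in
numpy — exact for non-negative lengths and faster than per-call sparse
solvers at the 8–50-node scale used here; it is verified against
exhaustive simple-path enumeration in the tests.

Null normalisation uses Maslov–Sneppen double-edge swaps: 100
surrogates (the swap count per edge defaults to 10 accepted swaps,
seed-controlled), each preserving node count, edge count, and the full
binary degree sequence exactly, with weights travelling on their edges
so the weight multiset is also preserved. Graphs with no two
node-disjoint edges admit no swap; their degree-preserving ensemble is
the graph itself and is treated as such. The small-world flag requires
normalised local efficiency > 1 and normalised global efficiency within
0.2 of 1 on at least half of the valid grid points (both thresholds
configurable). Curves are summarised by trapezoidal AUC over the grid.

Weights are raw correlations rather than Fisher-z values, matching the
"edge weight = correlation coefficient" convention.

## Group statistics

Voxel maps: per-voxel GLM of map value on group + covariates (gender,
age, three motion summaries; optionally per-voxel grey-matter volume
entered voxel-wise), t for the group coefficient, two-sided p with
residual df. Cluster-extent correction simulates null Gaussian maps on
the mask (optionally smoothed to match residual smoothness and
re-standardised), thresholds them at the height p (default uncorrected
p < 0.01 — a documented default, since height thresholds are rarely
stated explicitly in this literature), and takes the 1 − alpha quantile
of the max 26-connected cluster size as the extent cutoff.

Scalar metrics: Freedman–Lane permutation test — residualise the metric
on intercept + covariates, permute residuals, statistic = difference of
adjusted group means, p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)
(default 10,000 permutations). Per-sparsity p-values are corrected by
Benjamini–Hochberg across the 27 grid points. Brain–behaviour coupling
uses partial Spearman correlation (rank-transform x, y, and the
covariates, residualise, Pearson on residuals; t-approximate p with
df = n − k − 2). ROC analysis sweeps all distinct score thresholds
(score ≥ threshold ⇒ patient), computes AUC by the Mann–Whitney
identity, reports the Youden-optimal operating point with sensitivity
and specificity rounded to one decimal percent, and can add a
percentile-bootstrap 95% CI (default 2000 replicates) for the AUC.

## Problem sizes and numerical choices

The bundled end-to-end run uses the 12×12×12 grid at 180 volumes with
100 nulls and completes in a few minutes on one CPU; calibration and
recovery experiments in the test suite use 8×8×8 grids, 100 cohorts,
and 199–999 permutations per test — sizes chosen so the full suite is
exact where exactness is claimed (1e-10–1e-12 tolerances against
enumeration oracles) and statistically well-powered where claims are
distributional. Degenerate inputs have explicit conventions: edgeless
graphs have efficiency 0, constant metrics give permutation p = 1 with
a warning, correlation r is clipped before arctanh, and an underflowing
Bonferroni level returns a floor of 1.0 with a warning.

## Known limitations

- The generator's block-structured covariance has no spatial smoothness
  within regions, so cluster-extent correction is exercised mainly by
  its own null simulations rather than by realistic spatial noise.
- Sensitivity/specificity conventions (score orientation, tie handling
  at thresholds) follow the patient-positive, score-≥-threshold rule;
  scores oriented the other way should be negated by the caller.
- The Monte-Carlo extent correction models residual smoothness with a
  single isotropic Gaussian kernel estimate; anisotropic smoothness is
  out of scope.
- Anatomical ROI shapes, slice timing, realignment, spatial
  normalisation, and voxel-based morphometry itself are out of scope;
  grey-matter volume maps are consumed only as covariates.
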