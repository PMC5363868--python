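# Methods

## Analysis model

The pipeline treats each subject as a pair of measurements over ten
subcortical regions (thalamus, putamen, hippocampus, caudate, amygdala;
left and right): a regional volume in cc, and an eigenvector-centrality
value computed from a whole-brain functional network. The scientific
questions are (1) which regions differ between NC, MCI and AD, per modality;
(2) how well the significant regions jointly discriminate the three groups;
and (3) what each group's regional profile ("connectional fingerprint")
looks like as a whole.

### Preprocessing (ROI level)

Order is fixed: discard the first k volumes (default 4, pre-equilibrium
scans) → ordinary least-squares residualization against an orthonormalized
polynomial time basis (default cubic) plus any user-supplied nuisance columns
(e.g. white-matter/CSF means, motion parameters) → zero-phase band-pass.
The filter is a forward–backward Butterworth, order 2 per pass (effective 4),
passband 0.009–0.08 Hz by default; zero phase is chosen because phase
distortion would perturb inter-ROI correlations, the only downstream
consumer. The polynomial and nuisance regressors are fit jointly; a
rank-deficient design falls back to the minimum-norm solution with a
warning rather than failing, since duplicated nuisance columns are a common
user input.

### Networks

Edges are Pearson correlations, Fisher-transformed (atanh) for variance
stabilization. Binarization keeps the k = round(s·R(R−1)/2) largest-z
upper-triangle entries. Ranking is by **signed** z by default — strong
negative correlations are excluded — with an `absolute` switch, since
conventions differ across studies; ties break toward the lexicographically
smaller index pair so results are exactly reproducible. Because atanh is
strictly increasing, thresholding z or r gives identical networks (asserted
in tests).

The analysis sparsity is recomputed per cohort as the smallest value on the
1–50% grid (1% steps) at which every subject's network is one connected
component; a forced sparsity is accepted for replication runs. Edges are
added in a fixed rank order, so per-subject connectivity is monotone in s
and the cohort answer is the maximum of per-subject minima; the
implementation exploits this only for early termination, and an acceptance
test checks it against a brute-force grid scan.

### Centrality

Eigenvector centrality is the principal eigenvector of the binary adjacency
matrix, computed by dense symmetric eigendecomposition up to 512 nodes
(exact at atlas scale) and by power iteration (tol 1e−10, ≤ 10,000
iterations) beyond. The vector is sign-fixed non-negative and normalized to
**unit Euclidean norm**; a `max_one` normalization is available. Unit norm is
a reasoned default — typical published per-region values (~0.02–0.08 over
90 regions) are consistent with it — not an externally fixed convention.
Disconnected graphs are refused with the component count: the Perron vector
is not well defined across components, and in-pipeline the sparsity search
guarantees connectivity. Every returned eigenpair must satisfy
max|Ax − λx| < 1e−8 or the solver raises.

### Permutation inference

The statistic is the absolute difference of group means (a Welch-t variant is
configurable; the mean difference is the minimal reading of a
"null-distribution of group differences" design). Each of B permutations
(default 5000) reassigns all subjects to the three groups with original
sizes, and all pairwise statistics are recomputed from the pseudo-groups —
a single whole-cohort relabelling scheme shared by the three comparisons.
Correction is Westfall–Young maxT across the ten regions within each
(modality, comparison) family, the canonical permutation-based family-wise
device; `correction="none"` gives per-region uncorrected p. The estimator
(1 + count)/(1 + B) includes the observed statistic, so p ∈ [1/(B+1), 1].

Feature selection keeps regions with corrected p < α (default 0.05) in at
least two of the three comparisons, pooling volume and centrality features
into one list.

### Classification

A random forest (500 trees, √p features per split, unlimited depth, no class
weighting — library-conventional defaults, echoed in the result metadata)
is evaluated by leave-one-out cross-validation with per-fold seed
substreams. By default feature selection happens once on the full sample,
replicating the common (leaky) published practice; `nested_selection=True`
re-runs the permutation-test selection inside every training fold for a
leakage-free estimate. The analytic baseline for c balanced classes is
100/c percent.

### Fingerprints

Per group and region: mean and a 95% Student-t interval on the mean
(mean ± t₀.₉₇₅,ₙ₋₁·SD/√n; the t-interval is the standard small-sample choice
where the interval construction is otherwise unspecified). The radar area is
(1/2)·sin(2π/k)·Σ mᵢmᵢ₊₁ over the canonical region order (thalamus L/R,
putamen L/R, hippocampus L/R, caudate L/R, amygdala L/R). The area is
homogeneous of degree 2, invariant under cyclic rotation of the order (not
arbitrary permutation — hence the fixed canonical order), and strictly
monotone under elementwise dominance, which is what licenses reading a
shrinking area as global degeneration.

## Synthetic cohort generator

The generator defines the study conditions: 35/40/30 subjects, 90 ROIs,
140 time points at TR = 3 s. Time series are temporally white zero-mean
multivariate normal draws; Pearson correlation is the only consumer, so
temporal autocorrelation adds nothing the analysis can see (band-limited
series can be produced by applying the band-pass post hoc). The base
correlation structure is a two-level community model — ROI i belongs to
community i mod 6, correlation 0.45 within and 0.10 between communities —
chosen as the simplest structure that yields connected thresholded graphs
with non-trivial hubs; it is PSD by construction. Volumes are independent
normals per region (the analysis treats regions marginally), truncated at a
0.1 cc floor, with group-specific means/SDs defaulting to typical published
NC/MCI/AD subcortical statistics (e.g. NC hippocampus L 4.66 (0.68) cc).

Planted effects scale a target ROI's covariance row/column (hub weakening or
strengthening) or shift a group's mean volume. The default effect set encodes
the qualitative disease pattern — hippocampus-L connectivity weakening in MCI
(×0.70) and AD (×0.55), putamen-L (×0.60), thalamus-L and caudate-L (×0.70)
weakening in AD — so the default pipeline exercises a realistic
mixed-signal regime. Hub scaling can break positive semidefiniteness; the
matrix is then repaired by alternating projection onto the PSD cone and the
unit-diagonal set (eigenvalue clipping at 0, diagonal reset), run to a
−1e−12 smallest-eigenvalue stop with a 500-iteration cap — a 100-iteration
cap proved insufficient for strong strengthening effects to reach the
−1e−10 output guarantee.

Randomness: a master seed plus a SHA-256 hash of each subject id seeds
per-subject substreams, so cohorts are bit-reproducible and an individual
subject's data are invariant under cohort resizing.

What the generator does **not** emulate: raw 4-D images, head motion,
scanner drift, physiological noise spectra, hemodynamic autocorrelation, or
volume–connectivity coupling within subject. Passing tests therefore
certify the statistical machinery (calibration, power against planted
effects, reproducibility), not robustness to acquisition artifacts in real
data.

## Calibration and problem sizes used in tests

Type-I-error calibration uses fully exchangeable null cohorts (no effects,
identical volume distributions across groups) at the default group sizes:
200 cohort seeds, B = 1000, rejection rates pooled over the ten regions
within each comparison (2000 draws per comparison; a per-region-per-comparison
band of ±0.03 around 0.05 at 200 draws is ≈ ±2σ and would reject a perfectly
calibrated test with high probability across 30 simultaneous checks).
Planted-effect recovery uses 20 cohorts with hippocampus-L hub weakening
(×0.5) in AD at full sample sizes with B = 1000; classifier noise
calibration averages 50 LOOCV runs with 64-tree forests. These reduced
replication counts are the package's own test-scale choices; the analysis
defaults remain B = 5000 and 500 trees, and `scripts/acceptance.py` runs at
those defaults.

## Known limitations

- Real-data entry points operate on extracted ROI tables or NIfTI
  volumes already in a common space; registration, segmentation and motion
  correction are upstream of this package.
- The chosen sparsity is a data-dependent quantity; cohorts of different
  size or noise level legitimately select different values, so forced
  sparsity should be used when comparing across cohorts.
- With selection on the full sample (the default), LOOCV accuracy is
  optimistically biased; use `nested_selection=True` for honest estimates.
- maxT correction assumes exchangeability of subjects under the null within
  the whole cohort; covariate adjustment (age, sex) is out of scope.
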