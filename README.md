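# connfp

Joint subcortical volumetry and resting-state functional-network analysis for
three-group dementia cohorts (normal controls, mild cognitive impairment,
Alzheimer's disease), with "connectional fingerprint" summaries.

The package is for neuroimaging researchers who have (or want to simulate)
per-subject ROI time series and subcortical volumes and need a reproducible
route from those inputs to: binarized functional networks, regional
eigenvector centrality, permutation-based group statistics, a three-class
classifier, and per-group radar fingerprints.

## Method

For each subject, ROI time series (after discarding pre-equilibrium volumes,
polynomial/nuisance regression and optional 0.009–0.08 Hz band-pass) yield a
Pearson correlation matrix **R**, Fisher-transformed to **Z** = atanh(**R**).
**Z** is binarized at a fixed sparsity *s* by keeping the
*k* = round(*s*·R(R−1)/2) strongest edges; the analysis sparsity is the
smallest value on a 1–50% grid at which **every** subject's network is a
single connected component. Node importance is eigenvector centrality: the
Perron eigenvector **x** of the adjacency matrix **A**, satisfying
**Ax** = λ**x**, normalized to unit Euclidean norm.

Group differences per subcortical region (thalamus, putamen, hippocampus,
caudate, amygdala; left/right) are tested for both modalities (volume,
centrality) with permutation tests: subjects are randomly reassigned to the
three groups (sizes preserved) 5000 times; the statistic is the absolute
group-mean difference; family-wise correction uses the Westfall–Young maxT
device, p = (1 + #{max-null ≥ observed}) / (1 + B). Regions with corrected
p < 0.05 in at least two of the three pairwise comparisons become classifier
features; a 500-tree random forest is evaluated by leave-one-out
cross-validation (baseline for three classes: 33%). Finally, each group's
fingerprint places its per-region means on radar axes; the enclosed polygon
area, (1/2)·sin(2π/k)·Σᵢ mᵢ·mᵢ₊₁, summarizes global degeneration.

Because the real cohorts behind this design are access-restricted, the
package includes a first-class synthetic cohort generator: group-specific
ROI covariance with plantable hub-weakening effects, and group-specific
volume distributions — every stage is testable end-to-end without data
downloads.

## Worked example

```python
from connfp import CohortConfig, fingerprint_summary, generate_cohort

cohort = generate_cohort(CohortConfig(seed=7))
profiles = fingerprint_summary(cohort.volumes_matrix(), cohort.labels,
                               cohort.target_roi_names)
for g in ("NC", "MCI", "AD"):
    p = profiles[g]
    print(f"{g}: radar area {p.area:8.2f}  hippocampus-L mean "
          f"{p.region_means[4]:.2f} cc [{p.ci_low[4]:.2f}, {p.ci_high[4]:.2f}]")
```

prints

```
NC: radar area    86.41  hippocampus-L mean 4.78 cc [4.51, 5.05]
MCI: radar area    82.39  hippocampus-L mean 4.43 cc [4.17, 4.69]
AD: radar area    74.14  hippocampus-L mean 3.82 cc [3.55, 4.09]
```

— hippocampal volume falls with disease stage and the shrinking radar area
condenses atrophy across all ten regions into one number per group.
The scripts in `examples/` walk through each capability (cohort generation,
networks and the sparsity search, centrality statistics, classification,
fingerprints, the full pipeline); `connfp simulate` and `connfp run` expose
the two shell-level entry points.

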