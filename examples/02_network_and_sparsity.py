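"""Build binarized functional networks and find the common sparsity.

Each subject's ROI time series becomes a Pearson correlation matrix, is
Fisher-transformed, and is thresholded at a fixed sparsity. The cohort-wide
sparsity is the smallest grid value at which every subject's network is a
single connected component.
"""
from connfp import (CohortConfig, RoiTimeSeries, binarize_at_sparsity,
                    correlation_matrix, fisher_z, generate_cohort,
                    minimum_common_sparsity)

cohort = generate_cohort(CohortConfig(seed=7))
zs = []
for sub in cohort.subjects:
    ts = RoiTimeSeries(sub.timeseries, cohort.config.tr_seconds, cohort.roi_names)
    zs.append(fisher_z(correlation_matrix(ts)))

s_min = minimum_common_sparsity(zs)
print(f"minimum common sparsity: {s_min:.0%} "
      "(smallest edge density connecting every subject's network)")

net = binarize_at_sparsity(zs[0], s_min)
print(f"subject {cohort.subject_ids[0]}: {net.n_edges} edges on "
      f"{net.n_nodes} nodes at sparsity {net.sparsity:.0%}")
# Below this sparsity at least one subject's graph fragments, and eigenvector
# centrality (which needs a connected graph) would be undefined.
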