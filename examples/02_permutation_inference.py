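"""FWE-corrected inference by sign-flip permutation.

Generates a synthetic paired comparison with a genuine connectivity change,
builds null distributions of the maximum CSS/CMS statistics over the full
sign-flip enumeration, and reports FWE-corrected cluster p-values, plus the
element-wise max-t baseline for contrast.
"""

import numpy as np

from connclust import (
    cluster_null_distributions,
    elementwise_maxt_test,
    enumerate_flips,
    extract_clusters,
    fwe_pvalue,
    link_count_map,
    paired_t_matrix,
    pearson_connectivity,
    threshold_to_adjacency,
)
from connclust.simulate import SimulationConfig, generate_groups

config = SimulationConfig(shape=(14, 14), n_subjects=10, n_timepoints=120,
                          cn=0.6, radius=2.0, cv=1.0, t0=4.0)
A, B, C, primary, _ = generate_groups(config, trial_seed=7)
grid = config.grid()

mats_c = [pearson_connectivity(s, on_zero_variance="zero").values for s in C]
mats_b = [pearson_connectivity(s, on_zero_variance="zero").values for s in B]

scheme = enumerate_flips(config.n_subjects, "full")
print(f"{scheme.n_permutations} sign-flip labellings "
      f"(2^{config.n_subjects}, identity included)")

dists = cluster_null_distributions(mats_c, mats_b, config.t0, scheme, grid)
tmat = paired_t_matrix(mats_c, mats_b)
lcm = link_count_map(threshold_to_adjacency(tmat, config.t0, "positive"),
                     grid)
primary_set = set(primary.tolist())
for cl in extract_clusters(lcm)[:3]:
    p_css = fwe_pvalue(cl.css_extent, dists["css"], "two")
    p_cms = fwe_pvalue(cl.cms_mass, dists["cms"], "two")
    in_truth = bool(primary_set & set(cl.member_indices.tolist()))
    print(f"cluster at {cl.peak_voxel} (truth: {'signal' if in_truth else 'noise'}): "
          f"CSS {cl.css_extent} (p={p_css:.4f}), CMS {cl.cms_mass} "
          f"(p={p_cms:.4f})")
# p-values are corrected family-wise: they compare each cluster against the
# permutation distribution of the *largest* cluster anywhere in the slice,
# so p <= 0.05 controls the chance of any false-positive cluster at 5%.

max_d, min_d, sig = elementwise_maxt_test(mats_c, mats_b, scheme)
print(f"element-wise baseline: observed max t = {max_d.values[0]:.2f}, "
      f"{int(sig.sum()) // 2} significant connections at alpha=0.05")
# The single-connection test must beat the max-t null across ~19k elements
# at once, which is why cluster statistics usually find effects it misses.
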