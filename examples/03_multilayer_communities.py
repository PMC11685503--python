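"""Multilayer community detection with subjects as layers.

Builds a small cohort network, maximizes the multilayer modularity Q at
(gamma, omega) = (1.2, 0.1), and derives a consensus assignment over many
stochastic runs.  The adjusted Rand index against the planted communities
shows whether the detection recovered the ground truth in every layer.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from netlayers import (
    CohortSpec, ResolutionParams, assemble_multilayer, build_connectivity,
    consensus_partition, louvain_optimize, make_atlas, simulate_timeseries,
)

spec = CohortSpec(
    n_nodes=30, network_sizes=(10, 10, 10), n_layers_per_group=6,
    within_block_corr=0.6, between_block_corr=0.1, n_timepoints=200, seed=4,
)
atlas = make_atlas(spec)
mats = [
    build_connectivity(simulate_timeseries(atlas, spec, "A", k), atlas, k, "A")
    for k in range(6)
]
net = assemble_multilayer(mats, atlas)
params = ResolutionParams(gamma=1.2, omega=0.1)

single = louvain_optimize(net, params, seed=0)
cons = consensus_partition(net, params, n_iter=20, seed=0)
truth = atlas.network_codes()
aris = [adjusted_rand_score(truth, cons.labels[:, s]) for s in range(net.n_layers)]

print(f"single run : Q = {single.q_value:.4f}, {single.n_communities} communities")
print(f"consensus  : Q = {cons.q_value:.4f}, {cons.n_communities} communities "
      f"({cons.meta['consensus_rounds']} stabilization round(s))")
print(f"per-layer ARI vs planted communities: min {min(aris):.2f}, max {max(aris):.2f}")
# ARI = 1.0 in every layer means the three planted networks were recovered
# exactly for every simulated subject.
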