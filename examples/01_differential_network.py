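"""Build a differential co-expression network from two synthetic cohorts.

Simulates a case cohort carrying rewired co-expression modules and a control
cohort without them, soft-thresholds each cohort's Pearson adjacency at
beta = 10, takes the per-edge absolute adjacency difference d, filters to
curated physical interactions and keeps the largest connected component.
"""

import numpy as np

from targetforest import (
    betweenness,
    compute_adjacency,
    differential_edges,
    filter_physical,
    largest_component,
)
from targetforest.synthetic import simulate_all

scenario = simulate_all(seed=11, n_genes=120, n_modules=3, n_differential=2,
                        module_size=8)
truth = scenario.truth

net_case = compute_adjacency(scenario.expr_case, beta=10)
net_ctrl = compute_adjacency(scenario.expr_control, beta=10)
dn = differential_edges(net_case, net_ctrl)
dn_phys = filter_physical(dn, scenario.annotations)
dn_lcc = largest_component(dn_phys)

d_planted = np.mean([
    dn.graph.edges[u, v]["d"]
    for k in truth.differential_modules
    for i, u in enumerate(truth.module_genes(k))
    for v in truth.module_genes(k)[i + 1:]
])
d_all = np.mean([dat["d"] for _, _, dat in dn.edges()])

print(f"physical edges kept      : {dn_phys.n_edges} of {dn.n_edges}")
print(f"largest component        : {dn_lcc.n_nodes} nodes / {dn_lcc.n_edges} edges")
print(f"mean d, planted modules  : {d_planted:.4f}")
print(f"mean d, all gene pairs   : {d_all:.4f}")

btw = betweenness(dn_lcc)
top = sorted(btw, key=lambda g: -btw[g])[:5]
print("top betweenness          :", ", ".join(f"{g}={btw[g]:.0f}" for g in top))
print()
print("A planted-module mean d well above the background mean shows the")
print("rewired co-expression survives soft-thresholding; high-betweenness")
print("genes are the broker nodes of the physical differential network.")
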