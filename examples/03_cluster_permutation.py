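"""Cluster-based permutation testing on the frontal asymmetry space.

Pointwise Welch t statistics are thresholded at the two-sided 0.05 critical
value, suprathreshold nodes are grouped into connected clusters, and each
cluster's mass (summed t) is compared with the permutation null of the most
extreme cluster mass.  Small designs switch to exact enumeration of all
relabelings automatically.
"""

import numpy as np

from faaverse import (
    band_log_power,
    cluster_permutation_test,
    generate_band_power,
    make_standard_layout,
    pair_asymmetry,
)
from faaverse.cluster import pair_graph
from faaverse.synth import StudyConfig

layout = make_standard_layout()
cfg = StudyConfig(study_id="demo", n_per_group={"diagnosed": 20, "healthy": 20},
                  asymmetry_effect_d=-1.2, seed=3)
ds = generate_band_power(cfg)
asym = pair_asymmetry(band_log_power(ds))
graph = pair_graph(layout, list(asym.pairs))
pred = (ds.meta["group"] == "diagnosed").to_numpy(float)

res = cluster_permutation_test(asym.values, pred, graph, kind="group",
                               n_perm=5000, seed=1)
print(f"Search space: {graph.n_nodes} frontal pairs "
      f"({', '.join(graph.node_ids)})")
print(f"Entry threshold |t| > {res.threshold:.3f}; "
      f"stat map range [{res.min_t:.2f}, {res.max_t:.2f}]")
print(f"Null built from {res.n_perm_used} {res.method} relabelings")
for cl in res.clusters:
    names = [graph.node_ids[i] for i in cl.nodes]
    print(f"  cluster {names}  mass = {cl.mass:+.2f}  p = {cl.p:.4f}")
if not res.clusters:
    print("  no suprathreshold clusters")
print("\nRow as it would appear in a cluster results table:")
print({k: (round(v, 3) if isinstance(v, float) else v)
       for k, v in res.to_table_row().items()})
print("A negative-mass cluster with small p is the classical left-sided "
      "FAA pattern localized over frontal pairs.")

# Tiny designs: the p-value is exact, not Monte-Carlo
sub = np.r_[np.nonzero(pred == 1)[0][:4], np.nonzero(pred == 0)[0][:4]]
tiny = cluster_permutation_test(asym.values[sub], pred[sub], graph,
                                kind="group", n_perm=1000, seed=1)
print(f"\n4-vs-4 subset: method = {tiny.method} "
      f"({tiny.n_perm_used} relabelings enumerated)")
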