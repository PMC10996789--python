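"""Detect co-expression modules in a synthetic CSF discovery cohort.

Generates a proteins x samples abundance matrix with 8 planted modules,
builds the signed bicor/TOM network, cuts the dendrogram and refines
membership by kME consistency, then compares against the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from csfnet.network import (build_network, cluster_dendrogram, detect_modules,
                            enforce_kme_consistency, merge_close_modules)
from csfnet.simulate import generate_discovery_cohort

matrix, metadata, truth = generate_discovery_cohort(seed=7)
print(f"cohort: {matrix.n_proteins} proteins x {matrix.n_samples} samples, "
      f"{truth.n_modules()} planted modules")

net = build_network(matrix, beta=12, tom_denom="mean")
linkage, d = cluster_dendrogram(net.tom)
detected = detect_modules(linkage, d, matrix.protein_ids,
                          deep_split=4, min_module_size=30)
merged = merge_close_modules(matrix, detected, cut_height=0.07)
final = enforce_kme_consistency(matrix, merged)

score = adjusted_rand_score([truth.membership[p] for p in matrix.protein_ids],
                            [final[p] for p in matrix.protein_ids])
sizes = {m: s for m, s in sorted(final.sizes().items()) if m != "grey"}
print(f"detected modules: {sizes}")
print(f"grey fraction: {merged.grey_fraction():.3f} before kME reassignment, "
      f"{final.grey_fraction():.3f} after")
print(f"adjusted Rand index vs planted truth: {score:.3f}")
print("ARI near 1 means the detected partition matches the planted modules; "
      "grey holds proteins with no co-expression community.")
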