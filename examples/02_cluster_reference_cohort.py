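"""Cluster a 426-fish reference cohort and name the communities.

Draws a day-1 feature cohort from the four archetypes, selects the graph's
k from the internal-validity plateau, partitions with Louvain, and prints
the recovered community structure.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from fishclust import CohortSpec, fit, generate_feature_cohort, name_clusters

spec = CohortSpec(n_sessions=1, seed=20)  # 426 fish across 4 strains x 2 sexes
features, metadata, truth = generate_feature_cohort(spec)

model = fit(features, seed=0)  # no k given: scan + plateau selection
sizes = np.bincount(model.labels)[1:]
names = name_clusters(model)

print(f"selected k            : {model.k}")
print(f"communities found     : {model.n_communities}")
print(f"community sizes       : {sizes.tolist()}")
print(f"assignment neighbors  : m = {model.m_assign} (half the smallest community)")
print(f"semantic names        : { {c: names[c] for c in sorted(names)} }")
ari = adjusted_rand_score(truth["archetype"], model.labels)
print(f"ARI vs planted truth  : {ari:.3f}")
print(
    "\nThe k-NN/Louvain chain recovers exactly the four planted behavioral"
    "\narchetypes (ARI 1.0 means the partition matches the ground truth up to"
    "\nlabel names). m is the neighbor count later used to assign new sessions."
)
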