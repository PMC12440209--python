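"""Two-stage glycemic profiling: SOM + k-means over label subsets.

The training set is split into hypoglycemia / non-hypoglycemia /
hyperglycemia / non-hyperglycemia subsets; each trains a 10x10 SOM whose
100 prototypes are grouped by k-means into 3 behavioral subgroups, giving
12 stored centroids. New instances are routed to their system's nearest
centroids by Euclidean distance in the z-scored feature space.
"""

from collections import Counter

from glycloop import SimScenario, generate_cohort, build_dataset
from glycloop.profiling import assign_clusters, build_profile_index, choose_k, train_som
import numpy as np

records, _ = generate_cohort(SimScenario(n_patients=4, n_days=20, seed=3))
instances = build_dataset(records)
store = build_profile_index(instances, seed=0, som_epochs=200)

print(f"centroid store: {len(store.centroids)} centroids "
      f"({store.k} per system x event-class)\n")

counts = Counter(i.cluster_id_s1 for i in instances)
print("S1 training-cluster occupancy (0-2 event, 3-5 non-event):")
for cid in sorted(counts):
    print(f"  cluster {cid}: {counts[cid]} meals")

v = instances[0].features.to_array()
print("\nranked S1 centroids for the first instance (distance in z-units):")
for key, dist in assign_clusters(store, v, "S1"):
    print(f"  {key}: {dist:.3f}")

# the k=3 choice, re-derived on one subset's prototypes
X = np.vstack([i.features.to_array() for i in instances
               if i.label_hypo == 0])[:, store.feature_idx]
Z = (X - store.norm_mean) / store.norm_sd
som = train_som(Z, epochs=200, seed=0)
k, diag = choose_k(som.weights, seed=0)
print(f"\nsilhouette-selected k on the non-hypo subset prototypes: {k}")
print("silhouette per k:", {kk: round(s, 3) for kk, s in diag['silhouette'].items()})
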