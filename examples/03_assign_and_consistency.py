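"""Assign day-2 sessions to day-1 clusters and test longitudinal consistency.

Simulates a two-session cohort with partial archetype persistence, fits the
reference clustering on day 1, assigns day 2 out-of-sample, and runs the
two-day percent-overlap permutation test.
"""

import numpy as np

from fishclust import (
    CohortSpec,
    assign,
    fit,
    generate_feature_cohort,
    two_day_overlap,
)

spec = CohortSpec(persistence=0.6, n_sessions=2, seed=42)
features, metadata, truth = generate_feature_cohort(spec)
day1 = features[features["session"] == "1"].reset_index(drop=True)
day2 = features[features["session"] == "2"].reset_index(drop=True)

model = fit(day1, k=114, seed=0)
labels_day2 = assign(model, day2)

percent, result = two_day_overlap(model.labels, labels_day2, m=10_000, seed=1)
print(f"fish in the same cluster on both days : {percent:.1f}%")
print(f"permutation average overlap           : {result.extra['null_mean_percent']:.1f}%")
print(f"permutation p-value (m=10,000)        : {result.p:.4f}")
print(
    "\nWith 60% day-to-day archetype persistence, far more fish keep their"
    "\ncluster than the ~26% expected when day-2 labels are shuffled across"
    "\nfish, so the permutation p-value sits at the 1/10001 resolution floor."
)
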