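"""Group-composition and repeated-measures permutation inference.

Builds a cohort whose strain/sex groups have unequal archetype propensities,
then asks: (1) which strain-sex groups are over/under-represented in which
cluster, (2) does a planted sex difference in distance travelled survive a
4x2 permutation ANOVA, and (3) how consistent are multi-session labels.
"""

import numpy as np
import pandas as pd

from fishclust import (
    CohortSpec,
    fdr_adjust,
    fit,
    generate_feature_cohort,
    overlap_test,
    perm_anova,
    representation_test,
)
from fishclust.simulate import SEXES, STRAINS

# TL fish lean shy, males lean toward active exploration; everyone else uniform
probs = {}
for strain in STRAINS:
    for sex in SEXES:
        p = np.full(4, 0.25)
        if strain == "TL":
            p = np.array([0.55, 0.15, 0.15, 0.15])
        elif sex == "M":
            p = np.array([0.15, 0.20, 0.45, 0.20])
        probs[(strain, sex)] = p

spec = CohortSpec(archetype_probs=probs, persistence=0.6, n_sessions=5, seed=3)
features, metadata, truth = generate_feature_cohort(spec)
day1 = features[features["session"] == "1"].reset_index(drop=True)
meta1 = metadata[metadata["session"] == "1"].reset_index(drop=True)

model = fit(day1, k=114, seed=0)
rep = representation_test(
    meta1["strain"] + ":" + meta1["sex"], model.labels, m=10_000, seed=1
)
hits = rep[rep["p_adjusted"] < 0.05].sort_values("p_adjusted")
print("over/under-represented strain:sex cells (BH-FDR < 0.05):")
print(hits[["group", "cluster", "count", "expected", "direction", "p_adjusted"]]
      .to_string(index=False))

# planted sex effect: males are enriched for the high-distance archetype
dv = day1.merge(meta1, on=["fish_id", "session"])
anova = perm_anova(dv, "distance_cm", between=["strain", "sex"], m=10_000, seed=2)
ps = fdr_adjust([anova[k].p for k in anova])
for (effect, res), p_adj in zip(anova.items(), ps):
    print(f"ANOVA {effect:>11}: F = {res.observed:6.2f}, p = {res.p:.4f}, "
          f"p_adj = {p_adj:.4f}")

# longitudinal consistency over the 5 sessions
wide = truth.pivot(index="fish_id", columns="session", values="archetype")
res = overlap_test(wide.to_numpy(), m=10_000, seed=4)
print(f"\nmean overlap score over 5 sessions   : {res.observed:.2f} "
      f"(chance {res.null_sample.mean():.2f}), p = {res.p:.4f}")
print(
    "\nThe representation test flags the planted TL-shy and male-explorer"
    "\nbiases; the ANOVA detects the sex effect on distance travelled that"
    "\nthose biases induce; and the overlap test shows per-fish cluster"
    "\nmembership repeats across sessions far above chance."
)
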