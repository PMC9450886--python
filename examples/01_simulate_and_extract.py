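"""Simulate archetype swim traces and extract the four exploratory features.

Generates short trials for each behavioral archetype in a 15 cm novel tank
and prints the cohort-mean feature profile per archetype.
"""

import numpy as np
import pandas as pd

from fishclust import DEFAULT_ARCHETYPES, TankGeometry, extract_features, generate_trace

geometry = TankGeometry()  # 15 cm tank, 11.1 cm water, 1000-voxel grid
rng = np.random.default_rng(1)

rows = []
for name, archetype in DEFAULT_ARCHETYPES.items():
    for _ in range(10):
        trace = generate_trace(
            archetype, geometry, duration=120, fps=30, seed=int(rng.integers(2**31))
        )
        fv = extract_features(trace, geometry)
        rows.append(
            {
                "archetype": name,
                "bottom_cm": fv.bottom_cm,
                "center_cm": fv.center_cm,
                "distance_cm": fv.distance_cm,
                "percent_explored": fv.percent_explored,
            }
        )

profile = pd.DataFrame(rows).groupby("archetype").mean().round(2)
print(profile)
print(
    "\nEach row is an archetype's mean feature vector over 10 simulated 2-min"
    "\ntrials: height above the tank floor (cm), distance from the vertical"
    "\ncenter line (cm), total path length (cm), and percent of the 1000 tank"
    "\nvoxels visited. Shy fish sit low and explore least; bold fish swim high"
    "\nand central; wall-huggers track the walls; active explorers cover the"
    "\nmost distance and volume."
)
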