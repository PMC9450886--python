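import numpy as np
import pandas as pd
import pytest

from fishclust import TankGeometry, SwimTrace
from fishclust.features import FEATURE_NAMES


@pytest.fixture
def geometry():
    return TankGeometry()


@pytest.fixture
def static_trace():
    """A fish parked at the tank center at 5 cm height, 10 s @ 30 fps."""
    n = 300
    t = np.arange(n) / 30.0
    xyz = np.tile([7.5, 7.5, 5.0], (n, 1))
    return SwimTrace(t=t, xyz=xyz, fps=30.0)


def make_blobs(sizes, centers=None, sd=1.0, seed=0):
    """Well-separated Gaussian blobs in 4-D feature space with known labels."""
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = np.eye(len(sizes), 4) * 30.0
        centers += np.arange(len(sizes))[:, None] * 10.0
    rows, labels = [], []
    for ci, (n, c) in enumerate(zip(sizes, np.asarray(centers, dtype=float))):
        rows.append(c + rng.normal(0, sd, size=(n, 4)))
        labels.extend([ci] * n)
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "fish_id", [f"f{i:04d}" for i in range(len(df))])
    return df, np.asarray(labels)


@pytest.fixture
def blob_cohort():
    """120 fish in 4 planted clusters, separation >> within-cluster sd."""
    return make_blobs([24, 28, 32, 36], sd=1.0, seed=7)
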