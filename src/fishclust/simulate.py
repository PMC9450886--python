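"""Synthetic swim traces and cohorts with the structure the analysis assumes.

No trajectory data are deposited with novel-tank studies at this scale, so
every downstream stage (feature extraction, clustering, assignment,
permutation inference) is exercised against generated data whose ground
truth is known.

The world being emulated: 6-min trials in a 15 x 15 x 15 cm tank with
~11.1 cm of water, recorded at 30 frames/s; four behavioral archetypes
(shy, wall-hugger, active explorer, bold) whose extracted features
reproduce the qualitative profile of real clusters; cohorts of four
zebrafish strains (AB, TL, TU, WIK) of both sexes with strain/sex-dependent
archetype proportions; and day-to-day archetype persistence modeled as a
first-order Markov chain on labels.

Movement model: a correlated random walk with Ornstein–Uhlenbeck-like
directional persistence, vertical drift toward a preferred height above the
bottom, a horizontal radial potential (positive ``wall_affinity`` attracts
toward the walls, negative toward the center line), and reflective
boundaries at the walls and water surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TankGeometry
from .trace import SwimTrace

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "CalibrationSet",
    "ARCHETYPES",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_ARCHETYPE_FEATURE_MEANS",
    "DEFAULT_FEATURE_SD",
    "generate_trace",
    "generate_cohort",
    "generate_feature_cohort",
    "generate_calibration",
]

ARCHETYPES = ("shy", "wall_hugger", "active_explorer", "bold")
STRAINS = ("AB", "TL", "TU", "WIK")
SEXES = ("F", "M")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Movement parameters of one behavioral archetype.

    Parameters
    ----------
    name : str
        One of ``shy``, ``wall_hugger``, ``active_explorer``, ``bold``.
    depth_pref : float
        Target height above the bottom, cm.
    wall_affinity : float
        Strength of the horizontal radial drift; positive pulls toward the
        walls, negative toward the vertical center line. Dimensionless
        multiplier on a cm/s drift scale.
    speed_mean, speed_sd : float
        Mean and spread of the per-frame swim speed, cm/s.
    turn_persistence : float
        Directional autocorrelation of the heading in [0, 1); higher values
        give straighter paths.
    """

    name: str
    depth_pref: float
    wall_affinity: float
    speed_mean: float
    speed_sd: float
    turn_persistence: float

    def __post_init__(self) -> None:
        vals = (
            self.depth_pref,
            self.wall_affinity,
            self.speed_mean,
            self.speed_sd,
            self.turn_persistence,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("archetype parameters must be finite")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0")
        if self.speed_sd < 0:
            raise ValueError("speed_sd must be >= 0")
        if not (0 <= self.turn_persistence < 1):
            raise ValueError("turn_persistence must be in [0, 1)")
        if self.depth_pref < 0:
            raise ValueError("depth_pref must be >= 0")


# Defaults calibrated so the features extracted from generated traces
# reproduce the qualitative per-cluster profile seen in real cohorts:
# shy lowest in bottom distance and percent explored; wall-huggers highest
# in center distance; active explorers highest in distance travelled and
# percent explored; bold highest in bottom distance, lowest in center
# distance, below-average distance travelled.
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "shy": ArchetypeSpec("shy", depth_pref=1.0, wall_affinity=0.0,
                         speed_mean=1.2, speed_sd=0.5, turn_persistence=0.70),
    "wall_hugger": ArchetypeSpec("wall_hugger", depth_pref=4.5, wall_affinity=1.8,
                                 speed_mean=6.0, speed_sd=2.0, turn_persistence=0.80),
    "active_explorer": ArchetypeSpec("active_explorer", depth_pref=5.5, wall_affinity=0.8,
                                     speed_mean=10.0, speed_sd=3.0, turn_persistence=0.60),
    "bold": ArchetypeSpec("bold", depth_pref=9.5, wall_affinity=-0.6,
                          speed_mean=4.0, speed_sd=1.2, turn_persistence=0.80),
}


def _uniform_probs() -> dict[tuple[str, str], np.ndarray]:
    return {(s, x): np.full(4, 0.25) for s in STRAINS for x in SEXES}


@dataclass(frozen=True)
class CohortSpec:
    """Composition and longitudinal design of a synthetic cohort.

    ``strain_sex_table`` maps ``(strain, sex)`` to a fish count; the default
    mirrors a realistic 426-fish reference cohort (AB 58F/52M, TL 54F/50M,
    TU 58F/50M, WIK 51F/53M). ``archetype_probs`` maps each group to its
    probability vector over the four archetypes (order of ``ARCHETYPES``).
    ``persistence`` is the probability a fish keeps its archetype on the next
    session; otherwise it is resampled from its group's archetype
    probabilities (a first-order Markov chain on labels).
    """

    strain_sex_table: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("AB", "F"): 58, ("AB", "M"): 52,
            ("TL", "F"): 54, ("TL", "M"): 50,
            ("TU", "F"): 58, ("TU", "M"): 50,
            ("WIK", "F"): 51, ("WIK", "M"): 53,
        }
    )
    archetype_probs: dict[tuple[str, str], np.ndarray] = field(default_factory=_uniform_probs)
    persistence: float = 0.6
    n_sessions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strain_sex_table:
            raise ValueError("strain_sex_table must not be empty")
        for key, n in self.strain_sex_table.items():
            if n < 0:
                raise ValueError(f"negative count for {key}")
            p = np.asarray(self.archetype_probs[key], dtype=float)
            if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError(f"archetype_probs for {key} must be a length-4 simplex vector")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be in [0, 1]")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    @property
    def n_fish(self) -> int:
        return sum(self.strain_sex_table.values())


def generate_trace(
    archetype: ArchetypeSpec,
    geometry: TankGeometry | None = None,
    duration: float = 360.0,
    fps: float = 30.0,
    seed: int = 0,
) -> SwimTrace:
    """Simulate one fish-session trace as a bounded correlated random walk.

    Returns ``ceil(duration * fps)`` frames of 3D positions inside the water
    volume. Heading evolves as an AR(1) process with coefficient
    ``turn_persistence``; each frame the fish moves at a truncated-Gaussian
    speed along a direction blending its previous heading, vertical drift
    toward ``depth_pref``, and a horizontal radial drift scaled by
    ``wall_affinity``. Boundaries reflect.
    """
    geometry = geometry or TankGeometry()
    if not (np.isfinite(duration) and duration > 0 and np.isfinite(fps) and fps > 0):
        raise ValueError("duration and fps must be positive and finite")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * fps))
    dt = 1.0 / fps
    side, depth = geometry.side, geometry.water_depth
    margin = min(0.5, side / 10)  # body-size standoff from the walls
    center = np.array([side / 2, side / 2])

    pos = np.empty((n, 3))
    # start near the tank center at the preferred depth
    pos[0] = [
        side / 2 + rng.normal(0, 1.0),
        side / 2 + rng.normal(0, 1.0),
        np.clip(archetype.depth_pref + rng.normal(0, 0.5), 0.2, depth - 0.2),
    ]
    pos[0, :2] = np.clip(pos[0, :2], margin, side - margin)

    heading = rng.standard_normal(3)
    heading /= np.linalg.norm(heading)
    phi = archetype.turn_persistence
    # per-frame innovations; sqrt(1-phi^2) keeps heading variance stationary
    noise = rng.standard_normal((n, 3)) * np.sqrt(1.0 - phi**2)
    speeds = np.clip(rng.normal(archetype.speed_mean, archetype.speed_sd, n), 0.0, None)

    # drift scales, cm/s, chosen so behavioral biases dominate noise but do
    # not pin the fish to a wall
    z_gain = 1.2
    r_gain = 1.0

    for i in range(1, n):
        p = pos[i - 1]
        drift = np.zeros(3)
        drift[2] = z_gain * (archetype.depth_pref - p[2]) / max(depth, 1e-9)
        radial = p[:2] - center
        rnorm = np.linalg.norm(radial)
        if rnorm > 1e-9:
            drift[:2] = r_gain * archetype.wall_affinity * radial / rnorm
        elif archetype.wall_affinity > 0:
            theta = rng.uniform(0, 2 * np.pi)
            drift[:2] = r_gain * archetype.wall_affinity * np.array(
                [np.cos(theta), np.sin(theta)]
            )
        heading = phi * heading + (1.0 - phi) * drift + noise[i]
        hn = np.linalg.norm(heading)
        if hn > 1e-12:
            step_dir = heading / hn
        else:
            step_dir = np.zeros(3)
        new = p + speeds[i] * dt * step_dir
        # reflect off the four walls and the floor/surface
        for ax, lo, hi in ((0, margin, side - margin), (1, margin, side - margin), (2, 0.0, depth)):
            if new[ax] < lo:
                new[ax] = lo + (lo - new[ax])
                heading[ax] = -heading[ax]
            if new[ax] > hi:
                new[ax] = hi - (new[ax] - hi)
                heading[ax] = -heading[ax]
            new[ax] = np.clip(new[ax], lo, hi)
        pos[i] = new

    t = np.arange(n) * dt
    return SwimTrace(t=t, xyz=pos, fps=fps, fish_id="", session="")


def _markov_labels(
    rng: np.random.Generator, probs: np.ndarray, n_sessions: int, persistence: float
) -> np.ndarray:
    """Archetype index per session for one fish under the persistence chain."""
    labels = np.empty(n_sessions, dtype=int)
    labels[0] = rng.choice(4, p=probs)
    for s in range(1, n_sessions):
        if rng.random() < persistence:
            labels[s] = labels[s - 1]
        else:
            labels[s] = rng.choice(4, p=probs)
    return labels


def generate_cohort(
    spec: CohortSpec,
    geometry: TankGeometry | None = None,
    archetypes: dict[str, ArchetypeSpec] | None = None,
    duration: float = 360.0,
    fps: float = 30.0,
) -> tuple[list[SwimTrace], pd.DataFrame, pd.DataFrame]:
    """Simulate traces for a full cohort across sessions.

    Returns ``(traces, metadata, true_labels)`` where metadata has columns
    ``fish_id, strain, sex, session`` (one row per fish-session, aligned with
    ``traces``) and true_labels has ``fish_id, session, archetype`` for
    recovery testing. Sessions are labeled ``"1"``, ``"2"``, ...
    """
    geometry = geometry or TankGeometry()
    archetypes = archetypes or DEFAULT_ARCHETYPES
    rng = np.random.default_rng(spec.seed)
    traces: list[SwimTrace] = []
    meta_rows, label_rows = [], []
    fish_no = 0
    for (strain, sex), count in sorted(spec.strain_sex_table.items()):
        probs = np.asarray(spec.archetype_probs[(strain, sex)], dtype=float)
        for _ in range(count):
            fish_no += 1
            fid = f"fish{fish_no:04d}"
            arch_idx = _markov_labels(rng, probs, spec.n_sessions, spec.persistence)
            for s in range(spec.n_sessions):
                session = str(s + 1)
                name = ARCHETYPES[arch_idx[s]]
                trace_seed = int(rng.integers(0, 2**31 - 1))
                tr = generate_trace(
                    archetypes[name], geometry, duration=duration, fps=fps, seed=trace_seed
                )
                tr.fish_id, tr.session = fid, session
                traces.append(tr)
                meta_rows.append(
                    {"fish_id": fid, "strain": strain, "sex": sex, "session": session}
                )
                label_rows.append({"fish_id": fid, "session": session, "archetype": name})
    return traces, pd.DataFrame(meta_rows), pd.DataFrame(label_rows)


# Archetype feature centroids for the fast (trace-free) cohort path, in the
# units of the extracted features (cm, cm, cm, %). Pairwise separation is
# >= 3 within-cluster standard deviations in every discriminating feature,
# and the profile follows the same qualitative ordering as the trace
# archetypes above.
DEFAULT_ARCHETYPE_FEATURE_MEANS = pd.DataFrame(
    {
        "bottom_cm": [1.5, 5.0, 6.0, 9.0],
        "center_cm": [5.5, 7.5, 5.0, 2.0],
        "distance_cm": [1400.0, 2200.0, 3400.0, 1800.0],
        "percent_explored": [8.0, 20.0, 38.0, 26.0],
    },
    index=list(ARCHETYPES),
)

DEFAULT_FEATURE_SD = pd.Series(
    {"bottom_cm": 0.8, "center_cm": 0.8, "distance_cm": 150.0, "percent_explored": 4.0}
)


def generate_feature_cohort(
    spec: CohortSpec,
    archetype_means: pd.DataFrame | None = None,
    within_sd: pd.Series | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-fish feature vectors directly from per-archetype Gaussians.

    A fast path that skips trace simulation: each fish-session's four features
    are drawn from an isotropic (per-feature-scaled) Gaussian centred on its
    archetype's centroid. Returns ``(features, metadata, true_labels)`` with
    features columns ``fish_id, session, bottom_cm, center_cm, distance_cm,
    percent_explored``.
    """
    means = DEFAULT_ARCHETYPE_FEATURE_MEANS if archetype_means is None else archetype_means
    sds = DEFAULT_FEATURE_SD if within_sd is None else pd.Series(within_sd)
    if list(means.index) != list(ARCHETYPES):
        means = means.loc[list(ARCHETYPES)]
    if (sds <= 0).any():
        raise ValueError("within_sd must be positive for every feature")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, meta_rows, label_rows = [], [], []
    fish_no = 0
    cols = list(means.columns)
    sd_vec = sds[cols].to_numpy(dtype=float)
    for (strain, sex), count in sorted(spec.strain_sex_table.items()):
        probs = np.asarray(spec.archetype_probs[(strain, sex)], dtype=float)
        for _ in range(count):
            fish_no += 1
            fid = f"fish{fish_no:04d}"
            arch_idx = _markov_labels(rng, probs, spec.n_sessions, spec.persistence)
            for s in range(spec.n_sessions):
                session = str(s + 1)
                name = ARCHETYPES[arch_idx[s]]
                feat = means.loc[name].to_numpy(dtype=float) + rng.normal(0, sd_vec)
                rows.append({"fish_id": fid, "session": session, **dict(zip(cols, feat))})
                meta_rows.append(
                    {"fish_id": fid, "strain": strain, "sex": sex, "session": session}
                )
                label_rows.append({"fish_id": fid, "session": session, "archetype": name})
    return pd.DataFrame(rows), pd.DataFrame(meta_rows), pd.DataFrame(label_rows)


@dataclass(frozen=True)
class CalibrationSet:
    """Paired depth measurements with and without water, for the diffraction fit.

    ``pairs[:, 0]`` is z measured without water (true depth); ``pairs[:, 1]``
    is the same point measured through water.
    """

    pairs: np.ndarray
    true_slope: float
    true_intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=float))
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2 or self.pairs.shape[0] < 2:
            raise ValueError("need >= 2 calibration pairs")


def generate_calibration(
    true_slope: float = 0.75,
    true_intercept: float = 1.0,
    n_points: int = 100,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> CalibrationSet:
    """Simulate paired depth-calibration measurements.

    Points of varying distance from the camera (spanning the 0–20 cm working
    range) are measured with and without water; the in-air reading follows
    ``z_air = slope * z_water + intercept + noise``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    z_water = rng.uniform(0.0, 20.0, n_points)
    z_air = true_slope * z_water + true_intercept + rng.normal(0, noise_sd, n_points)
    return CalibrationSet(
        pairs=np.column_stack([z_air, z_water]),
        true_slope=true_slope,
        true_intercept=true_intercept,
        noise_sd=noise_sd,
    )
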