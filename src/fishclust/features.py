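"""Exploratory-behavior feature extraction from 3D swim traces.

Four scalars summarize each 6-min trial:

* **bottom distance** (B, cm) — trial-mean height of the fish above the
  least-squares bottom plane; low values indicate bottom dwelling (geotaxis).
* **center distance** (C, cm) — trial-mean perpendicular distance from the
  vertical line through the tank center; high values indicate wall proximity
  (thigmotaxis).
* **distance travelled** (L, cm) — total path length, summed over
  successive-frame Euclidean steps.
* **percent explored** (E, %) — share of a 1000-voxel discretization of the
  tank visited at least once.

Preprocessing order: depth (diffraction) correction -> interpolation of
missing z -> Savitzky–Golay smoothing (window 7, order 3) for B, C and L.
Percent explored is computed on the unsmoothed (but corrected and
interpolated) trace so that voxel occupancy reflects measured positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .geometry import TankGeometry, point_line_distance, point_plane_distance
from .trace import SwimTrace

__all__ = [
    "DepthCorrection",
    "FeatureVector",
    "FEATURE_NAMES",
    "fit_depth_correction",
    "apply_depth_correction",
    "interpolate_missing_z",
    "smooth_trace",
    "bottom_distance",
    "center_distance",
    "distance_travelled",
    "percent_explored",
    "extract_features",
    "binned_features",
    "extract_feature_table",
]

FEATURE_NAMES = ["bottom_cm", "center_cm", "distance_cm", "percent_explored"]


@dataclass(frozen=True)
class DepthCorrection:
    """Linear map from in-water measured depth to true depth.

    Water refracts the stereo depth signal, so raw in-water z readings are
    biased; the correction is the least-squares line fitted to paired
    measurements of the same points with and without water.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero, intercept finite")

    def __call__(self, z_water: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(z_water, dtype=float) + self.intercept


IDENTITY_CORRECTION = DepthCorrection(1.0, 0.0)


def fit_depth_correction(pairs) -> DepthCorrection:
    """OLS fit of true depth (measured without water) on in-water depth.

    Parameters
    ----------
    pairs : sequence of (z_air, z_water) or object with a ``pairs`` attribute
        Paired calibration measurements in cm, e.g. 100 points of varying
        distance from the camera measured with and without water.
    """
    pairs = getattr(pairs, "pairs", pairs)
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 calibration pairs of (z_air, z_water)")
    z_air, z_water = arr[:, 0], arr[:, 1]
    if np.ptp(z_water) <= 0:
        raise ValueError("calibration predictor (in-water z) is degenerate")
    slope, intercept = np.polyfit(z_water, z_air, 1)
    return DepthCorrection(float(slope), float(intercept))


def apply_depth_correction(trace: SwimTrace, correction: DepthCorrection) -> SwimTrace:
    xyz = trace.xyz.copy()
    xyz[:, 2] = correction(xyz[:, 2])
    return trace.copy_with(xyz=xyz)


def interpolate_missing_z(trace: SwimTrace) -> SwimTrace:
    """Fill missing depth readings by linear interpolation in time.

    Interior gaps are linear between the flanking measurements; gaps at the
    trace ends take the nearest available value. Present values are unchanged.
    """
    z = trace.xyz[:, 2]
    ok = np.isfinite(z)
    if not ok.any():
        raise ValueError("all z values missing; nothing to interpolate from")
    if ok.all():
        return trace.copy_with()
    filled = np.interp(trace.t, trace.t[ok], z[ok])
    xyz = trace.xyz.copy()
    xyz[:, 2] = np.where(ok, z, filled)
    return trace.copy_with(xyz=xyz)


def smooth_trace(trace: SwimTrace, window: int = 7, order: int = 3) -> SwimTrace:
    """Savitzky–Golay smoothing of each coordinate channel.

    Defaults follow the trace-processing convention for these trials: a
    seven-frame window with a cubic polynomial. Edge frames use the filter's
    polynomial extrapolation so output length equals input length.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("order must be < window")
    if len(trace) < window:
        raise ValueError(f"trace of {len(trace)} frames shorter than window {window}")
    if np.isnan(trace.xyz).any():
        raise ValueError("interpolate missing z before smoothing")
    xyz = savgol_filter(trace.xyz, window_length=window, polyorder=order, axis=0, mode="interp")
    return trace.copy_with(xyz=xyz)


def _require_complete(trace: SwimTrace) -> None:
    if np.isnan(trace.xyz).any():
        raise ValueError("trace has missing z; run interpolate_missing_z first")


def bottom_distance(trace: SwimTrace, geometry: TankGeometry) -> float:
    """Trial-mean unsigned distance (cm) from the fish to the bottom plane."""
    _require_complete(trace)
    return float(point_plane_distance(trace.xyz, geometry.bottom_plane).mean())


def center_distance(trace: SwimTrace, geometry: TankGeometry) -> float:
    """Trial-mean perpendicular distance (cm) to the vertical center line."""
    _require_complete(trace)
    top, bot = geometry.center_line
    return float(point_line_distance(trace.xyz, top, bot).mean())


def distance_travelled(trace: SwimTrace) -> float:
    """Total path length (cm): sum of successive-frame Euclidean distances."""
    _require_complete(trace)
    steps = np.diff(trace.xyz, axis=0)
    return float(np.linalg.norm(steps, axis=1).sum())


def _voxel_indices(trace: SwimTrace, geometry: TankGeometry) -> np.ndarray:
    """Flat voxel index per frame; out-of-grid frames are clamped with a warning.

    Voxels are half-open boxes [lo, hi) along each axis, the last box closed,
    over side x side x voxel_grid_depth.
    """
    nx, ny, nz = geometry.voxel_counts
    extents = np.array([geometry.side, geometry.side, geometry.voxel_grid_depth])
    counts = np.array([nx, ny, nz])
    scaled = trace.xyz / extents * counts
    idx = np.floor(scaled).astype(int)
    # points exactly on the far face belong to the last voxel
    idx = np.where((trace.xyz == extents) & (idx == counts), counts - 1, idx)
    clamped = np.clip(idx, 0, counts - 1)
    if (clamped != idx).any():
        n_bad = int((clamped != idx).any(axis=1).sum())
        warnings.warn(
            f"{n_bad} frames outside the voxel grid were clamped to boundary voxels",
            stacklevel=3,
        )
    return np.ravel_multi_index((clamped[:, 0], clamped[:, 1], clamped[:, 2]), tuple(counts))


def percent_explored(trace: SwimTrace, geometry: TankGeometry) -> float:
    """Percent of tank voxels visited at least once (default grid: 1000 voxels)."""
    _require_complete(trace)
    visited = np.unique(_voxel_indices(trace, geometry)).size
    return 100.0 * visited / geometry.n_voxels


@dataclass(frozen=True)
class FeatureVector:
    """The four exploratory parameters of one fish-session."""

    bottom_cm: float
    center_cm: float
    distance_cm: float
    percent_explored: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.bottom_cm, self.center_cm, self.distance_cm, self.percent_explored]
        )


def _preprocess(
    trace: SwimTrace,
    correction: DepthCorrection | None,
    window: int,
    order: int,
    smooth_explored: bool,
) -> tuple[SwimTrace, SwimTrace]:
    """Return (smoothed trace for B/C/L, trace for E)."""
    t = apply_depth_correction(trace, correction or IDENTITY_CORRECTION)
    t = interpolate_missing_z(t)
    smoothed = smooth_trace(t, window=window, order=order)
    return smoothed, (smoothed if smooth_explored else t)


def extract_features(
    trace: SwimTrace,
    geometry: TankGeometry,
    correction: DepthCorrection | None = None,
    window: int = 7,
    order: int = 3,
    smooth_explored: bool = False,
) -> FeatureVector:
    """Run the full per-trace pipeline and return the four exploratory scalars.

    Applies depth correction, fills missing z, smooths for the three
    kinematic/positional features, and counts voxel occupancy for percent
    explored (on the unsmoothed trace unless ``smooth_explored``).
    """
    smoothed, for_explored = _preprocess(trace, correction, window, order, smooth_explored)
    return FeatureVector(
        bottom_cm=bottom_distance(smoothed, geometry),
        center_cm=center_distance(smoothed, geometry),
        distance_cm=distance_travelled(smoothed),
        percent_explored=percent_explored(for_explored, geometry),
    )


def binned_features(
    trace: SwimTrace,
    geometry: TankGeometry,
    n_bins: int = 6,
    correction: DepthCorrection | None = None,
    window: int = 7,
    order: int = 3,
    smooth_explored: bool = False,
) -> list[FeatureVector]:
    """Features per contiguous equal time interval (default six 1-min bins).

    The whole trace is preprocessed once, then frames are split into
    ``n_bins`` near-equal contiguous blocks. Path length partitions the
    inter-frame steps, so per-bin L sums exactly to the whole-trace L.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(trace):
        raise ValueError("more bins than frames")
    smoothed, for_explored = _preprocess(trace, correction, window, order, smooth_explored)
    bounds = np.linspace(0, len(trace), n_bins + 1).round().astype(int)
    out: list[FeatureVector] = []
    for b in range(n_bins):
        lo, hi = bounds[b], bounds[b + 1]
        sm = smoothed.xyz[lo:hi]
        # include the step bridging from the previous bin so L is additive
        lo_step = max(lo - 1, 0)
        steps = np.diff(smoothed.xyz[lo_step:hi], axis=0)
        sub_e = for_explored.copy_with(t=for_explored.t[lo:hi], xyz=for_explored.xyz[lo:hi])
        out.append(
            FeatureVector(
                bottom_cm=float(point_plane_distance(sm, geometry.bottom_plane).mean()),
                center_cm=float(point_line_distance(sm, *geometry.center_line).mean()),
                distance_cm=float(np.linalg.norm(steps, axis=1).sum()) if len(steps) else 0.0,
                percent_explored=100.0
                * np.unique(_voxel_indices(sub_e, geometry)).size
                / geometry.n_voxels,
            )
        )
    return out


def extract_feature_table(
    traces: dict | list,
    geometry: TankGeometry,
    correction: DepthCorrection | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Extract features for many traces into a tidy table.

    ``traces`` is either a list of SwimTrace (fish_id/session taken from each
    trace) or a mapping ``(fish_id, session) -> SwimTrace``.
    Returns columns ``fish_id, session, bottom_cm, center_cm, distance_cm,
    percent_explored``.
    """
    if isinstance(traces, dict):
        items = [(fid, ses, tr) for (fid, ses), tr in traces.items()]
    else:
        items = [(tr.fish_id, tr.session, tr) for tr in traces]
    rows = []
    for fid, ses, tr in items:
        fv = extract_features(tr, geometry, correction=correction, **kwargs)
        rows.append(
            {
                "fish_id": fid,
                "session": ses,
                "bottom_cm": fv.bottom_cm,
                "center_cm": fv.center_cm,
                "distance_cm": fv.distance_cm,
                "percent_explored": fv.percent_explored,
            }
        )
    return pd.DataFrame(rows)
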