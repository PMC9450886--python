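"""Tank geometry: dimensions, bottom plane, center line, and the voxel grid.

The arena is a five-sided open-top acrylic cube (default 15 x 15 x 15 cm)
filled to ~11.1 cm with water.  Percent-explored discretizes the full tank
cube into ``voxel_counts`` evenly spaced boxes (default 10 x 10 x 10 = 1000),
so voxels above the waterline exist but are unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TankGeometry", "fit_bottom_plane", "point_plane_distance", "point_line_distance"]


def _unit_plane(a: float, b: float, c: float, d: float) -> tuple[float, float, float, float]:
    """Normalize plane coefficients so (a, b, c) has unit length and c >= 0.

    Orienting the normal toward positive z (the water volume) makes signed
    distances above the bottom positive.
    """
    n = float(np.hypot(np.hypot(a, b), c))
    if n == 0 or not np.isfinite(n):
        raise ValueError("degenerate plane normal")
    a, b, c, d = a / n, b / n, c / n, d / n
    if c < 0:
        a, b, c, d = -a, -b, -c, -d
    return (a, b, c, d)


@dataclass(frozen=True)
class TankGeometry:
    """Geometry of the novel-tank arena.

    Parameters
    ----------
    side : float
        Inner side length of the cubic tank, cm.
    water_depth : float
        Water column height, cm. 2.5 L over a 15 x 15 cm base gives 11.1 cm.
    bottom_plane : tuple of 4 floats
        ``(a, b, c, d)`` of the bottom plane ``ax + by + cz + d = 0`` with
        unit normal oriented into the water. Defaults to the ideal floor z=0.
    center_line : tuple of two 3-vectors
        Center-top and center-bottom points defining the vertical center line.
    voxel_counts : (nx, ny, nz)
        Voxel grid resolution for percent-explored; product is the voxel total.
    voxel_z_extent : float or None
        Vertical extent of the voxel grid. ``None`` (default) spans the full
        tank cube (``side``); set to ``water_depth`` to grid only the water.
    """

    side: float = 15.0
    water_depth: float = 11.1
    bottom_plane: tuple[float, float, float, float] = None  # type: ignore[assignment]
    center_line: tuple[tuple[float, float, float], tuple[float, float, float]] = None  # type: ignore[assignment]
    voxel_counts: tuple[int, int, int] = (10, 10, 10)
    voxel_z_extent: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.side) and self.side > 0):
            raise ValueError("side must be positive and finite")
        if not (np.isfinite(self.water_depth) and 0 < self.water_depth <= self.side):
            raise ValueError("water_depth must be in (0, side]")
        if self.bottom_plane is None:
            object.__setattr__(self, "bottom_plane", (0.0, 0.0, 1.0, 0.0))
        else:
            object.__setattr__(self, "bottom_plane", _unit_plane(*self.bottom_plane))
        if self.center_line is None:
            cx = cy = self.side / 2.0
            object.__setattr__(
                self, "center_line", ((cx, cy, self.water_depth), (cx, cy, 0.0))
            )
        top, bot = (np.asarray(p, dtype=float) for p in self.center_line)
        if np.allclose(top, bot):
            raise ValueError("center_line endpoints must differ")
        nx, ny, nz = self.voxel_counts
        if min(nx, ny, nz) < 1:
            raise ValueError("voxel_counts must be positive")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.voxel_counts
        return nx * ny * nz

    @property
    def voxel_grid_depth(self) -> float:
        return self.side if self.voxel_z_extent is None else float(self.voxel_z_extent)


def fit_bottom_plane(points: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares plane through >= 3 non-collinear 3D points.

    Fits ``z = alpha*x + beta*y + gamma`` by ordinary least squares (the
    floor is near-horizontal, so z-residual regression is appropriate) and
    returns unit-normal coefficients ``(a, b, c, d)`` of ``ax+by+cz+d = 0``
    oriented toward the water volume.

    Raises
    ------
    ValueError
        If fewer than 3 points or the points are collinear in the x-y plane.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 points of shape (n, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    xy = pts[:, :2] - pts[:, :2].mean(axis=0)
    # collinear in x-y -> the regression design is rank deficient
    sv = np.linalg.svd(xy, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("points are collinear; plane is not identifiable")
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    (alpha, beta, gamma), *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    # z = alpha x + beta y + gamma  ->  alpha x + beta y - z + gamma = 0
    return _unit_plane(alpha, beta, -1.0, gamma)


def point_plane_distance(points: np.ndarray, plane: tuple[float, float, float, float]) -> np.ndarray:
    """Unsigned distance of each point to a unit-normal plane, cm."""
    a, b, c, d = plane
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.abs(pts @ np.array([a, b, c]) + d)


def point_line_distance(points: np.ndarray, p0, p1) -> np.ndarray:
    """Perpendicular distance of each point to the (infinite) line through p0, p1."""
    p0 = np.asarray(p0, dtype=float)
    u = np.asarray(p1, dtype=float) - p0
    u = u / np.linalg.norm(u)
    v = np.atleast_2d(np.asarray(points, dtype=float)) - p0
    proj = np.outer(v @ u, u)
    return np.linalg.norm(v - proj, axis=1)
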