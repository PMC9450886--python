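"""The SwimTrace container: one fish-session's time-ordered 3D coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SwimTrace", "read_trace_csv", "write_trace_csv"]

TRACE_COLUMNS = ["frame", "t_s", "x_cm", "y_cm", "z_cm"]


@dataclass
class SwimTrace:
    """A single fish-session 3D swim trace.

    ``xyz`` is an (n, 3) float array in cm; missing depth readings are NaN in
    the z column (typically <1% of frames in real recordings, where the depth
    stream occasionally fails to return a point at the fish).
    """

    t: np.ndarray
    xyz: np.ndarray
    fps: float
    fish_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.t.ndim != 1 or self.xyz.ndim != 2 or self.xyz.shape != (self.t.size, 3):
            raise ValueError("t must be (n,) and xyz (n, 3)")
        if self.t.size < 2:
            raise ValueError("a trace needs at least 2 frames")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("frame times must be finite")
        if not np.all(np.isfinite(self.xyz[:, :2])):
            raise ValueError("x/y coordinates must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def missing_z_fraction(self) -> float:
        return float(np.isnan(self.xyz[:, 2]).mean())

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy_with(self, **kwargs) -> "SwimTrace":
        out = replace(self, **kwargs)
        out.t = out.t.copy() if "t" not in kwargs else out.t
        out.xyz = out.xyz.copy() if "xyz" not in kwargs else out.xyz
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "t_s": self.t,
                "x_cm": self.xyz[:, 0],
                "y_cm": self.xyz[:, 1],
                "z_cm": self.xyz[:, 2],
            }
        )


def read_trace_csv(path, fps: float | None = None, fish_id: str = "", session: str = "") -> SwimTrace:
    """Read a trace CSV with header ``frame,t_s,x_cm,y_cm,z_cm``.

    If ``fps`` is not given it is inferred from the median frame interval.
    """
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    t = df["t_s"].to_numpy(dtype=float)
    if fps is None:
        dt = np.median(np.diff(t))
        if not (np.isfinite(dt) and dt > 0):
            raise ValueError(f"cannot infer fps from {path}")
        fps = 1.0 / dt
    xyz = df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    return SwimTrace(t=t, xyz=xyz, fps=fps, fish_id=fish_id, session=session)


def write_trace_csv(trace: SwimTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
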