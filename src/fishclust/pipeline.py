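"""End-to-end pipeline: simulate -> extract -> cluster -> assign -> stats.

Ties the stages together with stable on-disk formats (all CSV/JSON/YAML,
diffable and desk-scale), a single root seed fanned out to every stage by
fixed offsets, and a run manifest that makes a run exactly reproducible.

File formats
------------
traces           ``<fish_id>_<session>.csv`` with header ``frame,t_s,x_cm,y_cm,z_cm``
metadata         ``fish_id,strain,sex,session``
calibration      ``z_air_cm,z_water_cm``
features         ``fish_id,session,bottom_cm,center_cm,distance_cm,percent_explored``
labels           ``fish_id,session,cluster``
model directory  ``params.json, edges.csv, labels.csv, reference.csv``
stats            tidy ``test,effect_or_cell,observed,p,p_adjusted,m,seed``
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import assign, fit, save_model
from .features import extract_feature_table, fit_depth_correction
from .geometry import TankGeometry
from .permstats import representation_test, two_day_overlap
from .simulate import CohortSpec, generate_calibration, generate_cohort, generate_feature_cohort
from .trace import read_trace_csv, write_trace_csv

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs", "load_config"]

log = logging.getLogger("fishclust")

STRAIN_VOCAB = {"AB", "TL", "TU", "WIK"}
SEX_VOCAB = {"F", "M"}

# fixed per-stage seed offsets fanned out from the root seed
_STAGE_OFFSET = {"simulate": 1, "calibration": 2, "cluster": 3, "stats": 4}


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run; defaults match the study constants.

    ``mode`` selects how the synthetic cohort is produced: ``"features"``
    draws feature vectors directly from the archetype Gaussians (fast);
    ``"traces"`` simulates full 3D swim traces and extracts features from
    them (slower, exercises the whole stack).
    """

    side: float = 15.0
    water_depth: float = 11.1
    fps: float = 30.0
    duration: float = 360.0
    smoothing_window: int = 7
    smoothing_order: int = 3
    voxel_counts: tuple[int, int, int] = (10, 10, 10)
    k: int | None = None
    similarity_form: str = "inverse"
    m_resamples: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    mode: str = "features"
    n_sessions: int = 2
    persistence: float = 0.6
    strain_sex_table: dict | None = None

    def geometry(self) -> TankGeometry:
        return TankGeometry(
            side=self.side,
            water_depth=self.water_depth,
            voxel_counts=tuple(self.voxel_counts),
        )

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(
            persistence=self.persistence,
            n_sessions=self.n_sessions,
            seed=self.seed + _STAGE_OFFSET["simulate"],
        )
        if self.strain_sex_table is not None:
            table = {
                (str(k).split(":")[0], str(k).split(":")[1]) if isinstance(k, str) else tuple(k): v
                for k, v in self.strain_sex_table.items()
            }
            kwargs["strain_sex_table"] = table
        return CohortSpec(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected to catch typos."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "voxel_counts" in raw:
        raw["voxel_counts"] = tuple(raw["voxel_counts"])
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    """Snapshot of a completed run: config, seeds, versions, per-stage counts."""

    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))


def _stats_rows(test, results, m, seed):
    rows = []
    for key, r in results.items():
        rows.append(
            {
                "test": test,
                "effect_or_cell": key,
                "observed": r.observed,
                "p": r.p,
                "p_adjusted": r.p_adjusted if r.p_adjusted is not None else np.nan,
                "m": m,
                "seed": seed,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Run the full workflow on a synthetic cohort and write all outputs.

    Stages: simulate a cohort (and, in trace mode, a depth calibration),
    extract or take features, fit the reference clustering on session 1,
    assign every later session with the reference model, then run the
    strain x sex representation test on session 1 and the session-1 vs
    session-2 percent-overlap permutation test. All intermediate tables are
    written under ``out_dir`` and summarized in ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed, version=__version__)
    geometry = config.geometry()
    spec = config.cohort_spec()

    if config.mode == "traces":
        traces, meta, truth = generate_cohort(
            spec, geometry, duration=config.duration, fps=config.fps
        )
        cal = generate_calibration(seed=config.seed + _STAGE_OFFSET["calibration"])
        pd.DataFrame(cal.pairs, columns=["z_air_cm", "z_water_cm"]).to_csv(
            out / "calibration.csv", index=False
        )
        correction = fit_depth_correction(cal)
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for tr in traces:
            write_trace_csv(tr, trace_dir / f"{tr.fish_id}_{tr.session}.csv")
        features = extract_feature_table(
            traces,
            geometry,
            correction=None,  # synthetic traces are already in true cm
            window=config.smoothing_window,
            order=config.smoothing_order,
        )
        manifest.stages["calibration"] = {
            "slope": correction.slope,
            "intercept": correction.intercept,
        }
    elif config.mode == "features":
        features, meta, truth = generate_feature_cohort(spec)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    meta.to_csv(out / "metadata.csv", index=False)
    truth.to_csv(out / "true_archetypes.csv", index=False)
    features.to_csv(out / "features.csv", index=False)
    manifest.stages["simulate"] = {"n_fish": int(meta["fish_id"].nunique()), "rows": len(meta)}
    manifest.stages["extract"] = {"rows": len(features)}

    sessions = sorted(features["session"].unique(), key=str)
    feats1 = features[features["session"] == sessions[0]].reset_index(drop=True)
    model = fit(
        feats1,
        k=config.k,
        seed=config.seed + _STAGE_OFFSET["cluster"],
        form=config.similarity_form,
    )
    save_model(model, out / "model")
    labels = model.labels_frame()
    labels.insert(1, "session", sessions[0])
    all_labels = [labels]
    for ses in sessions[1:]:
        fs = features[features["session"] == ses].reset_index(drop=True)
        lab = pd.DataFrame(
            {"fish_id": fs["fish_id"], "session": ses, "cluster": assign(model, fs)}
        )
        all_labels.append(lab)
    labels_df = pd.concat(all_labels, ignore_index=True)
    labels_df.to_csv(out / "labels.csv", index=False)
    manifest.stages["cluster"] = {
        "k": model.k,
        "n_communities": model.n_communities,
        "n_min": model.n_min,
        "m_assign": model.m_assign,
    }

    # statistics: representation on session 1, two-session percent overlap
    stats_seed = config.seed + _STAGE_OFFSET["stats"]
    meta1 = meta[meta["session"] == sessions[0]].reset_index(drop=True)
    merged = meta1.merge(labels_df[labels_df["session"] == sessions[0]], on=["fish_id", "session"])
    rep = representation_test(
        merged["strain"] + ":" + merged["sex"],
        merged["cluster"],
        m=config.m_resamples,
        seed=stats_seed,
    )
    rep.to_csv(out / "representation.csv", index=False)
    stats_rows = [
        {
            "test": "representation",
            "effect_or_cell": f"{r.group}|{r.cluster}",
            "observed": r.count,
            "p": r.p,
            "p_adjusted": r.p_adjusted,
            "m": config.m_resamples,
            "seed": stats_seed,
        }
        for r in rep.itertuples()
    ]
    if len(sessions) >= 2:
        wide = labels_df.pivot(index="fish_id", columns="session", values="cluster")
        pct, res = two_day_overlap(
            wide[sessions[0]].to_numpy(),
            wide[sessions[1]].to_numpy(),
            m=config.m_resamples,
            seed=stats_seed,
        )
        stats_rows.append(
            {
                "test": "two_day_overlap",
                "effect_or_cell": "percent_overlap",
                "observed": pct,
                "p": res.p,
                "p_adjusted": np.nan,
                "m": config.m_resamples,
                "seed": stats_seed,
            }
        )
        manifest.stages["overlap"] = {
            "percent_overlap": pct,
            "null_mean_percent": res.extra["null_mean_percent"],
            "p": res.p,
        }
    pd.DataFrame(stats_rows).to_csv(out / "stats.csv", index=False)
    manifest.stages["stats"] = {"rows": len(stats_rows)}
    manifest.write(out / "manifest.json")
    return manifest


def validate_inputs(paths: dict) -> list[dict]:
    """Report-only validation of input files; returns a list of issue records.

    ``paths`` may contain ``traces`` (directory of trace CSVs), ``meta``
    (metadata CSV), ``features``, ``labels``, ``calibration``. Checks CSV
    headers, strictly increasing time, strain/sex vocabulary (with
    whitespace-normalization warnings), and lists fish with missing sessions
    (mirroring the exclusion of incompletely recorded videos).
    """
    issues: list[dict] = []

    def add(file, kind, detail):
        issues.append({"file": str(file), "issue": kind, "detail": detail})

    meta = None
    if "meta" in paths:
        meta_path = Path(paths["meta"])
        try:
            meta = pd.read_csv(meta_path)
        except Exception as e:  # noqa: BLE001 - report, don't raise
            add(meta_path, "unreadable", str(e))
        else:
            need = {"fish_id", "strain", "sex", "session"}
            missing = need - set(meta.columns)
            if missing:
                add(meta_path, "missing_columns", sorted(missing))
                meta = None
            else:
                for col, vocab in (("strain", STRAIN_VOCAB), ("sex", SEX_VOCAB)):
                    raw = meta[col].astype(str)
                    stripped = raw.str.strip()
                    if (raw != stripped).any():
                        add(meta_path, "whitespace_normalized", f"{col} values had surrounding whitespace")
                    bad = sorted(set(stripped) - vocab)
                    if bad:
                        add(meta_path, "unknown_vocabulary", {col: bad})
                sessions = set(meta["session"].astype(str))
                per_fish = meta.groupby("fish_id")["session"].apply(
                    lambda s: set(s.astype(str))
                )
                incomplete = {f: sorted(sessions - s) for f, s in per_fish.items() if s != sessions}
                if incomplete:
                    add(meta_path, "missing_sessions", incomplete)

    if "traces" in paths:
        tdir = Path(paths["traces"])
        files = sorted(tdir.glob("*.csv")) if tdir.is_dir() else []
        if not files:
            add(tdir, "no_trace_files", "directory missing or empty")
        for f in files:
            try:
                df = pd.read_csv(f)
            except Exception as e:  # noqa: BLE001
                add(f, "unreadable", str(e))
                continue
            need = {"frame", "t_s", "x_cm", "y_cm", "z_cm"}
            missing = need - set(df.columns)
            if missing:
                add(f, "missing_columns", sorted(missing))
                continue
            t = df["t_s"].to_numpy(dtype=float)
            bad = np.flatnonzero(np.diff(t) <= 0)
            if bad.size:
                add(f, "non_monotone_time", {"first_bad_row": int(bad[0] + 1)})

    for key, need in (
        ("features", {"fish_id", "session", "bottom_cm", "center_cm", "distance_cm", "percent_explored"}),
        ("labels", {"fish_id", "session", "cluster"}),
        ("calibration", {"z_air_cm", "z_water_cm"}),
    ):
        if key in paths:
            fpath = Path(paths[key])
            try:
                df = pd.read_csv(fpath)
            except Exception as e:  # noqa: BLE001
                add(fpath, "unreadable", str(e))
                continue
            missing = need - set(df.columns)
            if missing:
                add(fpath, "missing_columns", sorted(missing))
    return issues
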