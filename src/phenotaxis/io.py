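"""Configuration files, tabular interchange formats, and the end-to-end
pipeline runner.

All interchange is delimited text (CSV with header).  Units are fixed
package-wide: positions in um, times in s, concentrations in mM, protein
counts in molecules/cell; frame indices are 1-based within a movie.  Every
run writes a manifest recording the configuration snapshot, the root seed,
the package version, and SHA-256 digests of the outputs, from which the
run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    WT_TB_BINS,
    jensen_compare,
    kymograph,
    mean_position_by_bin,
    performance_map,
)
from .classify import classify_frames
from .environment import Chamber, GradientSpec
from .expression import ExpressionConfig
from .microscope import build_plan, filter_tracks, observe, summarize_tracks
from .motility import MotorParams
from .signaling import PathwayParams
from .simulator import SimConfig, simulate_population

__all__ = [
    "load_config",
    "dump_config",
    "read_tracks",
    "write_tracks",
    "read_frames",
    "write_frames",
    "run_pipeline",
]

FRAME_COLUMNS = [
    "track_id",
    "cell_id",
    "sweep",
    "field",
    "frame",
    "t",
    "x",
    "y",
    "true_tumble",
]
TRACK_COLUMNS = [
    "track_id",
    "cell_id",
    "sweep",
    "field",
    "n_frames",
    "duration",
    "mean_speed",
    "mean_run_speed",
    "max_msd",
    "tb",
    "mean_x",
    "true_tb",
]

_SECTIONS = {
    "expression": ExpressionConfig,
    "pathway": PathwayParams,
    "motor": MotorParams,
    "chamber": Chamber,
    "gradient": GradientSpec,
}


def load_config(path: str | Path) -> SimConfig:
    """Parse a YAML configuration into a validated SimConfig.

    The file holds one block per module (expression, pathway, motor,
    chamber, gradient) plus top-level simulation keys; every key is
    optional and overrides the package default.  Validation failures name
    the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for section, cls in _SECTIONS.items():
        block = raw.pop(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - valid
        if unknown:
            raise ValueError(f"{section}: unknown keys {sorted(unknown)}")
        try:
            kwargs[section] = cls(**block)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{section}: {err}") from err
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown top-level keys {sorted(unknown)}")
    cfg = SimConfig(**kwargs, **raw)
    cfg.validate()
    return cfg


def dump_config(cfg: SimConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["gradient"].pop("custom_fn", None)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def _read_table(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} is missing columns {missing}")
    return df


def read_frames(path: str | Path) -> pd.DataFrame:
    return _read_table(path, FRAME_COLUMNS, "frame")


def write_frames(frames: pd.DataFrame, path: str | Path) -> None:
    frames.to_csv(path, index=False)


def read_tracks(path: str | Path, require_tb: bool = True) -> pd.DataFrame:
    cols = TRACK_COLUMNS if require_tb else [c for c in TRACK_COLUMNS if c != "tb"]
    return _read_table(path, cols, "track")


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    observation: dict | None = None,
    tb_edges: np.ndarray = WT_TB_BINS,
) -> Path:
    """Execute simulate -> observe -> classify -> filter -> analyze.

    Writes trajectories (per-cell table + observed frames), classified and
    filtered tracks, the mean-position series, the performance map, the
    Jensen comparison, the kymograph table, and a manifest.  Partial
    outputs are removed on failure.
    """
    if not isinstance(config, SimConfig):
        config = load_config(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        traj = simulate_population(config)
        plan = build_plan(config.chamber, config.duration, **(observation or {}))
        frames = observe(traj, plan)
        labels = classify_frames(frames, fps=plan.fps, seed=config.seed or 0)
        tracks = summarize_tracks(frames, labels, fps=plan.fps)
        kept = filter_tracks(tracks)
        frames_kept = frames[frames["track_id"].isin(kept["track_id"])]

        traj.cells.to_csv(out / "cells.csv", index=False)
        write_frames(frames.assign(state=labels), out / "frames.csv")
        write_tracks(kept, out / "tracks.csv")
        mean_position_by_bin(frames_kept, kept, plan, tb_edges).to_csv(
            out / "mean_position.csv", index=False
        )
        pmap = performance_map(frames_kept, kept, plan)
        pd.DataFrame(
            pmap.phi, index=pmap.sweep_times, columns=pmap.bin_centers
        ).to_csv(out / "performance_map.csv")
        jensen_compare(frames_kept, kept, plan).to_csv(
            out / "jensen.csv", index=False
        )
        kymo_table, *_ = kymograph(frames_kept, plan)
        kymo_table.to_csv(out / "kymograph.csv", index=False)
        dump_config(config, out / "config.yaml")

        outputs = sorted(p.name for p in out.iterdir() if p.suffix == ".csv")
        manifest = {
            "package": "phenotaxis",
            "version": __version__,
            "seed": config.seed,
            "created": datetime.now(timezone.utc).isoformat(),
            "config": "config.yaml",
            "digests": {name: _sha256(out / name) for name in outputs},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out
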