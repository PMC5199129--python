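"""Shared fixtures: desk-scale simulations reused across test modules.

The expensive population runs (wild-type race, synchronized control,
low/high-CheR conditions) are session-scoped so the whole suite pays for
each condition once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenotaxis.analysis import WT_TB_BINS, mean_position_by_bin
from phenotaxis.classify import classify_frames
from phenotaxis.microscope import build_plan, filter_tracks, observe, summarize_tracks
from phenotaxis.presets import preset
from phenotaxis.simulator import simulate_control, simulate_population

RACE_SEED = 7
CONTROL_SEED = 11
LOW_SEED = 101
HIGH_SEED = 102


def run_pipeline_for(name: str, n_cells: int, duration: float, seed: int) -> dict:
    """Simulate one condition and run the observation/classification/
    filtering pipeline; returns all intermediate products."""
    cfg = preset(name, n_cells=n_cells, duration=duration, seed=seed)
    traj = simulate_population(cfg)
    plan = build_plan(cfg.chamber, cfg.duration)
    frames = observe(traj, plan)
    labels = classify_frames(frames, fps=plan.fps, seed=0)
    tracks = summarize_tracks(frames, labels, fps=plan.fps)
    kept = filter_tracks(tracks)
    frames_kept = frames[frames["track_id"].isin(kept["track_id"])]
    return {
        "config": cfg,
        "traj": traj,
        "plan": plan,
        "frames": frames,
        "labels": labels,
        "tracks": tracks,
        "kept": kept,
        "frames_kept": frames_kept,
    }


@pytest.fixture(scope="session")
def race():
    """Reduced wild-type gradient race: 1,000 cells, ~47 min (five sweeps,
    the last centered near 42.5 min)."""
    out = run_pipeline_for("wt-gradient", n_cells=1000, duration=2840.0, seed=RACE_SEED)
    out["series"] = mean_position_by_bin(
        out["frames_kept"], out["kept"], out["plan"], WT_TB_BINS
    )
    return out


@pytest.fixture(scope="session")
def control_table():
    """Synchronized-internal-state control in the 0.1 mM/mm gradient."""
    cfg = preset("control", n_cells=500, duration=2700.0, seed=CONTROL_SEED)
    return simulate_control(cfg)


@pytest.fixture(scope="session")
def low_pipeline():
    """Low-CheR (10 uM IPTG analog) gradient condition, 400 cells."""
    return run_pipeline_for("cheR-low", n_cells=400, duration=2840.0, seed=LOW_SEED)


@pytest.fixture(scope="session")
def high_pipeline():
    """High-CheR (100 uM IPTG analog) gradient condition, 400 cells."""
    return run_pipeline_for("cheR-high", n_cells=400, duration=2840.0, seed=HIGH_SEED)


@pytest.fixture(scope="session")
def pooled(low_pipeline, high_pipeline):
    """Low + high CheR conditions pooled (the map-building union)."""
    offset = int(low_pipeline["kept"]["track_id"].max()) + 1
    frames_hi = high_pipeline["frames_kept"].copy()
    frames_hi["track_id"] += offset
    kept_hi = high_pipeline["kept"].copy()
    kept_hi["track_id"] += offset
    frames = pd.concat([low_pipeline["frames_kept"], frames_hi], ignore_index=True)
    kept = pd.concat([low_pipeline["kept"], kept_hi], ignore_index=True)
    return {"frames": frames, "kept": kept, "plan": low_pipeline["plan"]}
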