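"""Kinematic features, three-state clustering, and tumble-bias recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenotaxis.classify import (
    INTERMEDIATE,
    RUN,
    TUMBLE,
    classify_frames,
    classify_states,
    kinematic_features,
    tumble_bias,
)
from phenotaxis.microscope import build_plan, observe, summarize_tracks
from phenotaxis.presets import preset
from phenotaxis.simulator import simulate_population

FPS = 8.78


def test_features_constant_velocity_track():
    t = np.arange(40) / FPS
    x = 25.0 * t
    y = np.full_like(t, 3.0)
    f = kinematic_features(x, y, FPS)
    assert np.allclose(f[:, 0], 25.0)
    assert np.allclose(f[1:-1, 1], 0.0)
    assert np.allclose(f[1:-1, 2], 0.0, atol=1e-9)


def test_features_alternating_velocity():
    """Position bouncing +/-v each frame gives acceleration 2 v fps."""
    v = 10.0
    n = 30
    x = np.zeros(n)
    x[1::2] = v / FPS  # alternates 0, v/fps, 0, ...
    f = kinematic_features(x, np.zeros(n), FPS)
    assert np.allclose(f[:, 0], v)
    assert np.allclose(f[2:-2, 1], 2 * v * FPS, rtol=1e-9)


def test_features_circular_motion():
    """Uniform circular motion: acceleration is the centripetal v*omega,
    angular acceleration zero (constant heading-change rate)."""
    omega = 1.2
    R = 20.0
    t = np.arange(60) / FPS
    x = R * np.cos(omega * t)
    y = R * np.sin(omega * t)
    f = kinematic_features(x, y, FPS)
    v_chord = 2 * R * np.sin(omega / (2 * FPS)) * FPS  # discrete-step speed
    assert np.allclose(f[5:-5, 0], v_chord, rtol=1e-6)
    assert np.allclose(f[5:-5, 1], v_chord * 2 * FPS * np.sin(omega / (2 * FPS)),
                       rtol=1e-3)
    assert np.allclose(f[5:-5, 2], 0.0, atol=1e-6)


def test_feature_extraction_requires_three_frames():
    with pytest.raises(ValueError):
        kinematic_features(np.zeros(2), np.zeros(2), FPS)


def test_synthetic_run_tumble_run_is_segmented():
    """50 straight frames, 5 stalled frames with a heading flip, 50 more
    straight frames: the stalled stretch is labeled tumble (allowing one
    frame of slack at each boundary as intermediate)."""
    rng = np.random.default_rng(0)
    v = 25.0 / FPS
    seg1 = np.cumsum(np.full(50, v))
    seg2 = np.full(5, seg1[-1]) + rng.normal(0, 0.02, 5)
    seg3 = seg2[-1] - np.cumsum(np.full(50, v))  # departs the other way
    x = np.concatenate([seg1, seg2, seg3])
    y = rng.normal(0, 0.02, len(x))
    feats = kinematic_features(x, y, FPS)
    labels = classify_states(feats, seed=0)
    assert np.all(labels[51:54] == TUMBLE)
    assert np.all(labels[2:48] != TUMBLE)
    assert np.all(labels[57:-2] != TUMBLE)


def test_degenerate_features_label_everything_run():
    feats = np.ones((100, 3))
    assert np.all(classify_states(feats, seed=0) == RUN)


def test_classification_invariant_to_rotation_and_translation():
    rng = np.random.default_rng(1)
    n = 400
    x = np.cumsum(rng.choice([0.0, 25.0 / FPS], n, p=[0.15, 0.85]))
    y = rng.normal(0, 0.05, n).cumsum()
    feats_a = kinematic_features(x, y, FPS)
    c, s = np.cos(1.1), np.sin(1.1)
    xr = c * x - s * y + 4_000.0
    yr = s * x + c * y - 120.0
    feats_b = kinematic_features(xr, yr, FPS)
    np.testing.assert_allclose(feats_a, feats_b, atol=1e-8)
    np.testing.assert_array_equal(
        classify_states(feats_a, seed=3), classify_states(feats_b, seed=3)
    )


def test_tumble_bias_arithmetic():
    assert tumble_bias(np.zeros(100, dtype=int)) == 0.0
    states = np.zeros(527, dtype=int)
    states[10] = TUMBLE
    assert tumble_bias(states) == pytest.approx(1 / 527)
    states = np.full(527, INTERMEDIATE)
    assert tumble_bias(states) == 0.0  # intermediate only dilutes
    with pytest.raises(ValueError):
        tumble_bias(np.array([]))


def test_run_only_tracks_have_negligible_tumble_fraction():
    """A CheY-less population provides no tumble signal; fewer than 1% of
    frames may be labeled tumble."""
    cfg = preset("delta-cheY", n_cells=25, duration=600.0, seed=17)
    traj = simulate_population(cfg)
    plan = build_plan(cfg.chamber, cfg.duration)
    frames = observe(traj, plan)
    labels = classify_frames(frames, fps=plan.fps, seed=0)
    assert (labels == TUMBLE).mean() < 0.01


@pytest.fixture(scope="module")
def uniform_recovery():
    """Uniform-environment wild-type population for recovery checks."""
    cfg = preset("wt-diffusion", n_cells=80, duration=620.0, seed=23)
    traj = simulate_population(cfg)
    plan = build_plan(cfg.chamber, cfg.duration, n_fields=4, span=4_500.0)
    frames = observe(traj, plan)
    labels = classify_frames(frames, fps=plan.fps, seed=0)
    tracks = summarize_tracks(frames, labels, fps=plan.fps)
    return traj, tracks


def test_classifier_recovers_ground_truth_tb(uniform_recovery):
    """On near-full-movie tracks the classified tumble bias matches the
    ground-truth labels with MAE <= 0.02 and no systematic bias."""
    _, tracks = uniform_recovery
    long = tracks[tracks["n_frames"] >= 500]
    assert len(long) >= 20
    err = long["tb"] - long["true_tb"]
    assert err.abs().mean() <= 0.02
    assert abs(err.mean()) <= 0.01


def test_estimated_tb_tracks_unstimulated_tb_without_noise():
    """With adaptation noise off, the classified tumble bias of long
    uniform-environment tracks recovers each cell's analytic unstimulated
    tumble bias."""
    cfg = preset("wt-diffusion", n_cells=100, duration=1_200.0, seed=29)
    cfg.pathway = replace(cfg.pathway, sigma_m=0.0)
    traj = simulate_population(cfg)
    plan = build_plan(cfg.chamber, cfg.duration, n_fields=4, span=4_500.0)
    frames = observe(traj, plan)
    labels = classify_frames(frames, fps=plan.fps, seed=0)
    tracks = summarize_tracks(frames, labels, fps=plan.fps)
    long = tracks[tracks["n_frames"] >= 500]
    # aggregate each cell's movies (a single 60-s window is limited by the
    # ~0.03 sampling noise of the tumble process itself)
    per_cell = (
        long.assign(w=long["n_frames"] * long["tb"])
        .groupby("cell_id")
        .agg(total=("n_frames", "sum"), wtb=("w", "sum"))
    )
    per_cell["tb"] = per_cell["wtb"] / per_cell["total"]
    per_cell = per_cell.join(traj.cells.set_index("cell_id")["unstim_tb"])
    per_cell = per_cell[per_cell["total"] >= 1_500]
    assert len(per_cell) >= 15
    err = per_cell["tb"] - per_cell["unstim_tb"]
    assert err.abs().mean() <= 0.02
    assert abs(err.mean()) <= 0.01
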