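"""Population statistics: binned positions, counting, the performance map,
Jensen comparison, and gamma-population predictions."""

import numpy as np
import pandas as pd
import pytest

from phenotaxis.analysis import (
    LOW_TB_BINS,
    WT_TB_BINS,
    PerformanceMap,
    estimate_cell_count,
    gamma_mean_sd,
    jensen_compare,
    kymograph,
    mean_position_by_bin,
    performance_map,
    predict_population_performance,
)
from phenotaxis.environment import Chamber
from phenotaxis.microscope import build_plan


@pytest.fixture
def plan():
    return build_plan(Chamber(), duration=1_200.0)


def _toy_tables(tb_by_track, xs_by_track, sweep=0):
    frames, tracks = [], []
    for tid, (tb, xs) in enumerate(zip(tb_by_track, xs_by_track)):
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        frames.append(
            pd.DataFrame(
                {"track_id": tid, "cell_id": tid, "sweep": sweep, "field": 0,
                 "frame": np.arange(1, len(xs) + 1), "t": 0.0, "x": xs,
                 "y": 500.0, "true_tumble": False}
            )
        )
        tracks.append({"track_id": tid, "tb": tb})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(tracks)


def test_mean_position_simple_arithmetic(plan):
    frames, tracks = _toy_tables([0.05, 0.05], [[100.0], [300.0]])
    out = mean_position_by_bin(frames, tracks, plan, WT_TB_BINS)
    assert out[out["bin"] == 0]["mean_x"].iloc[0] == pytest.approx(200.0)


def test_mean_position_stationary_population(plan):
    frames, tracks = _toy_tables([0.05, 0.2, 0.3], [[500.0] * 4] * 3)
    out = mean_position_by_bin(frames, tracks, plan, WT_TB_BINS)
    assert np.allclose(out["mean_x"], 500.0)


def test_mean_position_invariant_to_track_relabeling(plan):
    frames, tracks = _toy_tables([0.05, 0.2], [[100.0, 200.0], [900.0]])
    out1 = mean_position_by_bin(frames, tracks, plan, WT_TB_BINS)
    shuffled_f = frames.assign(track_id=frames["track_id"].map({0: 7, 1: 3}))
    shuffled_t = tracks.assign(track_id=tracks["track_id"].map({0: 7, 1: 3}))
    out2 = mean_position_by_bin(shuffled_f, shuffled_t, plan, WT_TB_BINS)
    pd.testing.assert_frame_equal(out1, out2)


def test_fractional_cell_counting():
    frames, _ = _toy_tables([0.1], [np.linspace(0, 100, 527)])
    assert estimate_cell_count(frames) == pytest.approx(1.0)
    # two half-movie tracks also count as one cell
    frames2, _ = _toy_tables([0.1, 0.1], [np.zeros(264), np.zeros(263)])
    assert estimate_cell_count(frames2) == pytest.approx(1.0)
    assert estimate_cell_count(frames.iloc[:0]) == 0.0
    # additive over disjoint sets
    assert estimate_cell_count(pd.concat([frames, frames2])) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        estimate_cell_count(frames, frames_per_movie=0)


def test_kymograph_conserves_cell_equivalents(plan, race):
    table, grid_t, grid_x, matrix = kymograph(race["frames_kept"], plan)
    per_movie = table.groupby(["sweep", "field"])["cell_equiv"].sum()
    counts = race["frames_kept"].groupby(["sweep", "field"]).size() / 527
    for key, expect in counts.items():
        assert per_movie[key] == pytest.approx(expect, rel=1e-9)
    assert matrix.shape == (len(grid_t), len(grid_x))


def test_performance_map_bins_and_suppression(plan):
    # 50 identical tracks at tb = 0.1, x = 1000: one populated bin
    frames, tracks = _toy_tables([0.1] * 50, [[1_000.0]] * 50)
    pmap = performance_map(frames, tracks, plan, min_cells=45, frames_per_movie=1)
    assert pmap.bin_centers[0] == pytest.approx(0.0025)
    populated = np.isfinite(pmap.phi[0])
    assert populated.sum() == 1
    assert pmap.phi[0][populated][0] == pytest.approx(1_000.0)
    # 44 cell-equivalents fall below the plotting threshold
    frames44, tracks44 = _toy_tables([0.1] * 44, [[1_000.0]] * 44)
    pmap44 = performance_map(frames44, tracks44, plan, min_cells=45,
                             frames_per_movie=1)
    assert not np.isfinite(pmap44.phi).any()


def test_jensen_degenerate_single_phenotype(plan):
    frames, tracks = _toy_tables([0.1] * 6, [[700.0]] * 6)
    out = jensen_compare(frames, tracks, plan)
    assert out["mean_performance"].iloc[0] == pytest.approx(
        out["phi_of_mean"].iloc[0]
    )


def test_jensen_toy_convex_map_direct_arithmetic():
    """Two phenotypes at tb 0.01 and 0.2 with performance 1/tb: the
    population mean performance beats the performance of the mean
    phenotype, by direct evaluation of the convex map."""
    tb = np.array([0.01, 0.2])
    phi = lambda t: 1.0 / t
    e_phi = phi(tb).mean()
    phi_e = phi(tb.mean())
    assert e_phi == pytest.approx(52.5)
    assert phi_e == pytest.approx(9.5238, rel=1e-4)
    assert e_phi > phi_e


def _map_from_function(fn, sweep_times=(100.0,), width=0.005, tb_max=0.5):
    centers = np.arange(width / 2, tb_max, width)
    phi = np.tile(fn(centers), (len(sweep_times), 1))
    return PerformanceMap(
        sweep_times=np.asarray(sweep_times), bin_centers=centers,
        bin_width=width, phi=phi, cell_equiv=np.full_like(phi, 1e9),
        min_cells=0,
    )


def test_gamma_parameter_arithmetic():
    means = [gamma_mean_sd(k, th)[0] for k, th in
             [(36, 4.17e-3), (16, 6.25e-3), (4, 0.0125)]]
    sds = [gamma_mean_sd(k, th)[1] for k, th in
           [(36, 4.17e-3), (16, 6.25e-3), (4, 0.0125)]]
    assert means[0] == pytest.approx(0.15, abs=2e-4)
    assert means[1] == pytest.approx(0.10)
    assert means[2] == pytest.approx(0.05)
    assert np.allclose(sds, 0.025, atol=2e-5)
    assert gamma_mean_sd(1, 0.05) == (pytest.approx(0.05), pytest.approx(0.05))


def test_affine_map_prediction_is_exact():
    """For an affine performance map the gamma prediction equals
    a + b*k*theta independent of the distribution shape (Jensen equality)."""
    a, b = 100.0, 50.0
    pmap = _map_from_function(lambda t: a + b * t)
    pred = predict_population_performance(pmap, 36, 4.17e-3)
    assert pred["prediction"].iloc[0] == pytest.approx(a + b * 36 * 4.17e-3,
                                                       rel=1e-9)


def test_convex_map_prediction_obeys_jensen():
    """On a convex map the prediction dominates the map at the mean, and a
    wider equal-mean distribution predicts higher performance."""
    fn = lambda t: 4_000.0 * np.exp(-t / 0.04)  # convex, decreasing
    pmap = _map_from_function(fn)
    wide = predict_population_performance(pmap, 1, 0.05)["prediction"].iloc[0]
    narrow = predict_population_performance(pmap, 4, 0.0125)["prediction"].iloc[0]
    mid = predict_population_performance(pmap, 16, 6.25e-3)["prediction"].iloc[0]
    tight = predict_population_performance(pmap, 36, 4.17e-3)["prediction"].iloc[0]
    assert wide > narrow > mid > tight  # equal means, decreasing spread
    assert narrow > fn(4 * 0.0125)  # strict Jensen gain over phi(mean)


def test_prediction_rejects_uncovered_gamma_mass():
    pmap = _map_from_function(lambda t: 1_000.0 - t, tb_max=0.05)
    with pytest.raises(ValueError, match="mass"):
        predict_population_performance(pmap, 36, 4.17e-3)


def test_low_tb_bin_edges_prepend_low_induction_categories():
    assert LOW_TB_BINS[0] == 0.0
    assert LOW_TB_BINS[1] == pytest.approx(0.005)  # 0-1 tumbles/min
    assert LOW_TB_BINS[2] == pytest.approx(0.05)  # 2-26 tumbles/min
    assert WT_TB_BINS[-1] == 0.5
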