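"""Population-level analysis: tumble-bias binning, mean position over
time, kymographs, fractional cell counting, the empirical
phenotype-to-performance map phi_t(TB), the Jensen comparison
E[phi(TB)] vs phi(E[TB]), and performance prediction for hypothetical
(gamma-distributed) tumble-bias populations.

All position statistics weight every observed sample equally, mirroring
the fractional cell-counting convention in which one frame of observation
is 1/n-th of a cell (n = frames per movie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .microscope import FRAMES_PER_MOVIE, AcquisitionPlan

__all__ = [
    "WT_TB_BINS",
    "LOW_TB_BINS",
    "PerformanceMap",
    "mean_position_by_bin",
    "kymograph",
    "estimate_cell_count",
    "performance_map",
    "jensen_compare",
    "predict_population_performance",
    "gamma_mean_sd",
]

#: four equally spaced tumble-bias bins on [0, 0.5] (wild-type analysis)
WT_TB_BINS = np.array([0.0, 0.125, 0.25, 0.375, 0.5])
#: low-CheR analysis prepends the 0-1 and 2-26 tumbles/min categories
LOW_TB_BINS = np.array([0.0, 0.005, 0.05, 0.125, 0.25, 0.375, 0.5])


def _join_tb(frames: pd.DataFrame, tracks: pd.DataFrame) -> pd.DataFrame:
    tb = tracks.set_index("track_id")["tb"]
    out = frames.copy()
    out["tb"] = out["track_id"].map(tb)
    return out.dropna(subset=["tb"])


def mean_position_by_bin(
    frames: pd.DataFrame,
    tracks: pd.DataFrame,
    plan: AcquisitionPlan,
    edges: np.ndarray = WT_TB_BINS,
) -> pd.DataFrame:
    """Mean position of each tumble-bias bin per sweep.

    Every observed sample is weighted equally; the time coordinate is the
    sweep midpoint; the spread column is two standard errors of the mean.
    Empty (bin, sweep) combinations are omitted.
    Columns: sweep, t_mid, bin, bin_lo, bin_hi, mean_x, sem2, n_samples.
    """
    df = _join_tb(frames, tracks)
    df = df[(df["tb"] >= edges[0]) & (df["tb"] <= edges[-1])]
    df["bin"] = np.clip(np.digitize(df["tb"], edges) - 1, 0, len(edges) - 2)
    mids = plan.sweep_midpoints()
    rows = []
    for (sweep, b), g in df.groupby(["sweep", "bin"]):
        xs = g["x"].to_numpy()
        rows.append(
            {
                "sweep": sweep,
                "t_mid": mids[sweep],
                "bin": b,
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "mean_x": xs.mean(),
                "sem2": 2.0 * xs.std(ddof=1) / np.sqrt(len(xs)) if len(xs) > 1 else np.nan,
                "n_samples": len(xs),
            }
        )
    # whole-population series under bin = -1
    for sweep, g in df.groupby("sweep"):
        xs = g["x"].to_numpy()
        rows.append(
            {
                "sweep": sweep,
                "t_mid": mids[sweep],
                "bin": -1,
                "bin_lo": edges[0],
                "bin_hi": edges[-1],
                "mean_x": xs.mean(),
                "sem2": 2.0 * xs.std(ddof=1) / np.sqrt(len(xs)) if len(xs) > 1 else np.nan,
                "n_samples": len(xs),
            }
        )
    return pd.DataFrame(rows).sort_values(["sweep", "bin"]).reset_index(drop=True)


def kymograph(
    frames: pd.DataFrame,
    plan: AcquisitionPlan,
    n_regions: int = 5,
    frames_per_movie: int = FRAMES_PER_MOVIE,
):
    """Cell density over space and time.

    Each movie is split into ``n_regions`` equal spatial sub-regions;
    density is cell-equivalents (observed samples / frames_per_movie) per
    um of chamber axis.  The raw (time, position, density) samples are then
    linearly interpolated onto a regular space-time grid; grid nodes
    outside the convex hull of observations are NaN (unobserved).

    Returns (table, grid_t, grid_x, matrix).
    """
    rows = []
    for (sweep, fld), g in frames.groupby(["sweep", "field"]):
        lo, hi = plan.field_bounds[fld]
        region_edges = np.linspace(lo, hi, n_regions + 1)
        t0, t1 = plan.movie_window(sweep, fld)
        counts, _ = np.histogram(g["x"].to_numpy(), bins=region_edges)
        width = (hi - lo) / n_regions
        for r in range(n_regions):
            rows.append(
                {
                    "sweep": sweep,
                    "field": fld,
                    "region": r,
                    "t": 0.5 * (t0 + t1),
                    "x": 0.5 * (region_edges[r] + region_edges[r + 1]),
                    "density": counts[r] / frames_per_movie / width,
                    "cell_equiv": counts[r] / frames_per_movie,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, np.array([]), np.array([]), np.zeros((0, 0))
    from scipy.interpolate import griddata

    grid_t = np.unique(table["t"])
    grid_x = np.unique(table["x"])
    tt, xx = np.meshgrid(grid_t, grid_x, indexing="ij")
    matrix = griddata(
        table[["t", "x"]].to_numpy(),
        table["density"].to_numpy(),
        (tt, xx),
        method="linear",
    )
    return table, grid_t, grid_x, matrix


def estimate_cell_count(
    frames_or_tracks: pd.DataFrame, frames_per_movie: int = FRAMES_PER_MOVIE
) -> float:
    """Fractional cell counting: total observed samples / frames per movie.

    A track observed for a whole movie counts as one cell; additive over
    disjoint track sets.
    """
    if frames_per_movie <= 0:
        raise ValueError("frames_per_movie must be > 0")
    if "n_frames" in frames_or_tracks.columns:
        total = int(frames_or_tracks["n_frames"].sum())
    else:
        total = len(frames_or_tracks)
    return total / frames_per_movie


@dataclass
class PerformanceMap:
    """Empirical phi_t(TB): mean distance past the gate per (tb bin, sweep).

    phi is NaN where the cell-equivalent count is below min_cells.
    """

    sweep_times: np.ndarray  # s, sweep midpoints
    bin_centers: np.ndarray
    bin_width: float
    phi: np.ndarray  # (n_sweeps, n_bins) mean x in um
    cell_equiv: np.ndarray  # (n_sweeps, n_bins)
    min_cells: float


def performance_map(
    frames: pd.DataFrame,
    tracks: pd.DataFrame,
    plan: AcquisitionPlan,
    tb_bin_width: float = 0.005,
    min_cells: float = 45.0,
    tb_max: float = 0.5,
    frames_per_movie: int = FRAMES_PER_MOVIE,
) -> PerformanceMap:
    """Build phi_t(TB) from (possibly pooled) observed tracks.

    Tumble bias is binned at uniform width from zero, so the lowest bin
    center is half a width (0.0025 at the default width).  Points with
    fewer than ``min_cells`` cell-equivalents are suppressed (NaN).
    To pool conditions, concatenate their frame/track tables first.
    """
    df = _join_tb(frames, tracks)
    edges = np.arange(0.0, tb_max + tb_bin_width / 2, tb_bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mids = plan.sweep_midpoints()
    n_s, n_b = len(mids), len(centers)
    phi = np.full((n_s, n_b), np.nan)
    cells = np.zeros((n_s, n_b))
    bi = np.digitize(df["tb"], edges) - 1
    ok = (bi >= 0) & (bi < n_b)
    df = df[ok]
    bi = bi[ok]
    for (sweep, b), g in df.groupby([df["sweep"], bi]):
        if sweep >= n_s:
            continue
        cells[sweep, b] = len(g) / frames_per_movie
        if cells[sweep, b] >= min_cells:
            phi[sweep, b] = g["x"].mean()
    return PerformanceMap(
        sweep_times=mids,
        bin_centers=centers,
        bin_width=tb_bin_width,
        phi=phi,
        cell_equiv=cells,
        min_cells=min_cells,
    )


def jensen_compare(
    frames: pd.DataFrame,
    tracks: pd.DataFrame,
    plan: AcquisitionPlan,
    window: float = 0.01,
) -> pd.DataFrame:
    """Per sweep: mean performance of the population vs performance of the
    mean phenotype.

    E[phi(TB)] is the mean position over all samples; phi(E[TB]) the mean
    position over samples whose track tumble bias lies within ``window`` of
    the population mean tumble bias.  Sweeps with no cells inside the
    window get NaN for the latter.  Columns: sweep, t_mid, mean_tb,
    mean_performance, mean_performance_sem2, phi_of_mean,
    phi_of_mean_sem2, n_window_samples.
    """
    df = _join_tb(frames, tracks)
    mids = plan.sweep_midpoints()
    rows = []
    for sweep, g in df.groupby("sweep"):
        xs = g["x"].to_numpy()
        tb = g["tb"].to_numpy()
        mean_tb = tb.mean()
        near = np.abs(tb - mean_tb) <= window
        xs_near = xs[near]
        rows.append(
            {
                "sweep": sweep,
                "t_mid": mids[sweep],
                "mean_tb": mean_tb,
                "mean_performance": xs.mean(),
                "mean_performance_sem2": 2.0 * xs.std(ddof=1) / np.sqrt(len(xs))
                if len(xs) > 1
                else np.nan,
                "phi_of_mean": xs_near.mean() if xs_near.size else np.nan,
                "phi_of_mean_sem2": 2.0 * xs_near.std(ddof=1) / np.sqrt(len(xs_near))
                if len(xs_near) > 1
                else np.nan,
                "n_window_samples": int(near.sum()),
            }
        )
    return pd.DataFrame(rows)


def gamma_mean_sd(k: float, theta: float) -> tuple[float, float]:
    """Mean k*theta and SD sqrt(k)*theta of a gamma phenotype distribution."""
    return k * theta, np.sqrt(k) * theta


def predict_population_performance(
    pmap: PerformanceMap,
    k: float,
    theta: float,
    max_uncovered_mass: float = 0.2,
    sweeps: list[int] | None = None,
) -> pd.DataFrame:
    """Predicted performance of a gamma(k, theta) tumble-bias population.

    For each sweep the populated part of the map is linearly interpolated
    and integrated against the gamma density, truncated and renormalized on
    the map's support.  The piecewise-linear integrand makes the integral
    exact (gamma partial expectations in closed form), so an affine map
    returns a + b*k*theta to machine precision when the support covers the
    gamma mass.  Raises if more than ``max_uncovered_mass`` of the gamma
    probability falls outside the populated support.  ``sweeps`` restricts
    evaluation to the given sweep indices (partial desk-scale maps often
    cover the gamma support only at mid-experiment sweeps).
    """
    dist = gamma_dist(a=k, scale=theta)
    dist_p1 = gamma_dist(a=k + 1, scale=theta)  # for partial expectations
    rows = []
    for s, t in enumerate(pmap.sweep_times):
        if sweeps is not None and s not in sweeps:
            continue
        good = np.isfinite(pmap.phi[s])
        if good.sum() < 2:
            rows.append({"sweep": s, "t_mid": t, "prediction": np.nan})
            continue
        tb = pmap.bin_centers[good]
        phi = pmap.phi[s][good]
        covered = dist.cdf(tb[-1]) - dist.cdf(tb[0])
        if 1.0 - covered > max_uncovered_mass:
            raise ValueError(
                f"gamma(k={k}, theta={theta}) has {1.0 - covered:.1%} of its mass "
                f"outside the map support [{tb[0]}, {tb[-1]}] at sweep {s}"
            )
        total = 0.0
        for i in range(len(tb) - 1):
            a, b = tb[i], tb[i + 1]
            # phi(x) = c0 + c1 * x on [a, b]
            c1 = (phi[i + 1] - phi[i]) / (b - a)
            c0 = phi[i] - c1 * a
            mass = dist.cdf(b) - dist.cdf(a)
            partial_mean = k * theta * (dist_p1.cdf(b) - dist_p1.cdf(a))
            total += c0 * mass + c1 * partial_mean
        rows.append({"sweep": s, "t_mid": t, "prediction": total / covered})
    return pd.DataFrame(rows)
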