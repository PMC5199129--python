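"""Pseudo-microscope: mask continuous trajectories into the acquisition's
movie/field/frame structure, and apply the track-quality filters.

The stage sweeps sink-to-source, filming one 1-min movie per field at
8.78 frames/s with a short repositioning overhead between movies, then
starts over at the gate.  A simulated cell is "observed" only while it is
inside the field currently being filmed; every maximal run of consecutive
in-mask samples becomes an independent track, exactly as the experimental
tracker would see it.  Overlapping camera fields are trimmed at midlines so
each spatial point belongs to exactly one field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import Chamber
from .simulator import TrajectorySet

__all__ = [
    "AcquisitionPlan",
    "build_plan",
    "observe",
    "summarize_tracks",
    "filter_tracks",
    "FRAMES_PER_MOVIE",
]

#: frames in one 1-min movie at 8.78 fps (the cell-equivalent denominator)
FRAMES_PER_MOVIE = 527


@dataclass
class AcquisitionPlan:
    """Timing and geometry of the sweep acquisition."""

    n_fields: int = 8
    field_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    field_bounds: np.ndarray = field(default_factory=lambda: np.array([]))  # (F, 2) trimmed
    movie_duration: float = 60.0  # s
    fps: float = 8.78
    inter_movie_overhead: float = 10.9  # s stage repositioning between movies
    n_sweeps: int = 0

    @property
    def sweep_period(self) -> float:
        return self.n_fields * (self.movie_duration + self.inter_movie_overhead)

    @property
    def sweep_span(self) -> float:
        """First movie start to last movie end within one sweep."""
        return (self.n_fields - 1) * (
            self.movie_duration + self.inter_movie_overhead
        ) + self.movie_duration

    def movie_window(self, sweep: int, fld: int) -> tuple[float, float]:
        t0 = sweep * self.sweep_period + fld * (
            self.movie_duration + self.inter_movie_overhead
        )
        return t0, t0 + self.movie_duration

    def sweep_midpoints(self) -> np.ndarray:
        """Midpoint of each sink-to-source scan (s): the time coordinate of
        population statistics."""
        return (
            np.arange(self.n_sweeps) * self.sweep_period + 0.5 * self.sweep_span
        )

    @property
    def frames_per_movie(self) -> int:
        # samples in the half-open window [t0, t0 + movie_duration):
        # 527 for a 1-min movie at 8.78 fps
        return int(np.ceil(self.movie_duration * self.fps - 1e-9))


def build_plan(
    chamber: Chamber,
    duration: float,
    n_fields: int = 8,
    field_width: float = 1330.0,
    span: float | None = None,
    movie_duration: float = 60.0,
    fps: float = 8.78,
    inter_movie_overhead: float = 10.9,
) -> AcquisitionPlan:
    """Build the acquisition plan tiling ``span`` (default: whole chamber).

    Field centers are evenly spaced; raw camera extents (center +/- width/2)
    are trimmed at midlines between neighbors and clipped to [0, span], so
    the fields tile the observed region without double counting.  For
    no-gradient runs use n_fields=4 and span=4500 (the first 4.5 mm).
    """
    if span is None:
        span = chamber.length
    spacing = span / n_fields
    if field_width < spacing:
        raise ValueError(
            f"field_width {field_width} cannot tile {span} um with {n_fields} fields"
        )
    centers = (np.arange(n_fields) + 0.5) * spacing
    lo = np.maximum(centers - field_width / 2.0, 0.0)
    hi = np.minimum(centers + field_width / 2.0, float(span))
    # trim overlaps at midlines between adjacent centers
    mid = 0.5 * (centers[:-1] + centers[1:])
    lo[1:] = np.maximum(lo[1:], mid)
    hi[:-1] = np.minimum(hi[:-1], mid)
    plan = AcquisitionPlan(
        n_fields=n_fields,
        field_centers=centers,
        field_bounds=np.column_stack([lo, hi]),
        movie_duration=movie_duration,
        fps=fps,
        inter_movie_overhead=inter_movie_overhead,
    )
    # count sweeps whose last movie finishes within the acquisition duration
    n_sweeps = 0
    while n_sweeps * plan.sweep_period + plan.sweep_span <= duration + 1e-9:
        n_sweeps += 1
    plan.n_sweeps = n_sweeps
    if n_sweeps == 0:
        raise ValueError("duration too short for a single sweep")
    return plan


def observe(traj: TrajectorySet, plan: AcquisitionPlan) -> pd.DataFrame:
    """Mask trajectories by the movie time windows and field extents.

    Returns a long frame table with one row per observed sample:
    track_id, cell_id, sweep, field, frame (1-based within the movie),
    t, x, y, true_tumble.  Each maximal run of consecutive in-mask samples
    of one cell within one movie is one track.
    """
    fps = 1.0 / (traj.times[1] - traj.times[0]) if len(traj.times) > 1 else plan.fps
    if abs(fps - plan.fps) > 1e-6 * plan.fps:
        raise ValueError(
            f"trajectory sample rate {fps:.4f} Hz does not match plan fps {plan.fps}"
        )
    pieces = []
    track_id = 0
    for sweep in range(plan.n_sweeps):
        for fld in range(plan.n_fields):
            t0, t1 = plan.movie_window(sweep, fld)
            # half-open time window [t0, t1): a 1-min movie holds 527 samples
            i0 = int(np.searchsorted(traj.times, t0 - 1e-9, side="left"))
            i1 = int(np.searchsorted(traj.times, t1 - 1e-9, side="left"))
            if i0 >= i1:
                continue
            lo, hi = plan.field_bounds[fld]
            closed_right = fld == plan.n_fields - 1
            xs = traj.x[:, i0:i1]
            inside = (xs >= lo) & ((xs <= hi) if closed_right else (xs < hi))
            if not inside.any():
                continue
            padded = np.zeros((inside.shape[0], inside.shape[1] + 2), dtype=np.int8)
            padded[:, 1:-1] = inside
            d = np.diff(padded, axis=1)
            cells_s, starts = np.nonzero(d == 1)
            cells_e, ends = np.nonzero(d == -1)
            # starts/ends are aligned per cell in order
            for c, s, e in zip(cells_s, starts, ends):
                n = e - s
                sl = slice(i0 + s, i0 + e)
                pieces.append(
                    pd.DataFrame(
                        {
                            "track_id": np.full(n, track_id),
                            "cell_id": np.full(n, c),
                            "sweep": np.full(n, sweep, dtype=np.int16),
                            "field": np.full(n, fld, dtype=np.int16),
                            "frame": np.arange(s + 1, e + 1, dtype=np.int32),
                            "t": traj.times[sl],
                            "x": traj.x[c, sl].astype(float),
                            "y": traj.y[c, sl].astype(float),
                            "true_tumble": traj.tumble[c, sl],
                        }
                    )
                )
                track_id += 1
    if not pieces:
        return pd.DataFrame(
            columns=[
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
        )
    return pd.concat(pieces, ignore_index=True)


def summarize_tracks(
    frames: pd.DataFrame, labels: np.ndarray, fps: float = 8.78
) -> pd.DataFrame:
    """Per-track derived statistics from observed frames and per-frame states.

    labels : integer per-frame state codes aligned with ``frames`` rows
        (0 = run, 1 = tumble, 2 = intermediate; see classify module).

    Returns one row per track: n_frames, duration (n_frames/fps),
    mean_speed (all frame-to-frame speeds), mean_run_speed (run frames
    only; intermediate and tumble frames excluded), max_msd (time-averaged
    MSD at the largest available lag), tb (tumble frames / all frames).
    """
    frames = frames.assign(_state=np.asarray(labels))
    rows = []
    for tid, g in frames.groupby("track_id", sort=True):
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        st = g["_state"].to_numpy()
        n = len(g)
        if n >= 2:
            sp = np.hypot(np.diff(x), np.diff(y)) * fps
            mean_speed = float(sp.mean())
            # frame-aligned speeds (forward difference, last extended)
            spf = np.append(sp, sp[-1])
            run_sp = spf[st == 0]
            mean_run_speed = float(run_sp.mean()) if run_sp.size else np.nan
            max_msd = float((x[-1] - x[0]) ** 2 + (y[-1] - y[0]) ** 2)
        else:
            mean_speed = mean_run_speed = max_msd = np.nan
        rows.append(
            {
                "track_id": tid,
                "cell_id": int(g["cell_id"].iloc[0]),
                "sweep": int(g["sweep"].iloc[0]),
                "field": int(g["field"].iloc[0]),
                "n_frames": n,
                "duration": n / fps,
                "mean_speed": mean_speed,
                "mean_run_speed": mean_run_speed,
                "max_msd": max_msd,
                "tb": float((st == 1).sum() / n),
                "mean_x": float(x.mean()),
                "true_tb": float(g["true_tumble"].mean()),
            }
        )
    return pd.DataFrame(rows)


def filter_tracks(
    tracks: pd.DataFrame,
    min_speed: float = 5.0,
    max_speed: float = 60.0,
    min_msd: float = 30.0,
    max_tb: float = 0.5,
    min_duration: float = 6.0,
) -> pd.DataFrame:
    """Track-quality filters of the trajectory analysis.

    Retains tracks with mean speed (tumbles included) and mean run speed
    (tumbles excluded) in [5, 60] um/s, a maximum mean-squared displacement
    of at least 30 um^2, tumble bias in [0, 0.5], and a duration of at
    least 6 s (53 frames at 8.78 fps).  Idempotent.
    """
    keep = (
        tracks["mean_speed"].between(min_speed, max_speed)
        & tracks["mean_run_speed"].between(min_speed, max_speed)
        & (tracks["max_msd"] >= min_msd)
        & tracks["tb"].between(0.0, max_tb)
        & (tracks["duration"] >= min_duration)
    )
    return tracks[keep.fillna(False)].reset_index(drop=True)
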