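"""Population simulator: gene expression -> pathway -> motors -> kinematics.

This is the package's synthetic-data generator.  It reproduces the
statistical structure of the gradient-race assay: a diverse population
(per-cell protein counts, per-cell run speed) is released from a reservoir
strip behind a gate at x = 0 into a 10 mm x 1 mm chamber holding a linear
MeAsp gradient, and positions plus ground-truth run/tumble labels are
recorded at the acquisition frame rate.

The integration time step is snapped to an integer number of steps per
recorded frame (default ~11 steps of ~10.4 ms per 8.78 Hz frame) so sample
times are exactly uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import Chamber, GradientSpec, concentration_at
from .expression import PROTEINS, ExpressionConfig, sample_proteomes
from .motility import (
    MotorParams,
    behavior_from_bundle,
    cw_bias,
    stationary_tumble_bias,
    step_kinematics,
    step_motors,
)
from .signaling import (
    PathwayParams,
    PathwayState,
    adaptation_time,
    adapted_state,
    step_pathway,
)

__all__ = [
    "SimConfig",
    "TrajectorySet",
    "simulate_population",
    "simulate_control",
    "control_difference_at",
]


@dataclass
class SimConfig:
    """Full configuration of one population simulation."""

    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    pathway: PathwayParams = field(default_factory=PathwayParams)
    motor: MotorParams = field(default_factory=MotorParams)
    chamber: Chamber = field(default_factory=Chamber)
    gradient: GradientSpec = field(default_factory=GradientSpec)
    n_cells: int = 16_000
    duration: float = 3_900.0  # s (~65 min of acquisition)
    dt: float = 0.01  # s, requested integration step
    sample_rate: float = 8.78  # Hz
    speed_mean: float = 26.0  # um/s (per-cell run speed draw)
    speed_sd: float = 6.0  # um/s
    speed_min: float = 2.0  # um/s truncation of the speed draw
    equilibration: float = 60.0  # s behind the closed gate before release
    seed: int | None = None
    control_mode: bool = False

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells: must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration: must be > 0")
        if self.dt <= 0:
            raise ValueError("dt: must be > 0")
        if self.dt > 1.0 / self.sample_rate + 1e-12:
            raise ValueError(
                f"dt: integration step {self.dt} s exceeds the frame interval "
                f"{1.0 / self.sample_rate:.4f} s (require dt <= 1/sample_rate)"
            )
        if self.speed_mean <= 0 or self.speed_sd < 0:
            raise ValueError("speed_mean/speed_sd: must be positive/non-negative")

    @property
    def steps_per_frame(self) -> int:
        return max(1, round(1.0 / (self.sample_rate * self.dt)))

    @property
    def dt_effective(self) -> float:
        """Actual step: the frame interval divided into equal steps."""
        return 1.0 / (self.sample_rate * self.steps_per_frame)


@dataclass
class TrajectorySet:
    """Recorded population trajectories.

    times : (F,) sample times in s, uniform at 1/sample_rate.
    x, y : (N, F) float32 positions in um.
    tumble : (N, F) ground-truth tumble state at each sample instant.
    stim_tb : (N, F) instantaneous expected tumble bias (binomial oracle on
        the instantaneous CheY-P), recorded only in control mode.
    cells : per-cell table (speed, unstim_tb, adaptation_time, protein counts).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tumble: np.ndarray
    cells: pd.DataFrame
    config: SimConfig
    stim_tb: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    def to_frames(self) -> pd.DataFrame:
        """Long-format (cell_id, t, x, y, tumble) table."""
        n, f = self.x.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(np.arange(n), f),
                "t": np.tile(self.times, n),
                "x": self.x.ravel().astype(float),
                "y": self.y.ravel().astype(float),
                "tumble": self.tumble.ravel(),
            }
        )


def _draw_speeds(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cell run speed ~ Normal(mean, sd) truncated below at speed_min."""
    v = rng.normal(cfg.speed_mean, cfg.speed_sd, size=n)
    bad = v < cfg.speed_min
    while np.any(bad):
        v[bad] = rng.normal(cfg.speed_mean, cfg.speed_sd, size=int(bad.sum()))
        bad = v < cfg.speed_min
    return v


def simulate_population(config: SimConfig) -> TrajectorySet:
    """Simulate the gradient race and return recorded trajectories.

    Cells are initialized uniformly in the reservoir strip behind the gate,
    internally adapted to the local concentration, and (except in control
    mode) equilibrated for ``equilibration`` seconds behind the closed gate
    so motor and pathway states decorrelate from initialization.  At t = 0
    the gate is removed and positions are recorded at the sample rate with
    ground-truth behavior labels.

    In control mode every cell shares the population-mean proteome and the
    same initial internal state, no equilibration is applied (the
    synchronized start is the point of the control), and the instantaneous
    expected tumble bias is recorded per frame.
    """
    config.validate()
    cfg = config
    n = cfg.n_cells
    ss = np.random.SeedSequence(cfg.seed)
    rng_expr, rng_init, rng_dyn = [np.random.default_rng(s) for s in ss.spawn(3)]

    proteomes = sample_proteomes(cfg.expression, n, rng_expr)
    if cfg.control_mode:
        # one proteome for everyone: the rounded population-mean counts
        mean_counts = {
            p: float(np.rint(cfg.expression.mean_counts[p])) for p in PROTEINS
        }
        proteomes = pd.DataFrame(
            {p: np.full(n, mean_counts[p], dtype=np.int64) for p in PROTEINS}
        )
        proteomes.index.name = "cell_id"
    prot = {p: proteomes[p].to_numpy(dtype=float) for p in PROTEINS}

    speeds = _draw_speeds(cfg, n, rng_init)

    ch = cfg.chamber
    x = rng_init.uniform(ch.x_min, ch.gate_x, size=n)
    y = rng_init.uniform(0.0, ch.width, size=n)
    theta = rng_init.uniform(0.0, 2.0 * np.pi, size=n)
    if cfg.control_mode:
        # identical initial positions are not required (the *internal* state
        # is synchronized); keep the uniform reservoir loading
        pass

    L0 = concentration_at(x, 0.0, cfg.gradient, ch)
    state = adapted_state(prot, L0, cfg.pathway)
    if cfg.control_mode:
        # same internal state for every cell: adapted at the gate concentration
        Lg = concentration_at(np.zeros(n), 0.0, cfg.gradient, ch)
        state = adapted_state(prot, Lg, cfg.pathway)
    state = PathwayState(
        m=np.asarray(state.m, dtype=float).copy(),
        a=np.asarray(state.a, dtype=float).copy(),
        yp=np.asarray(state.yp, dtype=float).copy(),
        noise_state=np.zeros(n),
    )

    cw_star = np.asarray(cw_bias(state.yp, cfg.motor), dtype=float)
    unstim_tb = np.asarray(stationary_tumble_bias(cw_star, cfg.motor), dtype=float)
    motors = rng_dyn.random((n, cfg.motor.n_flagella)) < cw_star[:, None]
    running = behavior_from_bundle(motors, cfg.motor)

    dt = cfg.dt_effective
    spf = cfg.steps_per_frame

    def do_step(t: float, bounds) -> None:
        nonlocal state, motors, running
        L = concentration_at(np.clip(x, ch.x_min, ch.x_max), t, cfg.gradient)
        state = step_pathway(state, prot, L, dt, rng_dyn, cfg.pathway)
        motors = step_motors(motors, state.yp, cfg.motor, dt, rng_dyn)
        now_running = behavior_from_bundle(motors, cfg.motor)
        tumble_exit = now_running & ~running
        step_kinematics(
            x, y, theta, speeds, now_running, tumble_exit, dt, bounds, rng_dyn, cfg.motor
        )
        running = now_running

    # --- pre-release equilibration behind the closed gate ---
    if not cfg.control_mode and cfg.equilibration > 0:
        closed = (ch.x_min, ch.gate_x, 0.0, ch.width)
        for _ in range(int(round(cfg.equilibration / dt))):
            do_step(0.0, closed)

    # --- gate open: record at the sample rate ---
    n_frames = int(np.floor(cfg.duration * cfg.sample_rate)) + 1
    times = np.arange(n_frames) / cfg.sample_rate
    X = np.empty((n, n_frames), dtype=np.float32)
    Yp = np.empty((n, n_frames), dtype=np.float32)
    T = np.empty((n, n_frames), dtype=bool)
    S = np.empty((n, n_frames), dtype=np.float32) if cfg.control_mode else None

    open_bounds = (ch.x_min, ch.x_max, 0.0, ch.width)
    X[:, 0] = x
    Yp[:, 0] = y
    T[:, 0] = ~running
    if S is not None:
        S[:, 0] = stationary_tumble_bias(cw_bias(state.yp, cfg.motor), cfg.motor)
    for f in range(1, n_frames):
        t0 = times[f - 1]
        for s in range(spf):
            do_step(t0 + s * dt, open_bounds)
        X[:, f] = x
        Yp[:, f] = y
        T[:, f] = ~running
        if S is not None:
            S[:, f] = stationary_tumble_bias(cw_bias(state.yp, cfg.motor), cfg.motor)

    cells = proteomes.copy()
    cells.insert(0, "cell_id", np.arange(n))
    cells["speed"] = speeds
    cells["unstim_tb"] = unstim_tb
    cells["adaptation_time"] = np.asarray(adaptation_time(prot, 0.0, cfg.pathway))
    cells = cells.reset_index(drop=True)

    return TrajectorySet(
        times=times, x=X, y=Yp, tumble=T, cells=cells, config=cfg, stim_tb=S
    )


def simulate_control(
    config: SimConfig, bin_width: float = 400.0
) -> pd.DataFrame:
    """Control simulation: synchronized internal states, identical proteomes.

    Runs the population with ``control_mode`` and returns, binned by x, the
    mean difference between the instantaneous expected tumble bias (binomial
    motor oracle applied to instantaneous CheY-P) and the shared
    unstimulated tumble bias.  Columns: x_center, mean_diff, n_samples.
    """
    if not config.control_mode:
        raise ValueError("simulate_control requires control_mode=True")
    traj = simulate_population(config)
    unstim = traj.cells["unstim_tb"].to_numpy()[:, None]
    diff = (traj.stim_tb - unstim).ravel()
    xs = traj.x.ravel()
    edges = np.arange(0.0, config.chamber.length + bin_width, bin_width)
    idx = np.digitize(xs, edges) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    sums = np.bincount(idx[ok], weights=diff[ok], minlength=len(edges) - 1)
    counts = np.bincount(idx[ok], minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "x_center": 0.5 * (edges[:-1] + edges[1:]),
            "mean_diff": means,
            "n_samples": counts,
        }
    )


def control_difference_at(table: pd.DataFrame, x: float = 1000.0) -> float:
    """Mean stimulated-minus-unstimulated tumble-bias difference in the
    spatial bin whose center is nearest ``x`` (um)."""
    populated = table[table["n_samples"] > 0]
    if populated.empty:
        raise ValueError("no populated bins in control table")
    i = (populated["x_center"] - x).abs().idxmin()
    return float(populated.loc[i, "mean_diff"])
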