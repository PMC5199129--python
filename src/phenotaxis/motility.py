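"""Flagellar motors, run/tumble behavior, and 2D kinematics.

Each cell carries five flagellar motors that switch independently between
counterclockwise (CCW, bundle-forming) and clockwise (CW, bundle-breaking)
rotation.  The stationary CW probability of each motor is a steep Hill
function of CheY-P, and a cell runs while at least ``min_bundle`` (3 of 5)
flagella turn CCW.  The stationary number of CCW flagella is therefore
Binomial(n_flagella, 1 - cw_bias), which gives a closed-form tumble bias

    TB = P(#CCW < min_bundle) = BinomCDF(min_bundle - 1; n_flagella, 1 - cw)

used throughout the package as the analytic motor oracle.

Kinematics are strictly 2D (the 10-um-deep chamber is pseudo-2D): runs
advance the cell at its fixed per-cell speed with rotational diffusion,
tumbles do not translate, and the heading is redrawn uniformly when a
tumble ends.  A cell crossing a chamber wall is repositioned onto the wall
with its heading turned parallel to it, preserving the sign of its
tangential motion, so cells slide along walls until a tumble or rotational
diffusion redirects them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "MotorParams",
    "cw_bias",
    "stationary_tumble_bias",
    "step_motors",
    "behavior_from_bundle",
    "step_kinematics",
]


@dataclass
class MotorParams:
    """Motor and swimming constants.

    cw_bias_hill_k is the CheY-P level at half-maximal CW bias (molecule
    units, matching quasi_steady_yp); it is a calibration constant set so
    that wild-type census copy numbers give an adapted tumble bias near the
    wild-type mode.  The Hill coefficient 10 is the literature-standard
    ultrasensitivity of the flagellar switch.
    """

    n_flagella: int = 5
    min_bundle: int = 3  # minimum CCW flagella for a run
    cw_bias_hill_k: float = 4500.0
    cw_bias_hill_h: float = 10.0
    switch_timescale: float = 0.7  # s (total CCW<->CW switching rate = 1/this)
    rot_diffusion: float = 0.062  # rad^2/s during runs
    tumble_reorientation: str = "uniform"

    def __post_init__(self) -> None:
        if not (1 <= self.min_bundle <= self.n_flagella):
            raise ValueError("require 1 <= min_bundle <= n_flagella")
        for name in ("cw_bias_hill_k", "switch_timescale", "rot_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def cw_bias(yp, params: MotorParams):
    """Stationary per-motor CW probability: Hill function of CheY-P.

    cw = yp^h / (yp^h + k^h); exactly 0 at yp = 0 (CheY-less cells never
    switch CW), 1/2 at yp = k, saturating below 1.
    """
    yp = np.asarray(yp, dtype=float)
    if np.any(yp < 0):
        raise ValueError("yp must be >= 0")
    r = (yp / params.cw_bias_hill_k) ** params.cw_bias_hill_h
    out = r / (1.0 + r)
    return out if out.ndim else float(out)


def stationary_tumble_bias(cw, params: MotorParams):
    """Analytic tumble bias at fixed CW bias: P(Binomial(n, 1-cw) < min_bundle)."""
    cw = np.asarray(cw, dtype=float)
    out = binom.cdf(params.min_bundle - 1, params.n_flagella, 1.0 - cw)
    return out if np.ndim(out) else float(out)


def step_motors(
    motors: np.ndarray,
    yp,
    params: MotorParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance motor states by dt.  ``motors`` is a boolean array (..., n_flagella),
    True = CW.

    Each flagellum is an independent two-state Markov chain with total
    switching rate 1/switch_timescale partitioned so the stationary CW
    probability equals cw_bias(yp).  Per-step flip probabilities use the
    linear form rate*dt (clipped at 1), which keeps the discrete chain's
    stationary distribution exactly at cw_bias for any dt.
    """
    cw = np.asarray(cw_bias(yp, params), dtype=float)[..., None]
    rate = 1.0 / params.switch_timescale
    p_flip = np.where(motors, (1.0 - cw) * rate * dt, cw * rate * dt)
    flips = rng.random(motors.shape) < np.minimum(p_flip, 1.0)
    return motors ^ flips


def behavior_from_bundle(motors: np.ndarray, params: MotorParams) -> np.ndarray:
    """True where the cell runs: at least min_bundle flagella rotating CCW."""
    n_ccw = (~np.asarray(motors, dtype=bool)).sum(axis=-1)
    return n_ccw >= params.min_bundle


def _deflect_to_walls(x, y, theta, chamber_bounds, rng):
    """Clip positions to the box and turn headings parallel to the wall hit,
    preserving the tangential sign (random on ties).  Mutates in place."""
    x_min, x_max, y_min, y_max = chamber_bounds
    hit_y = (y < y_min) | (y > y_max)
    if np.any(hit_y):
        np.clip(y, y_min, y_max, out=y)
        c = np.cos(theta[hit_y])
        sign = np.sign(c)
        zero = sign == 0
        if np.any(zero):
            sign[zero] = rng.choice([-1.0, 1.0], size=zero.sum())
        theta[hit_y] = np.where(sign > 0, 0.0, np.pi)
    hit_x = (x < x_min) | (x > x_max)
    if np.any(hit_x):
        np.clip(x, x_min, x_max, out=x)
        s = np.sin(theta[hit_x])
        sign = np.sign(s)
        zero = sign == 0
        if np.any(zero):
            sign[zero] = rng.choice([-1.0, 1.0], size=zero.sum())
        theta[hit_x] = np.where(sign > 0, np.pi / 2, -np.pi / 2)


def step_kinematics(
    x: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    speed: np.ndarray,
    running: np.ndarray,
    tumble_exit: np.ndarray,
    dt: float,
    chamber_bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    params: MotorParams,
) -> None:
    """Advance positions/headings by dt in place.

    running : boolean, True where the cell is in a run this step.
    tumble_exit : boolean, True where a tumble ended this step (heading is
        redrawn uniformly on [0, 2pi) before the move).
    chamber_bounds : (x_min, x_max, y_min, y_max) box the cell must stay in.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if np.any(tumble_exit):
        theta[tumble_exit] = rng.uniform(0.0, 2.0 * np.pi, size=int(tumble_exit.sum()))
    if params.rot_diffusion > 0:
        theta += np.where(
            running,
            np.sqrt(2.0 * params.rot_diffusion * dt) * rng.standard_normal(theta.shape),
            0.0,
        )
    step = np.where(running, speed * dt, 0.0)
    x += step * np.cos(theta)
    y += step * np.sin(theta)
    _deflect_to_walls(x, y, theta, chamber_bounds, rng)
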