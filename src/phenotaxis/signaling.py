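"""Per-cell chemotaxis pathway: MWC receptor team, methylation adaptation,
and CheY-P output.

Model
-----
Receptor teams of ``n_tar`` Tar units are two-state (active/inactive) with
free-energy difference (in kT)

    F(m, L) = n_tar * [eps0 + eps_m * m + ln(1 + L/k_off) - ln(1 + L/k_on)]

and team activity a = 1 / (1 + exp(F)).  With k_off < k_on the ligand term
grows with L, so attractant binding raises F and *lowers* activity; eps_m < 0
so methylation restores it.  Methylation follows linear CheR/CheB kinetics

    dm/dt = k_r * R * (1 - a) - k_b * B * a

whose fixed point a* = k_r R / (k_r R + k_b B) depends only on the CheR/CheB
ratio — perfect adaptation.  The relaxation rate scales with the total
enzyme numbers, so low-CheR cells both tumble less and adapt more slowly
(the inverse tumble-bias/adaptation-time correlation).  Adaptation noise is
an Ornstein-Uhlenbeck process whose increments are added to m.  CheY-P is
computed at quasi-steady state from the CheA/CheY/CheZ counts because
phosphorylation dynamics are much faster than methylation.

All functions broadcast over numpy arrays, so a single code path serves
scalar unit tests and whole-population simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "PathwayParams",
    "PathwayState",
    "free_energy",
    "activity",
    "adapted_activity",
    "quasi_steady_yp",
    "adapted_state",
    "adaptation_time",
    "step_pathway",
]


@dataclass
class PathwayParams:
    """Pathway rate and energy constants.

    k_off/k_on are the Tar-MeAsp dissociation constants of the inactive and
    active receptor (mM).  eps0, eps_m, k_r, k_b, k_z, sigma_m and
    tau_m_noise are calibration constants (see docs/methods.md): they are
    set so that wild-type census copy numbers give an adapted tumble-bias
    distribution centered near the wild-type mode, with small-signal
    adaptation fast enough that climbing cells are nearly adapted past the
    first millimeter of the chamber.
    """

    n_tar: int = 6  # Tar receptors per assistance neighborhood
    k_off: float = 0.0182  # mM (inactive-state Kd)
    k_on: float = 3.0  # mM (active-state Kd)
    eps0: float = 1.0  # kT per receptor
    eps_m: float = -0.5  # kT per methyl group (< 0)
    k_r: float = 0.004  # methyl s^-1 per CheR molecule
    k_b: float = 0.004  # methyl s^-1 per CheB molecule
    k_a: float = 12.35  # CheA autophosphorylation rate (s^-1)
    k_y: float = 1.0  # phosphotransfer scale
    k_z: float = 9.5  # CheZ dephosphorylation scale
    sigma_m: float = 0.6  # stationary SD of adaptation noise (methyl units) at noise_ref_cheR
    tau_m_noise: float = 10.0  # correlation time of adaptation noise (s)
    noise_ref_cheR: float = 140.0  # CheR count at which the OU SD equals sigma_m (0 = no scaling)
    m_max: float = 8.0  # methylation ceiling (methyl groups per receptor team unit)

    def __post_init__(self) -> None:
        if not (0 < self.k_off < self.k_on):
            raise ValueError("require 0 < k_off < k_on")
        for name in ("k_r", "k_b", "k_a", "k_y", "k_z", "sigma_m", "tau_m_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eps_m >= 0:
            raise ValueError("eps_m must be negative")


@dataclass
class PathwayState:
    """Internal pathway state (scalar or per-cell arrays)."""

    m: np.ndarray | float  # mean methylation level
    a: np.ndarray | float  # receptor-team activity in [0, 1]
    yp: np.ndarray | float  # CheY-P level (molecule units)
    noise_state: np.ndarray | float = 0.0  # OU adaptation-noise value


def _ligand_term(L, params: PathwayParams):
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("concentration must be >= 0")
    return np.log1p(L / params.k_off) - np.log1p(L / params.k_on)


def free_energy(m, L, params: PathwayParams):
    """Receptor-team free energy F(m, L) in kT (see module docstring)."""
    return params.n_tar * (
        params.eps0 + params.eps_m * np.asarray(m, dtype=float) + _ligand_term(L, params)
    )


def activity(F):
    """Logistic MWC activity a = 1/(1 + exp(F)), saturating in (0, 1)."""
    return expit(-np.asarray(F, dtype=float))


def adapted_activity(R, B, params: PathwayParams):
    """Fixed-point activity a* = k_r R / (k_r R + k_b B).

    Requires at least one of R, B nonzero (with both zero there is no
    adaptation and no fixed point).
    """
    R = np.asarray(R, dtype=float)
    B = np.asarray(B, dtype=float)
    num = params.k_r * R
    den = num + params.k_b * B
    if np.any(den == 0):
        raise ValueError("adapted state undefined with CheR = CheB = 0")
    return num / den


def quasi_steady_yp(a, proteome, params: PathwayParams):
    """Quasi-steady CheY-P level for activity ``a``.

    yp = Y * flux / (flux + k_z * Z)  with  flux = k_y * k_a * a * A.
    ``proteome`` is any mapping with CheA/CheY/CheZ entries (a DataFrame of
    cells, a Series, or a plain dict).
    """
    A = np.asarray(proteome["CheA"], dtype=float)
    Y = np.asarray(proteome["CheY"], dtype=float)
    Z = np.asarray(proteome["CheZ"], dtype=float)
    flux = params.k_y * params.k_a * np.asarray(a, dtype=float) * A
    den = flux + params.k_z * Z
    out = np.where(den > 0, Y * flux / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def adapted_m(a_star, L, params: PathwayParams):
    """Methylation level solving activity(free_energy(m, L)) = a*, clipped
    to [0, m_max]."""
    a_star = np.asarray(a_star, dtype=float)
    with np.errstate(divide="ignore"):
        F_star = np.log(1.0 / a_star - 1.0)
    m = (F_star / params.n_tar - params.eps0 - _ligand_term(L, params)) / params.eps_m
    return np.clip(m, 0.0, params.m_max)


def adapted_state(proteome, L, params: PathwayParams) -> PathwayState:
    """Fixed point of the methylation dynamics at constant L.

    Note the returned activity is recomputed from the clipped m, so cells
    that hit the methylation ceiling (saturating attractant) report their
    actual, not nominal, adapted activity.
    """
    a_star = adapted_activity(proteome["CheR"], proteome["CheB"], params)
    m = adapted_m(a_star, L, params)
    a = activity(free_energy(m, L, params))
    yp = quasi_steady_yp(a, proteome, params)
    return PathwayState(m=m, a=a, yp=yp, noise_state=np.zeros_like(np.asarray(m)))


def adaptation_time(proteome, L, params: PathwayParams):
    """Linearized relaxation time tau of methylation around the fixed point.

    dm/dt linearized in m gives rate
    lambda = (k_r R + k_b B) * n_tar * |eps_m| * a*(1 - a*); tau = 1/lambda.
    Doubling R and B at fixed ratio leaves a* unchanged and halves tau.
    """
    R = np.asarray(proteome["CheR"], dtype=float)
    B = np.asarray(proteome["CheB"], dtype=float)
    a_star = adapted_activity(R, B, params)
    lam = (
        (params.k_r * R + params.k_b * B)
        * params.n_tar
        * abs(params.eps_m)
        * a_star
        * (1.0 - a_star)
    )
    return np.where(lam > 0, 1.0 / np.where(lam > 0, lam, 1.0), np.inf)


def step_pathway(
    state: PathwayState,
    proteome,
    L,
    dt: float,
    rng: np.random.Generator | None,
    params: PathwayParams,
) -> PathwayState:
    """Advance the pathway by one Euler step of length dt.

    m advances by the CheR/CheB drift plus the increment of an OU process
    with correlation time tau_m_noise (exact OU update, so the noise
    statistics hold for any dt).  The per-cell stationary noise SD is
    sigma_m * sqrt(noise_ref_cheR / CheR): methylation fluctuations grow as
    the methyltransferase becomes scarce, the small-copy-number mechanism
    that lets low-CheR cells tumble occasionally even though their mean
    activity is far below the motor threshold.  Set noise_ref_cheR = 0 to
    use a uniform SD of sigma_m.  Activity and CheY-P are recomputed from
    the new m.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    R = np.asarray(proteome["CheR"], dtype=float)
    B = np.asarray(proteome["CheB"], dtype=float)
    a = np.asarray(state.a, dtype=float)
    drift = (params.k_r * R * (1.0 - a) - params.k_b * B * a) * dt

    eta = np.asarray(state.noise_state, dtype=float)
    if params.sigma_m > 0 and rng is not None:
        if params.noise_ref_cheR > 0:
            sigma = params.sigma_m * np.sqrt(
                params.noise_ref_cheR / np.maximum(R, 1.0)
            )
        else:
            sigma = params.sigma_m
        decay = np.exp(-dt / params.tau_m_noise)
        eta_new = eta * decay + sigma * np.sqrt(1.0 - decay * decay) * (
            rng.standard_normal(np.shape(eta)) if np.ndim(eta) else rng.standard_normal()
        )
    else:
        eta_new = eta
    m = np.clip(
        np.asarray(state.m, dtype=float) + drift + (eta_new - eta),
        0.0,
        params.m_max,
    )
    a_new = activity(free_energy(m, L, params))
    yp = quasi_steady_yp(a_new, proteome, params)
    return PathwayState(m=m, a=a_new, yp=yp, noise_state=eta_new)
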