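"""Stochastic gene expression: per-cell chemotaxis protein copy numbers.

Non-genetic diversity in the simulated population originates here.  Each
cell draws a single *extrinsic* factor that multiplies the mean copy number
of every chemotaxis gene (the operon is expressed coherently), and each
protein additionally receives independent *intrinsic* noise.  Both levels
are log-normal, so counts are strictly positive before integer rounding.

The extrinsic noise magnitude ``omega`` is the coefficient of variation of
the shared factor.  Because downstream pathway output depends on protein
*ratios* (e.g. CheR/CheB) as well as absolute counts (CheY-P vs. the fixed
motor threshold), extrinsic noise translates mostly into motor-output
diversity while intrinsic noise diversifies the adapted pathway state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PROTEINS",
    "WT_MEAN_COUNTS",
    "ExpressionConfig",
    "sample_proteomes",
    "make_mutant",
]

#: Canonical protein order used throughout the package.
PROTEINS = ("CheA", "CheW", "CheR", "CheB", "CheY", "CheZ", "Tar", "Tsr")

#: Wild-type mean molecules/cell.  CheR = 140 molecules/cell is the
#: literature census value for wild-type E. coli; the other entries are the
#: standard census stoichiometry from the same source family.
WT_MEAN_COUNTS: dict[str, float] = {
    "CheA": 6700.0,
    "CheW": 6700.0,
    "CheR": 140.0,
    "CheB": 240.0,
    "CheY": 8200.0,
    "CheZ": 3200.0,
    "Tar": 5000.0,
    "Tsr": 10000.0,
}


def _lognormal_params(mean: float | np.ndarray, cv: float):
    """(mu, sigma) of a log-normal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


@dataclass
class ExpressionConfig:
    """Parameters of the two-level (extrinsic x intrinsic) expression model.

    Parameters
    ----------
    mean_counts
        Mean molecules/cell for each protein in :data:`PROTEINS`.
    omega
        Extrinsic noise magnitude: CV of the shared per-cell factor
        multiplying all genes (dimensionless, >= 0).
    intrinsic_cv
        Per-protein intrinsic coefficient of variation (dimensionless, >= 0).
    seed
        Default RNG seed used when no generator is passed explicitly.
    """

    mean_counts: dict[str, float] = field(
        default_factory=lambda: dict(WT_MEAN_COUNTS)
    )
    omega: float = 0.08
    intrinsic_cv: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.mean_counts) - set(PROTEINS)
        if unknown:
            raise ValueError(f"unknown proteins in mean_counts: {sorted(unknown)}")
        missing = set(PROTEINS) - set(self.mean_counts)
        if missing:
            raise ValueError(f"mean_counts missing proteins: {sorted(missing)}")
        for name, m in self.mean_counts.items():
            if m < 0:
                raise ValueError(f"mean count for {name} must be >= 0, got {m}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.intrinsic_cv < 0:
            raise ValueError(f"intrinsic_cv must be >= 0, got {self.intrinsic_cv}")


def sample_proteomes(
    config: ExpressionConfig,
    n_cells: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample per-cell protein copy numbers.

    Returns a DataFrame with one row per cell and one integer column per
    protein.  A single log-normal extrinsic factor (mean 1, CV ``omega``)
    multiplies every protein of a cell; each protein then receives
    independent log-normal intrinsic noise with CV ``intrinsic_cv``.
    Continuous draws are rounded half-to-even and clipped at zero.

    With ``omega = intrinsic_cv = 0`` the sampling is deterministic and every
    cell carries exactly the rounded mean counts.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if config.omega > 0:
        mu, sigma = _lognormal_params(1.0, config.omega)
        extrinsic = rng.lognormal(mu, sigma, size=n_cells)
    else:
        extrinsic = np.ones(n_cells)

    counts = {}
    for name in PROTEINS:
        mean = config.mean_counts[name]
        if mean == 0.0:
            counts[name] = np.zeros(n_cells, dtype=np.int64)
            continue
        cell_mean = extrinsic * mean
        if config.intrinsic_cv > 0:
            mu, sigma = _lognormal_params(cell_mean, config.intrinsic_cv)
            raw = rng.lognormal(mu, sigma)
        else:
            raw = cell_mean
        # round-half-to-even, then clip at zero
        counts[name] = np.maximum(np.rint(raw), 0.0).astype(np.int64)

    df = pd.DataFrame(counts, columns=list(PROTEINS))
    df.index.name = "cell_id"
    return df


def make_mutant(
    config: ExpressionConfig, protein: str, new_mean: float
) -> ExpressionConfig:
    """Return a copy of ``config`` with one protein's mean replaced.

    ``new_mean = 0`` models a clean deletion: every sampled cell then has
    exactly zero copies of that protein.
    """
    if protein not in PROTEINS:
        raise ValueError(f"unknown protein {protein!r}; expected one of {PROTEINS}")
    if new_mean < 0:
        raise ValueError(f"new_mean must be >= 0, got {new_mean}")
    means = dict(config.mean_counts)
    means[protein] = float(new_mean)
    return replace(config, mean_counts=means)
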