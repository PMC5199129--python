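"""Chamber geometry and attractant concentration field.

Coordinate convention: x = 0 at the gate, increasing toward the attractant
source; distance past the gate is the performance coordinate.  Cells start
in a reservoir strip behind the gate (x < 0).  All lengths are in microns,
concentrations in mM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["Chamber", "GradientSpec", "concentration_at"]


@dataclass
class Chamber:
    """Observation chamber: 10 mm x 1 mm (x 10 um deep, treated as 2D),
    with a 0.3 mm loading reservoir behind the gate at x = 0."""

    length: float = 10_000.0  # um along the gradient axis
    width: float = 1_000.0  # um
    gate_x: float = 0.0
    reservoir_depth: float = 300.0  # um behind the gate

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.reservoir_depth <= 0:
            raise ValueError("chamber dimensions must be positive")

    @property
    def x_min(self) -> float:
        return self.gate_x - self.reservoir_depth

    @property
    def x_max(self) -> float:
        return self.gate_x + self.length


@dataclass
class GradientSpec:
    """Attractant (MeAsp) concentration field.

    kind='linear' is the idealized steady gradient of the assay: a ramp of
    ``slope`` mM/mm from zero at the gate, clipped at the source
    concentration.  kind='custom' accepts any non-negative function of
    (x [um], t [s]), e.g. a fitted space-time surface.
    """

    kind: str = "linear"  # {none, linear, custom}
    source_conc: float = 1.0  # mM at x = chamber.length
    slope: float = 0.1  # mM per mm
    custom_fn: Callable[[np.ndarray, float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "custom"):
            raise ValueError(f"unknown gradient kind {self.kind!r}")
        if self.kind == "custom" and self.custom_fn is None:
            raise ValueError("kind='custom' requires custom_fn")
        if self.source_conc < 0:
            raise ValueError("source_conc must be >= 0")


def concentration_at(
    x: np.ndarray | float,
    t: float,
    grad: GradientSpec,
    chamber: Chamber | None = None,
) -> np.ndarray | float:
    """Concentration (mM) at position(s) x and time t.

    Behind the gate (x < 0) the concentration equals c(0) — the sink side is
    plain buffer.  If ``chamber`` is given, x is range-checked against
    [-reservoir_depth, length].
    """
    x = np.asarray(x, dtype=float)
    if chamber is not None:
        if np.any(x < chamber.x_min - 1e-9) or np.any(x > chamber.x_max + 1e-9):
            raise ValueError("position outside chamber and reservoir")
    if grad.kind == "none":
        c = np.zeros_like(x)
    elif grad.kind == "linear":
        # slope is mM/mm; x is um
        c = np.clip(grad.slope * 1e-3 * np.maximum(x, 0.0), 0.0, grad.source_conc)
    else:
        c = np.asarray(grad.custom_fn(np.maximum(x, 0.0), t), dtype=float)
        if np.any(c < 0):
            raise ValueError("custom gradient returned negative concentration")
    return c if c.ndim else float(c)
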