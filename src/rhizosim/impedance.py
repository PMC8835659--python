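"""Penetration resistance and the root impedance response.

Soil strength Q (kPa) comes from a pedotransfer function of bulk density,
porosity, overburden stress and water status:

    Q = rho * [ A* (F - e)^2 / (1 + e) * (sigma_s^p - psi S*)^f ]^2

with matric potential psi <= 0, so the water term -psi*S* is non-negative.
Root elongation responds through a decreasing Michaelis-Menten factor

    R_I = 1 - Q / (Q50 + Q)

which is 1 at zero strength and 0.5 at the class-specific Q50, and new-growth
diameter expands as elongation slows:

    D_I = R_I^(-alpha).

Impedance is a scalar (isotropic): it changes the rate, never the direction,
of root growth.
"""

from __future__ import annotations

import numpy as np

from .config import ImpedanceParams, PedotransferConstants
from .soil import SoilGrid, SoilLayerState

__all__ = [
    "penetration_resistance", "impedance_factor", "diameter_multiplier",
    "q_profile", "ImpedanceField", "impedance_at",
]


def penetration_resistance(layer, constants: PedotransferConstants) -> float:
    """Penetration resistance Q (kPa) for one soil layer state.

    Accepts a SoilLayerState or any object with bulk_density, porosity,
    net_stress, matric_potential and saturation attributes.
    """
    return float(_q_from_fields(
        layer.bulk_density, layer.porosity, layer.net_stress,
        layer.matric_potential, layer.saturation, constants))


def _q_from_fields(rho, e, sigma_s, psi, s_star, c: PedotransferConstants):
    rho = np.asarray(rho, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(c.F - e <= 0):
        raise ValueError(
            f"pedotransfer constant F={c.F} must exceed porosity (max e={np.max(e)})")
    base = np.asarray(sigma_s, dtype=float) ** c.p - np.asarray(psi) * np.asarray(s_star)
    if np.any(base < 0):
        bad = np.argmax(base < 0)
        raise ValueError(
            "negative base raised to non-integer exponent in the pedotransfer "
            f"water term (layer index {bad}: sigma_s^p - psi*S* = {np.min(base):.4g}); "
            "matric potential must be <= 0")
    q = rho * (c.A_star * (c.F - e) ** 2 / (1.0 + e) * base ** c.f) ** 2
    return q


def q_profile(grid: SoilGrid, constants: PedotransferConstants) -> np.ndarray:
    """Q at every layer midpoint from the grid's current state (vectorized)."""
    return _q_from_fields(grid.bulk_density, grid.porosity, grid.sigma_s,
                          grid.psi_kpa, grid.saturation, constants)


def impedance_factor(Q, Q50):
    """Relative elongation factor R_I = 1 - Q/(Q50 + Q), in (0, 1]."""
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError(f"penetration resistance must be >= 0, got {np.min(Q)}")
    if np.any(np.asarray(Q50, dtype=float) <= 0):
        raise ValueError("Q50 must be > 0")
    r = 1.0 - Q / (Q50 + Q)
    return float(r) if r.ndim == 0 else r


def diameter_multiplier(R_I, alpha: float):
    """Radial expansion of new growth, D_I = R_I^(-alpha) >= 1."""
    R_I = np.asarray(R_I, dtype=float)
    if np.any(R_I <= 0) or np.any(R_I > 1.0 + 1e-12):
        raise ValueError("R_I must lie in (0, 1]; zero-growth tips build no segment")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    d = R_I ** (-alpha)
    return float(d) if d.ndim == 0 else d


class ImpedanceField:
    """Depth-interpolable penetration resistance field.

    Q is piecewise-linear in depth between layer-midpoint values (Q is the
    physical field; the per-class response R_I is applied after
    interpolation). Positions outside the column clamp to the nearest layer;
    the field is horizontally uniform and isotropic.
    """

    def __init__(self, mid_depths: np.ndarray, q_values: np.ndarray):
        self.mid_depths = np.asarray(mid_depths, dtype=float)
        self.q_values = np.asarray(q_values, dtype=float)
        if np.any(self.q_values < 0):
            raise ValueError("Q profile must be non-negative")

    @classmethod
    def from_grid(cls, grid: SoilGrid, constants: PedotransferConstants) -> "ImpedanceField":
        return cls(grid.midpoints, q_profile(grid, constants))

    @classmethod
    def from_table(cls, table) -> "ImpedanceField":
        """Direct depth-profile specification: iterable of (depth cm, Q kPa)."""
        arr = np.asarray(list(table), dtype=float)
        order = np.argsort(arr[:, 0])
        return cls(arr[order, 0], arr[order, 1])

    def q_at(self, z):
        """Interpolated Q at depth(s) z; clamps beyond the first/last midpoint."""
        return np.interp(np.asarray(z, dtype=float), self.mid_depths, self.q_values)

    def factor_at(self, z, q50: float):
        """R_I at depth(s) z for a class with the given Q50."""
        return impedance_factor(self.q_at(z), q50)


def impedance_at(grid: SoilGrid, position, class_q50: float,
                 constants: PedotransferConstants) -> float:
    """R_I at a 3-D position (cm; only depth matters, horizontally uniform)."""
    z = np.asarray(position, dtype=float)[-1] if np.ndim(position) else float(position)
    field = ImpedanceField.from_grid(grid, constants)
    return float(field.factor_at(z, class_q50))
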