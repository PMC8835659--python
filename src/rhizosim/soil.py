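"""Depth-discretized soil column: bulk density profiles, porosity, overburden
stress and van Genuchten water state.

The column tiles [0, depth] cm with half-open layers [top, bottom); soil
properties vary only with depth, so the grid is one-dimensional with a 3-D
horizontal footprint used by the root geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    CM_H2O_PER_KPA,
    G_KPA_PER_G_CM3_CM,
    PARTICLE_DENSITY,
    PSI_FLOOR_KPA,
    ConfigurationError,
    VanGenuchtenParams,
    load_vg_table,
    vg_for_density,
)

__all__ = [
    "SoilLayerState", "SoilGrid", "build_density_profile", "estimate_porosity",
    "net_stress", "water_state", "theta_from_psi", "psi_from_theta",
    "hydraulic_conductivity",
]


def estimate_porosity(rho, particle_density: float = PARTICLE_DENSITY):
    """Porosity from bulk density: e = 1 - rho/particle_density."""
    rho = np.asarray(rho, dtype=float)
    if particle_density <= 0:
        raise ValueError("particle density must be > 0")
    if np.any(rho < 0) or np.any(rho > particle_density):
        raise ValueError(
            f"bulk density must lie in [0, {particle_density}] g cm-3")
    e = 1.0 - rho / particle_density
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# van Genuchten retention / conductivity (vectorized over layers)
# ---------------------------------------------------------------------------

def _vg_arrays(vg_list):
    tr = np.array([v.theta_r for v in vg_list])
    ts = np.array([v.theta_s for v in vg_list])
    al = np.array([v.alpha_vg for v in vg_list])
    n = np.array([v.n_vg for v in vg_list])
    ks = np.array([v.Ks for v in vg_list])
    return tr, ts, al, n, ks


def theta_from_psi(psi_kpa, vg: VanGenuchtenParams):
    """Volumetric water content from matric potential (kPa, <= 0)."""
    psi = np.minimum(np.asarray(psi_kpa, dtype=float), 0.0)
    m = vg.m_vg
    se = (1.0 + (vg.alpha_vg * np.abs(psi)) ** vg.n_vg) ** (-m)
    return vg.theta_r + se * (vg.theta_s - vg.theta_r)


def psi_from_theta(theta, vg: VanGenuchtenParams, floor_kpa: float = PSI_FLOOR_KPA):
    """Inverted retention curve; returns (psi_kpa, floored_flag)."""
    theta = np.asarray(theta, dtype=float)
    span = vg.theta_s - vg.theta_r
    se = (theta - vg.theta_r) / span
    floored = se <= 0.0
    se = np.clip(se, 1e-12, 1.0)
    m = vg.m_vg
    with np.errstate(over="ignore"):
        psi = -((se ** (-1.0 / m) - 1.0) ** (1.0 / vg.n_vg)) / vg.alpha_vg
    psi = np.where(se >= 1.0, 0.0, psi)
    floored = floored | (psi < floor_kpa)
    psi = np.maximum(psi, floor_kpa)
    if psi.ndim == 0:
        return float(psi), bool(floored)
    return psi, floored


def hydraulic_conductivity(se, vg_Ks, vg_m, l_param: float = 0.5):
    """Mualem conductivity from effective saturation (vectorized)."""
    se = np.clip(se, 1e-12, 1.0)
    return vg_Ks * se ** l_param * (1.0 - (1.0 - se ** (1.0 / vg_m)) ** vg_m) ** 2


def water_state(theta: float, vg: VanGenuchtenParams, e: float,
                floor_kpa: float = PSI_FLOOR_KPA):
    """Matric potential (kPa) and degree of saturation S* = theta/e for one layer.

    theta at or below residual water content returns the configured potential
    floor (the retention curve diverges there); the flag in the grid-level
    update records the event.
    """
    if not (0.0 < e <= 1.0):
        raise ValueError(f"porosity must be in (0, 1], got {e}")
    psi, _ = psi_from_theta(theta, vg, floor_kpa)
    s_star = float(np.clip(theta / e, 0.0, 1.0))
    return psi, s_star


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass
class SoilLayerState:
    """Read-only snapshot of one layer's state (grid arrays are authoritative)."""

    depth_top: float
    thickness: float
    bulk_density: float
    porosity: float
    water_content: float
    matric_potential: float
    saturation: float
    net_stress: float
    nitrate_mass: float


@dataclass
class SoilGrid:
    """Soil column state as per-layer arrays plus hydraulic parameters."""

    depth_top: np.ndarray          # cm
    thickness: np.ndarray          # cm
    bulk_density: np.ndarray       # g cm-3
    porosity: np.ndarray
    theta: np.ndarray              # volumetric water content
    psi_kpa: np.ndarray            # matric potential, <= 0
    saturation: np.ndarray         # S* = theta / porosity
    sigma_s: np.ndarray            # overburden stress at layer midpoint, kPa
    nitrate_mass: np.ndarray       # umol per layer
    vg_by_layer: list[VanGenuchtenParams]
    footprint: tuple[float, float] = (60.0, 26.0)
    psi_floor_kpa: float = PSI_FLOOR_KPA
    psi_floored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.psi_floored is None:
            self.psi_floored = np.zeros(self.n_layers, dtype=bool)

    @property
    def n_layers(self) -> int:
        return len(self.depth_top)

    @property
    def depth(self) -> float:
        return float(self.depth_top[-1] + self.thickness[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return self.depth_top + 0.5 * self.thickness

    @property
    def footprint_area_cm2(self) -> float:
        return self.footprint[0] * self.footprint[1]

    @property
    def layer_volume_cm3(self) -> np.ndarray:
        return self.thickness * self.footprint_area_cm2

    def layer(self, i: int) -> SoilLayerState:
        return SoilLayerState(
            depth_top=float(self.depth_top[i]), thickness=float(self.thickness[i]),
            bulk_density=float(self.bulk_density[i]), porosity=float(self.porosity[i]),
            water_content=float(self.theta[i]), matric_potential=float(self.psi_kpa[i]),
            saturation=float(self.saturation[i]), net_stress=float(self.sigma_s[i]),
            nitrate_mass=float(self.nitrate_mass[i]))

    @property
    def layers(self) -> list[SoilLayerState]:
        return [self.layer(i) for i in range(self.n_layers)]

    def layer_index(self, z) -> np.ndarray:
        """Layer index containing depth z (clamped into the column)."""
        edges = np.append(self.depth_top, self.depth)
        idx = np.searchsorted(edges, np.asarray(z, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_layers - 1)

    def update_water_state(self) -> None:
        """Refresh psi and S* from theta via each layer's retention curve."""
        tr, ts, al, n, _ = _vg_arrays(self.vg_by_layer)
        span = ts - tr
        se = np.clip((self.theta - tr) / span, 1e-12, 1.0)
        m = 1.0 - 1.0 / n
        with np.errstate(over="ignore"):
            psi = -((se ** (-1.0 / m) - 1.0) ** (1.0 / n)) / al
        psi = np.where(se >= 1.0, 0.0, psi)
        self.psi_floored = (self.theta <= tr) | (psi < self.psi_floor_kpa)
        self.psi_kpa = np.maximum(psi, self.psi_floor_kpa)
        self.saturation = np.clip(self.theta / self.porosity, 0.0, 1.0)

    def water_storage_cm(self) -> float:
        """Column water storage as an equivalent depth of water (cm)."""
        return float(np.sum(self.theta * self.thickness))

    def check_invariants(self) -> None:
        assert np.all(self.bulk_density > 0) and np.all(self.bulk_density < PARTICLE_DENSITY)
        assert np.all((self.porosity >= 0) & (self.porosity <= 1))
        assert np.all(self.theta >= -1e-12) and np.all(self.theta <= self.porosity + 1e-9)
        assert np.all(self.psi_kpa <= 1e-12)
        assert np.all(self.sigma_s >= 0)
        assert np.all(self.nitrate_mass >= -1e-9)
        bottoms = self.depth_top + self.thickness
        assert np.allclose(bottoms[:-1], self.depth_top[1:])
        assert self.depth_top[0] == 0.0


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def density_at(kind: str, z, depth: float = 150.0):
    """Bulk density (g cm-3) of a named profile at depth z (cm).

    uniform: 1.0 throughout; gradient: linear 1.0 at the surface to 1.6 at
    `depth`; plow_pan: gradient values with a 1.6 pan on [20, 30) cm.
    """
    z = np.asarray(z, dtype=float)
    if kind == "uniform":
        rho = np.ones_like(z)
    elif kind in ("gradient", "plow_pan"):
        rho = 1.0 + 0.6 * z / depth
        if kind == "plow_pan":
            rho = np.where((z >= 20.0) & (z < 30.0), 1.6, rho)
    else:
        raise ConfigurationError(
            f"unknown soil profile {kind!r}; valid: uniform, gradient, plow_pan")
    return float(rho) if rho.ndim == 0 else rho


def build_density_profile(kind: str, n_layers: int = 150, depth: float = 150.0,
                          footprint: tuple[float, float] = (60.0, 26.0),
                          psi_init_kpa: float = -33.0,
                          vg_table: dict | None = None) -> SoilGrid:
    """Build a soil column for one of the three named bulk-density scenarios.

    Density is evaluated at layer midpoints; porosity follows from bulk
    density; hydraulics interpolate the bundled density-indexed table; the
    initial water state is hydrostatic in neither sense but simply uniform at
    `psi_init_kpa` (field capacity by default).
    """
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    if n_layers < 2:
        raise ConfigurationError("need at least 2 layers")
    dz = depth / n_layers
    depth_top = np.arange(n_layers) * dz
    thickness = np.full(n_layers, dz)
    mid = depth_top + 0.5 * thickness
    rho = density_at(kind, mid, depth)
    e = estimate_porosity(rho)
    table = vg_table if vg_table is not None else load_vg_table()
    vg = [vg_for_density(r, table) for r in rho]
    theta = np.array([theta_from_psi(psi_init_kpa, v) for v in vg])
    grid = SoilGrid(
        depth_top=depth_top, thickness=thickness, bulk_density=rho,
        porosity=e, theta=theta, psi_kpa=np.full(n_layers, psi_init_kpa),
        saturation=np.clip(theta / e, 0, 1), sigma_s=np.zeros(n_layers),
        nitrate_mass=np.zeros(n_layers), vg_by_layer=vg, footprint=footprint)
    grid.sigma_s = np.array([net_stress(grid, z) for z in mid])
    grid.update_water_state()
    return grid


def net_stress(grid: SoilGrid, depth: float) -> float:
    """Overburden stress at a depth: g * integral of bulk density above, in kPa.

    Exact for the piecewise-constant layer densities; zero at the surface and
    non-decreasing with depth.
    """
    if depth < -1e-12 or depth > grid.depth + 1e-9:
        raise ValueError(f"depth {depth} cm outside column [0, {grid.depth}]")
    depth = float(np.clip(depth, 0.0, grid.depth))
    bottoms = grid.depth_top + grid.thickness
    covered = np.clip(np.minimum(bottoms, depth) - grid.depth_top, 0.0, None)
    return float(G_KPA_PER_G_CM3_CM * np.sum(grid.bulk_density * covered))
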