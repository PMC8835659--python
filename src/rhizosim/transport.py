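"""1-D vertical water flow and nitrate transport in the soil column.

Water follows the mixed-form Richards equation (modified-Picard implicit
scheme on a uniform node-per-layer grid) with a flux upper boundary
(precipitation minus evaporation) and a free-drainage (unit-gradient) or
no-flux lower boundary. Nitrate is advected with the pore-water flux and
dispersed (dispersivity x flux plus water-content-scaled diffusion) by an
explicit, CFL-sub-stepped finite-volume scheme that conserves mass to
machine precision; mass crossing the bottom boundary accumulates as
leaching. Mineralization is an optional zero-order source, default off.

Sign convention: fluxes are positive downward, in cm of water per day over
the column footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .config import (
    CM_H2O_PER_KPA,
    UG_N_PER_UMOL,
    ConfigurationError,
    NitrateRegime,
    ForcingRegime,
    TransportParams,
)
from .soil import SoilGrid, _vg_arrays

__all__ = [
    "initialize_nitrate", "water_step", "nitrate_step", "mineralization_step",
    "WaterStepResult", "kg_ha_to_umol",
]


def kg_ha_to_umol(kg_ha: float, area_cm2: float) -> float:
    """Convert an areal N rate (kg N ha-1) to micromol NO3-N over a footprint."""
    grams = kg_ha * 1000.0 * (area_cm2 / 1e8)
    return grams * 1e6 / UG_N_PER_UMOL


def initialize_nitrate(grid: SoilGrid, regime: NitrateRegime,
                       distribution: np.ndarray | None = None) -> SoilGrid:
    """Set per-layer nitrate so the column total matches the regime's areal mass.

    The default depth distribution is uniform over the top
    `regime.distribution_depth_cm`; the same shape is used for every regime
    (treatments differ at t = 0 only in total mass).
    """
    total = kg_ha_to_umol(regime.initial_mass_kg_ha, grid.footprint_area_cm2)
    if distribution is None:
        bottoms = grid.depth_top + grid.thickness
        covered = np.clip(np.minimum(bottoms, regime.distribution_depth_cm)
                          - grid.depth_top, 0.0, None)
        distribution = covered / covered.sum()
    else:
        distribution = np.asarray(distribution, dtype=float)
        if distribution.shape != (grid.n_layers,):
            raise ConfigurationError("distribution must have one fraction per layer")
        if not np.isclose(distribution.sum(), 1.0, atol=1e-9):
            raise ConfigurationError(
                f"distribution must sum to 1, got {distribution.sum():.6g}")
    grid.nitrate_mass = total * distribution
    return grid


# ---------------------------------------------------------------------------
# Richards water flow
# ---------------------------------------------------------------------------

@dataclass
class WaterStepResult:
    infiltration: float          # cm entering the surface over the step
    evaporation: float           # cm leaving the surface (actual, supply-limited)
    drainage: float              # cm leaving the bottom
    interface_flux: np.ndarray   # time-averaged flux at the n+1 interfaces, cm d-1
    mass_error: float            # cm, discrete storage-change minus boundary fluxes


_SS = 1e-4  # cm-1, storage above saturation; comparable to the unsaturated
# capacity just below the kink, so Picard sees a near-continuous dtheta/dh
_H_REG = -2.0  # cm, regularization head: K = Ks above it (the Mualem
# conductivity has infinite slope at saturation, which stalls iteration in
# perched near-saturated zones; capping at a small capillary height is the
# standard remedy)


def _theta_c_k(h_cm, tr, ts, al_cm, n, m, ks):
    """Retention, capacity and conductivity at pressure head h (cm), vectorized.

    For h >= 0 (perched saturation above slowly conducting layers) the
    retention curve continues with a tiny linear storage branch so the system
    stays regular; the associated water (<= Ss * h per layer) is far below
    the ledger tolerance. Conductivity is regularized to reach Ks at a small
    capillary height so its slope stays finite near saturation.
    """
    hneg = np.minimum(h_cm, 0.0)
    ah = al_cm * np.abs(hneg)
    se = (1.0 + ah ** n) ** (-m)
    theta = tr + se * (ts - tr)
    cap = np.where(
        h_cm < 0.0,
        al_cm * m * n * (ts - tr) * ah ** (n - 1.0) * (1.0 + ah ** n) ** (-m - 1.0),
        0.0) + _SS
    se_k = np.clip(se, 1e-12, 1.0)
    kr = se_k ** 0.5 * (1.0 - (1.0 - se_k ** (1.0 / m)) ** m) ** 2
    # rescale so relative conductivity reaches 1 at the regularization head
    ah_reg = al_cm * (-_H_REG)
    se_reg = (1.0 + ah_reg ** n) ** (-m)
    kr_reg = se_reg ** 0.5 * (1.0 - (1.0 - se_reg ** (1.0 / m)) ** m) ** 2
    k = ks * np.minimum(kr / kr_reg, 1.0)
    theta = np.where(h_cm >= 0.0, ts + _SS * np.maximum(h_cm, 0.0), theta)
    return theta, cap, k


def _richards_substep(h, theta_n, dz, dt, q_top, params: TransportParams,
                      tr, ts, al_cm, n, m, ks):
    """One implicit modified-Picard substep. Returns (h_new, theta_new, q_bot)."""
    nlay = h.size
    h_k = h.copy()

    def mass_residual(h_cand):
        """Continuity defect of the nonlinear system, cm of water per layer."""
        theta_c, _, k_c = _theta_c_k(h_cand, tr, ts, al_cm, n, m, ks)
        k_i = 0.5 * (k_c[:-1] + k_c[1:])
        qb = k_c[-1] if params.bottom_bc == "free_drainage" else 0.0
        q_in = k_i * (1.0 - (h_cand[1:] - h_cand[:-1]) / dz)
        q_all = np.concatenate(([q_top], q_in, [qb]))
        return (theta_c - theta_n) * dz - (q_all[:-1] - q_all[1:]) * dt

    converged = False
    for it in range(params.richards_max_iter):
        theta_k, cap_k, k_node = _theta_c_k(h_k, tr, ts, al_cm, n, m, ks)
        k_int = 0.5 * (k_node[:-1] + k_node[1:])  # interior interfaces
        q_bot = k_node[-1] if params.bottom_bc == "free_drainage" else 0.0

        a = np.zeros(nlay)
        b = cap_k / dt
        c = np.zeros(nlay)
        rhs = cap_k * h_k / dt - (theta_k - theta_n) / dt

        a[1:] = -k_int / dz ** 2
        c[:-1] = -k_int / dz ** 2
        b[1:] += k_int / dz ** 2
        b[:-1] += k_int / dz ** 2
        # gravity terms of interior interfaces
        rhs[:-1] -= k_int / dz
        rhs[1:] += k_int / dz
        # boundaries
        rhs[0] += q_top / dz
        rhs[-1] -= q_bot / dz

        ab = np.zeros((3, nlay))
        ab[0, 1:] = c[:-1]
        ab[1, :] = b
        ab[2, :-1] = a[1:]
        h_new = solve_banded((1, 1), ab, rhs)

        # relax later iterations: undamped Picard can 2-cycle around the
        # saturation kink of the retention curve; omega = 0.3 contracts such
        # a cycle at ~0.4 per iteration
        if it >= 6:
            h_new = 0.3 * h_new + 0.7 * h_k
        delta = np.max(np.abs(h_new - h_k))
        h_k = h_new
        if delta < params.richards_tol:
            converged = True
            break

    if not converged:
        # head may still flip around the near-zero-capacity saturated branch
        # while the mass defect is negligible; accept on the mass criterion
        if np.max(np.abs(mass_residual(h_k))) > 1e-8:
            return None  # genuine non-convergence; caller halves the step

    theta_new, _, k_node = _theta_c_k(h_k, tr, ts, al_cm, n, m, ks)
    q_bot = k_node[-1] if params.bottom_bc == "free_drainage" else 0.0
    return h_k, theta_new, float(q_bot)


def water_step(grid: SoilGrid, forcing: ForcingRegime, t: float, dt: float,
               params: TransportParams | None = None) -> WaterStepResult:
    """Advance soil water over [t, t+dt], sub-stepped for stability.

    Precipitation scheduled on a day is applied as a uniform intensity over
    that day; evaporation is limited by the water the top layer can supply
    above residual. On solver non-convergence the substep is halved down to
    `richards_dt_min`, then a hard error reports the state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params = params or TransportParams()
    tr, ts, al_kpa, n, ks = _vg_arrays(grid.vg_by_layer)
    al_cm = al_kpa / CM_H2O_PER_KPA
    m = 1.0 - 1.0 / n
    dz = float(grid.thickness[0])
    if not np.allclose(grid.thickness, dz):
        raise ConfigurationError("water solver requires uniform layer thickness")

    rain_rate = forcing.rain_on_day(int(np.floor(t + 1e-9))) / 1.0  # cm d-1 over the day
    h = grid.psi_kpa * CM_H2O_PER_KPA
    theta = grid.theta.copy()

    infiltration = evaporation = drainage = 0.0
    flux_time_integral = np.zeros(grid.n_layers + 1)
    mass_err = 0.0

    remaining = dt
    sub = min(params.richards_dt, dt)
    while remaining > 1e-12:
        sub = min(sub, remaining)
        # supply-limited evaporation for this substep
        avail = max(0.0, (theta[0] - tr[0] - 1e-4) * dz / sub)
        evap_rate = min(forcing.evaporation_rate, avail)
        q_top = rain_rate - evap_rate

        out = _richards_substep(h, theta, dz, sub, q_top, params,
                                tr, ts, al_cm, n, m, ks)
        if out is None:
            if sub / 2.0 < params.richards_dt_min:
                raise RuntimeError(
                    "Richards solver failed to converge at the minimum substep; "
                    f"t={t:.4f} d, dt={sub:.2e} d, "
                    f"theta range [{theta.min():.4f}, {theta.max():.4f}], "
                    f"head range [{h.min():.3g}, {h.max():.3g}] cm")
            sub /= 2.0
            continue

        h_new, theta_new, q_bot = out
        # interior interface fluxes consistent with the converged solution
        _, _, k_node = _theta_c_k(h_new, tr, ts, al_cm, n, m, ks)
        k_int = 0.5 * (k_node[:-1] + k_node[1:])
        q_interior = k_int * (1.0 - (h_new[1:] - h_new[:-1]) / dz)
        q_all = np.concatenate(([q_top], q_interior, [q_bot]))

        infiltration += rain_rate * sub
        evaporation += evap_rate * sub
        drainage += q_bot * sub
        flux_time_integral += q_all * sub
        mass_err += abs(np.sum(theta_new - theta) * dz - (q_top - q_bot) * sub)

        h, theta = h_new, theta_new
        remaining -= sub
        sub = min(params.richards_dt, remaining) if remaining > 0 else sub

    grid.theta = np.clip(theta, tr + 1e-9, ts)
    grid.update_water_state()
    return WaterStepResult(infiltration, evaporation, drainage,
                           flux_time_integral / dt, mass_err)


# ---------------------------------------------------------------------------
# nitrate transport
# ---------------------------------------------------------------------------

def nitrate_step(grid: SoilGrid, interface_flux: np.ndarray, dt: float,
                 params: TransportParams | None = None) -> float:
    """Advect and disperse nitrate with the given interface water fluxes.

    interface_flux has n_layers + 1 entries (cm d-1, downward positive);
    entry 0 is the surface, entry -1 the bottom. Rain carries no solute in
    and evaporation carries none out; leaching is the advective mass flux
    through the bottom. Returns the mass leached (umol) over dt. Total mass
    is conserved exactly: sum(before) = sum(after) + leached.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    params = params or TransportParams()
    q = np.asarray(interface_flux, dtype=float)
    if q.shape != (grid.n_layers + 1,):
        raise ValueError("need one flux per interface (n_layers + 1)")
    dz = grid.thickness
    w = grid.theta * dz                       # cm of water per layer
    m_mass = grid.nitrate_mass.copy()

    # effective dispersion at interior interfaces, cm2 d-1 (per unit area,
    # already multiplied by theta)
    theta_f = 0.5 * (grid.theta[:-1] + grid.theta[1:])
    q_int = q[1:-1]
    d_eff = params.dispersivity * np.abs(q_int) + params.diffusion_d0 * theta_f
    dz_f = 0.5 * (dz[:-1] + dz[1:])
    k_disp = d_eff / dz_f                     # exchange velocity, cm d-1

    # stable explicit substep from per-layer outflow rates
    out_rate = np.zeros(grid.n_layers)
    out_rate[:-1] += (np.clip(q_int, 0, None) + k_disp)
    out_rate[1:] += (np.clip(-q_int, 0, None) + k_disp)
    out_rate[-1] += max(q[-1], 0.0)
    with np.errstate(divide="ignore"):
        rates = out_rate / w
    max_rate = float(np.max(rates)) if rates.size else 0.0
    n_sub = max(1, int(np.ceil(dt * max_rate / 0.5)))
    sub = dt / n_sub

    leached = 0.0
    c = np.empty(grid.n_layers)
    for _ in range(n_sub):
        np.divide(m_mass, w * grid.footprint_area_cm2, out=c)  # umol cm-3 solution
        # advective interior fluxes, upwind concentration (umol d-1 / area basis)
        c_up = np.where(q_int >= 0, c[:-1], c[1:])
        f_adv = q_int * c_up
        f_disp = -k_disp * (c[1:] - c[:-1])
        f_int = (f_adv + f_disp) * grid.footprint_area_cm2   # umol d-1
        f_bot = max(q[-1], 0.0) * c[-1] * grid.footprint_area_cm2

        # per-layer outgoing mass over this substep (limiter basis)
        outgoing = np.zeros(grid.n_layers)
        outgoing[:-1] += np.clip(f_int, 0, None) * sub
        outgoing[1:] += np.clip(-f_int, 0, None) * sub
        outgoing[-1] += f_bot * sub
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(outgoing > m_mass, m_mass / np.maximum(outgoing, 1e-300), 1.0)
        # each flux is limited by its upwind (source) layer's scale
        f_int = np.where(f_int >= 0, f_int * scale[:-1], f_int * scale[1:])
        f_bot *= scale[-1]

        dm = np.zeros(grid.n_layers)
        dm[:-1] -= f_int * sub
        dm[1:] += f_int * sub
        dm[-1] -= f_bot * sub
        m_new = m_mass + dm
        if np.any(m_new < -1e-9):
            raise RuntimeError(
                "nitrate transport produced a negative mass despite the "
                f"flux limiter (min {m_new.min():.3g} umol)")
        leached += f_bot * sub
        m_mass = np.maximum(m_new, 0.0)

    grid.nitrate_mass = m_mass
    return float(leached)


def mineralization_step(grid: SoilGrid, rate: float, dt: float) -> SoilGrid:
    """Zero-order mineralization source: adds rate*dt umol to every layer."""
    if rate < 0:
        raise ValueError("mineralization rate must be >= 0")
    grid.nitrate_mass = grid.nitrate_mass + rate * dt
    return grid
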