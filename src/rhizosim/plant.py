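"""Plant carbon and nitrogen economy.

Carbon sources are the finite seed reserve and leaf-area-driven
photosynthesis; sinks are root and shoot construction and maintenance
respiration. Available carbon is split between root and shoot sinks in
proportion to their potential (stress-limited) demands. Nitrate uptake
follows Michaelis-Menten kinetics on root segment surface area against the
local soil solution concentration. Nitrogen status is the index

    stress % = clamp([1 - (u - m)/(o - m)] * 100, 0, 100)

where u is cumulative nitrate acquired and o and m are the optimal and
minimal plant N contents, which grow with shoot biomass. Stress feeds back
linearly on photosynthesis, leaf expansion and root growth, each with a
configurable floor; the root floor is the mildest, so the root mass fraction
rises under N limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, PlantParams, RootClassParams, UG_N_PER_UMOL
from .soil import SoilGrid

__all__ = [
    "PlantState", "CarbonLedger", "photosynthesis", "respiration",
    "allocate_carbon", "nitrate_uptake", "nitrogen_stress", "stress_feedback",
    "n_demand",
]


@dataclass
class PlantState:
    """Shoot abstraction, carbon pools and N-stress bookkeeping."""

    shoot_c: float                  # g C in shoot structure
    leaf_area: float                # cm2
    reserve_c: float                # g C, seed reserve + carry-over buffer
    cumulative_root_c: float = 0.0  # g C, construction + root respiration
    u_umol: float = 0.0             # cumulative nitrate acquired
    o_umol: float = 0.0
    m_umol: float = 0.0
    stress_pct: float = 0.0

    def shoot_dw(self, carbon_fraction: float) -> float:
        return self.shoot_c / carbon_fraction

    @classmethod
    def initial(cls, params: PlantParams) -> "PlantState":
        state = cls(shoot_c=params.initial_shoot_c,
                    leaf_area=params.sla * params.initial_shoot_c
                    / params.carbon_fraction * params.leaf_fraction,
                    reserve_c=params.seed_reserve_c,
                    u_umol=params.seed_n_umol)
        state.o_umol, state.m_umol = n_demand(
            state.shoot_dw(params.carbon_fraction), params)
        return state


@dataclass
class CarbonLedger:
    """Daily carbon bookkeeping; every row closes to machine precision."""

    rows: list = field(default_factory=list)

    def add(self, day, photosynthesis, reserve_draw, reserve_deposit,
            shoot_construction, root_construction, root_respiration,
            shoot_respiration) -> dict:
        sources = photosynthesis + reserve_draw
        sinks = (shoot_construction + root_construction + root_respiration
                 + shoot_respiration + reserve_deposit)
        row = dict(day=day, photosynthesis=photosynthesis,
                   seed_draw=reserve_draw, reserve_deposit=reserve_deposit,
                   shoot_construction=shoot_construction,
                   root_construction=root_construction,
                   root_respiration=root_respiration,
                   shoot_respiration=shoot_respiration,
                   residual=sources - sinks)
        tol = 1e-6 * max(sources, 1e-12)
        if abs(row["residual"]) > tol:
            raise RuntimeError(
                f"carbon ledger does not close on day {day}: "
                f"residual {row['residual']:.3e} g C vs sources {sources:.3e}")
        self.rows.append(row)
        return row


def photosynthesis(plant: PlantState, params: PlantParams,
                   stress_multiplier: float, dt: float,
                   ground_area_cm2: float) -> float:
    """Daily carbon fixation from intercepted light (g C).

    Beer-law light interception on leaf area index over the plant's ground
    area; saturates as the canopy closes.
    """
    if not (0.0 <= stress_multiplier <= 1.0):
        raise ValueError("stress multiplier must lie in [0, 1]")
    if plant.leaf_area < 0:
        raise ValueError("leaf area must be >= 0")
    lai = plant.leaf_area / ground_area_cm2
    area_m2 = ground_area_cm2 / 1e4
    return (params.lue * params.i0 * (1.0 - np.exp(-params.k_ext * lai))
            * area_m2 * stress_multiplier * dt)


def respiration(system, plant: PlantState, params: PlantParams, dt: float,
                age_factor=None) -> tuple[float, float]:
    """Maintenance respiration (root, shoot) in g C over dt.

    Root: class coefficient x segment biomass x optional age factor.
    Shoot: proportional to shoot structural carbon.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    root = 0.0
    if system is not None and system.n_segments:
        lengths = system.seg_length
        diam = system.seg_diameter
        cls_names = system.class_names
        tissue = np.array([system.classes[c].tissue_density for c in cls_names])
        coeff = np.array([system.classes[c].respiration_coeff for c in cls_names])
        biomass = np.pi / 4.0 * diam ** 2 * lengths * tissue[system.seg_class_code]
        factor = 1.0 if age_factor is None else age_factor(
            system.time - system.seg_birthday)
        root = float(np.sum(coeff[system.seg_class_code] * biomass * factor) * dt)
    shoot = params.shoot_maint_resp * plant.shoot_c * dt
    return root, shoot


def allocate_carbon(available: float, root_demand: float,
                    shoot_demand: float) -> tuple[float, float]:
    """Split available carbon across sinks; proportional rationing when short."""
    if root_demand < 0 or shoot_demand < 0:
        raise ValueError("demands must be >= 0")
    total = root_demand + shoot_demand
    if total <= available or total == 0.0:
        return root_demand, shoot_demand
    frac = available / total
    return root_demand * frac, shoot_demand * frac


def nitrate_uptake(system, grid: SoilGrid, dt: float,
                   classes: dict[str, RootClassParams] | None = None,
                   ) -> tuple[np.ndarray, float]:
    """Michaelis-Menten nitrate uptake by all root segments over dt.

    Each segment takes Imax * C/(Km + C) per cm2 of surface per day at its
    layer's solution concentration C (umol cm-3). Demands in a layer are
    scaled pro rata so the layer is at most exactly emptied. Decrements the
    grid and returns (per-layer uptake, total), in umol.
    """
    per_layer = np.zeros(grid.n_layers)
    if system is None or system.n_segments == 0:
        return per_layer, 0.0
    classes = classes or system.classes
    lengths = system.seg_length
    diam = system.seg_diameter
    mid_z = 0.5 * (system.seg_start[:, 2] + system.seg_end[:, 2])
    layer = grid.layer_index(mid_z)

    solution_volume = grid.theta * grid.layer_volume_cm3
    conc = np.where(solution_volume > 0, grid.nitrate_mass / solution_volume, 0.0)
    cls_names = system.class_names
    imax = np.array([classes[c].uptake_Imax for c in cls_names])[system.seg_class_code]
    km = np.array([classes[c].uptake_Km for c in cls_names])[system.seg_class_code]

    c_seg = conc[layer]
    surface = np.pi * diam * lengths
    demand = imax * c_seg / (km + c_seg) * surface * dt
    demand_per_layer = np.bincount(layer, weights=demand, minlength=grid.n_layers)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(demand_per_layer > grid.nitrate_mass,
                         grid.nitrate_mass / np.maximum(demand_per_layer, 1e-300), 1.0)
    taken = demand * scale[layer]
    per_layer = np.bincount(layer, weights=taken, minlength=grid.n_layers)
    per_layer = np.minimum(per_layer, grid.nitrate_mass)
    grid.nitrate_mass = grid.nitrate_mass - per_layer
    return per_layer, float(per_layer.sum())


def n_demand(shoot_dw: float, params: PlantParams) -> tuple[float, float]:
    """Optimal and minimal plant N contents (umol) at a shoot dry weight."""
    to_umol = 1e6 / UG_N_PER_UMOL
    o = params.optimal_n_frac * shoot_dw * to_umol
    m = params.minimal_n_frac * shoot_dw * to_umol
    return o, m


def nitrogen_stress(u: float, o: float, m: float) -> float:
    """N-stress index in percent: 0 at u >= o, 100 at u <= m, linear between."""
    if o <= m:
        raise ConfigurationError(
            f"optimal N content must exceed minimal (o={o}, m={m})")
    return float(np.clip((1.0 - (u - m) / (o - m)) * 100.0, 0.0, 100.0))


def stress_feedback(stress_pct: float, params: PlantParams | None = None,
                    ) -> tuple[float, float, float]:
    """Linear multipliers (photosynthesis, leaf expansion, root growth).

    Each ramps from 1 at zero stress to its floor at 100 % stress; root
    growth is penalized least, shifting allocation toward roots under N
    limitation.
    """
    if not (0.0 <= stress_pct <= 100.0):
        raise ValueError("stress must lie in [0, 100] percent")
    params = params or PlantParams()
    s = stress_pct / 100.0
    return (1.0 - (1.0 - params.photo_floor) * s,
            1.0 - (1.0 - params.leaf_floor) * s,
            1.0 - (1.0 - params.root_floor) * s)
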