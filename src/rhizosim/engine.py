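"""Daily simulation loop and the factorial experiment driver.

Per macro step (default 1 d) the engine couples the modules in a fixed
order: surface forcing, sub-stepped water flow, nitrate transport (and
optional mineralization), impedance-field refresh from the updated water
state, photosynthesis and seed-reserve draw, carbon allocation, root
elongation and branching (with wall reflection), nitrate uptake, and the
N-stress update, closing the water, nitrate and carbon ledgers daily. All
stochastic draws come from one seeded generator per run, so a (config, seed)
pair reproduces a run bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import architecture, metrics, plant as plant_mod, transport
from .config import ScenarioConfig, factorial_cells
from .impedance import ImpedanceField
from .soil import build_density_profile

__version__ = "0.1.0"

__all__ = ["SimulationResult", "run_simulation", "run_factorial"]


@dataclass
class SimulationResult:
    """Everything one run produces: ledgers, final state and provenance."""

    config: ScenarioConfig
    seed: int
    daily: pd.DataFrame
    system: architecture.RootSystem
    grid: object
    plant: plant_mod.PlantState
    carbon_ledger: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def final(self) -> pd.Series:
        return self.daily.iloc[-1]


def _depth_row(system, grid):
    ax = metrics.length_by_depth(system, class_filter="axial")
    lat = metrics.length_by_depth(system, class_filter="lateral")
    allp = metrics.length_by_depth(system)
    nit = metrics.nitrate_by_depth(grid)
    below = allp.edges[:-1] >= 75.0
    return {
        "d90_axial": metrics.d90_depth(ax),
        "d90_lateral": metrics.d90_depth(lat),
        "d90_all": metrics.d90_depth(allp),
        "d50_nitrate": metrics.d50_nitrate_depth(nit),
        "length_below_75": float(np.sum(allp.values[below])),
    }


def run_simulation(config: ScenarioConfig, seed: int | None = None) -> SimulationResult:
    """Run one scenario for its configured duration.

    `seed` overrides config.seed when given. Raises with day context if any
    module step fails.
    """
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    tp = config.transport
    pp = config.plant
    imp = config.impedance
    regime = config.make_regime()

    grid = build_density_profile(
        config.soil_profile, config.n_layers, config.depth, config.footprint,
        psi_init_kpa=tp.psi_init_kpa)
    transport.initialize_nitrate(grid, regime)
    nitrate_initial = float(grid.nitrate_mass.sum())

    system = architecture.initialize_root_system(
        config.root_classes, config.emergence_schedule, rng,
        domain=(config.footprint[0], config.footprint[1], config.depth))
    pstate = plant_mod.PlantState.initial(pp)
    ledger = plant_mod.CarbonLedger()
    wobble_scale = 1.0 if config.wobble_enabled else 0.0

    rows = []
    cum = dict(infiltration=0.0, evaporation=0.0, drainage=0.0,
               leached=0.0, mineralized=0.0, uptake=0.0,
               root_resp=0.0, shoot_resp=0.0)
    leaf_rate_prev = 0.0  # cm2 d-1, previous step's leaf expansion
    dt = config.growth_dt
    n_steps = int(round(config.duration / dt))
    t = 0.0
    for step in range(n_steps):
        try:
            # (1-3) forcing, water, nitrate transport
            wres = transport.water_step(grid, regime.forcing, t, dt, tp)
            leached = transport.nitrate_step(grid, wres.interface_flux, dt, tp)
            if tp.mineralization_rate > 0:
                transport.mineralization_step(grid, tp.mineralization_rate, dt)
                cum["mineralized"] += tp.mineralization_rate * dt * grid.n_layers

            # (4) impedance field from the updated water state
            if config.q_profile_override is not None:
                field_q = ImpedanceField.from_table(config.q_profile_override)
            else:
                field_q = ImpedanceField.from_grid(grid, config.pedotransfer)

            # (5) carbon sources
            photo_mult, leaf_mult, root_mult = plant_mod.stress_feedback(
                pstate.stress_pct, pp)
            # midpoint leaf-area predictor (previous step's expansion rate)
            # keeps canopy carbon supply second-order in the macro step
            la_saved = pstate.leaf_area
            pstate.leaf_area = la_saved + 0.5 * leaf_rate_prev * dt
            photo = plant_mod.photosynthesis(
                pstate, pp, photo_mult, dt, config.footprint_area_cm2)
            pstate.leaf_area = la_saved
            root_resp, shoot_resp = plant_mod.respiration(system, pstate, pp, dt)
            root_demand = architecture.root_carbon_demand(
                system, field_q, root_mult, dt, imp, pp)
            # logistic potential: exponential early, determinate late
            shoot_demand = (pp.shoot_rgr * pstate.shoot_c
                            * max(0.0, 1.0 - pstate.shoot_c / pp.shoot_c_max)
                            * dt * leaf_mult)
            need = root_resp + shoot_resp + root_demand + shoot_demand
            reserve_draw = min(pstate.reserve_c, pp.seed_draw_max * dt,
                               max(0.0, need - photo))
            available = photo + reserve_draw

            # respiration has priority; scale down if the plant cannot pay
            resp_total = root_resp + shoot_resp
            if resp_total > available:
                pay = available / resp_total if resp_total > 0 else 1.0
                root_resp *= pay
                shoot_resp *= pay
            growth_c = max(0.0, available - root_resp - shoot_resp)

            # (6) allocation, (7) growth
            to_root, to_shoot = plant_mod.allocate_carbon(
                growth_c, root_demand, shoot_demand)
            used_root = architecture.elongate_tips(
                system, field_q, to_root, root_mult, dt, rng, imp, pp,
                wobble_scale=wobble_scale)
            system.time = t + dt
            architecture.branch(system, dt, rng)
            pstate.shoot_c += to_shoot
            leaf_growth = to_shoot / pp.carbon_fraction * pp.sla * pp.leaf_fraction
            pstate.leaf_area += leaf_growth
            leaf_rate_prev = leaf_growth / dt

            # unused growth carbon returns to the reserve buffer
            reserve_deposit = growth_c - used_root - to_shoot
            pstate.reserve_c += reserve_deposit - reserve_draw
            pstate.cumulative_root_c += used_root + root_resp

            # (8) uptake, (9) stress
            _, uptake = plant_mod.nitrate_uptake(system, grid, dt)
            pstate.u_umol += uptake
            pstate.o_umol, pstate.m_umol = plant_mod.n_demand(
                pstate.shoot_dw(pp.carbon_fraction), pp)
            pstate.stress_pct = plant_mod.nitrogen_stress(
                pstate.u_umol, pstate.o_umol, pstate.m_umol)

            # (10) ledgers
            ledger.add(t + dt, photo, reserve_draw, reserve_deposit,
                       to_shoot, used_root, root_resp, shoot_resp)
            for k, v in (("infiltration", wres.infiltration),
                         ("evaporation", wres.evaporation),
                         ("drainage", wres.drainage), ("leached", leached),
                         ("uptake", uptake), ("root_resp", root_resp),
                         ("shoot_resp", shoot_resp)):
                cum[k] += v
            t += dt

            row = dict(
                day=t, shoot_c=pstate.shoot_c,
                shoot_dw=pstate.shoot_dw(pp.carbon_fraction),
                leaf_area=pstate.leaf_area, reserve_c=pstate.reserve_c,
                stress_pct=pstate.stress_pct, u_umol=pstate.u_umol,
                o_umol=pstate.o_umol, m_umol=pstate.m_umol,
                uptake_day=uptake, photosynthesis=photo,
                cumulative_root_c=pstate.cumulative_root_c,
                root_construction=used_root, shoot_construction=to_shoot,
                root_respiration=root_resp, shoot_respiration=shoot_resp,
                total_root_length=system.total_length(),
                axial_length=system.total_length("axial"),
                lateral_length=system.total_length("lateral"),
                n_segments=system.n_segments,
                water_storage=grid.water_storage_cm(),
                infiltration=wres.infiltration, evaporation=wres.evaporation,
                drainage=wres.drainage, water_mass_error=wres.mass_error,
                nitrate_total=float(grid.nitrate_mass.sum()),
                leached_day=leached, cum_leached=cum["leached"],
                cum_uptake=cum["uptake"], cum_infiltration=cum["infiltration"],
                cum_evaporation=cum["evaporation"], cum_drainage=cum["drainage"],
                cum_mineralized=cum["mineralized"],
            )
            row.update(_depth_row(system, grid))
            rows.append(row)
        except Exception as err:
            raise RuntimeError(
                f"simulation failed on day {t:.2f} (step {step + 1}/{n_steps}) "
                f"of cell {config.soil_profile}/{config.phenotype}/"
                f"{config.nitrate_regime}") from err

    daily = pd.DataFrame(rows)
    # cross-module conservation: initial + mineralized = remaining + leached + uptake
    nitrate_closure = (nitrate_initial + cum["mineralized"]
                       - float(grid.nitrate_mass.sum()) - cum["leached"]
                       - cum["uptake"])
    provenance = dict(config_hash=config.config_hash(), seed=seed,
                      version=__version__,
                      nitrate_initial=nitrate_initial,
                      nitrate_closure=nitrate_closure)
    return SimulationResult(config=config, seed=seed, daily=daily,
                            system=system, grid=grid, plant=pstate,
                            carbon_ledger=pd.DataFrame(ledger.rows),
                            provenance=provenance)


def run_factorial(replicates: int = 6, base_seed: int = 0,
                  cells=None, progress: bool = False,
                  **config_overrides):
    """Run the 3 soil x 4 phenotype x 3 regime factorial (or a subset).

    Each cell runs `replicates` times with seeds base_seed + replicate index.
    Returns (per-run metrics DataFrame, aggregate mean/std DataFrame,
    failures list); failed cells are reported and do not stop the sweep.
    """
    cells = list(cells) if cells is not None else factorial_cells()
    rows, failures = [], []
    for (soil, pheno, regime), rep in itertools.product(cells, range(replicates)):
        cfg = ScenarioConfig(soil_profile=soil, phenotype=pheno,
                             nitrate_regime=regime, seed=base_seed + rep,
                             replicates=replicates, **config_overrides)
        if progress:
            print(f"running {soil}/{pheno}/{regime} rep {rep}", flush=True)
        try:
            res = run_simulation(cfg)
        except Exception as err:  # partial failures reported per cell
            failures.append(dict(soil_profile=soil, phenotype=pheno,
                                 nitrate_regime=regime, replicate=rep,
                                 error=str(err)))
            continue
        final = res.final
        rows.append(dict(
            soil_profile=soil, phenotype=pheno, nitrate_regime=regime,
            replicate=rep, seed=cfg.seed + 0,
            total_root_length=final["total_root_length"],
            axial_length=final["axial_length"],
            lateral_length=final["lateral_length"],
            length_below_75=final["length_below_75"],
            d90_axial=final["d90_axial"], d90_lateral=final["d90_lateral"],
            d50_nitrate=final["d50_nitrate"],
            cumulative_root_c=final["cumulative_root_c"],
            shoot_dw=final["shoot_dw"], stress_pct=final["stress_pct"],
            cum_uptake=final["cum_uptake"], cum_leached=final["cum_leached"]))
    per_run = pd.DataFrame(rows)
    if len(per_run):
        agg = (per_run
               .drop(columns=["replicate", "seed"])
               .groupby(["soil_profile", "phenotype", "nitrate_regime"])
               .agg(["mean", "std"]))
    else:
        agg = pd.DataFrame()
    return per_run, agg, failures
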