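"""Scenario configuration: parameter containers, bundled defaults, YAML I/O.

Every number a scenario needs lives here as an explicit, overridable default:
soil hydraulics for a Hagerstown-like silt loam, the pedotransfer constants of
the penetration-resistance function, the maize root-class table, the forcing
and nitrate regimes, and the plant carbon/nitrogen economy parameters.

Units: depth/length cm (positive downward), time d, pressure kPa (matric
potential <= 0), carbon g C, nitrate micromol NO3-N, water flux cm d-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------

PARTICLE_DENSITY = 2.65           # g cm-3, standard mineral soil
G_KPA_PER_G_CM3_CM = 0.0981       # kPa of overburden per (g cm-3 * cm)
CM_H2O_PER_KPA = 10.19716         # pressure-head conversion
UG_N_PER_UMOL = 14.0067           # NO3-N molar mass, ug per umol
PSI_FLOOR_KPA = -1.5e4            # matric-potential floor near residual water

SOIL_PROFILES = ("uniform", "gradient", "plow_pan")
PHENOTYPES = ("1000-1000", "1000-4000", "4000-1000", "4000-4000")
NITRATE_REGIMES = ("highN_highLeach", "lowN_highLeach", "highN_lowLeach")


class ConfigurationError(ValueError):
    """Raised for invalid scenario configuration."""


# ---------------------------------------------------------------------------
# soil hydraulics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VanGenuchtenParams:
    """Van Genuchten retention / Mualem conductivity parameters for one layer.

    theta_r/theta_s are volumetric water contents, alpha_vg is per kPa,
    n_vg dimensionless (> 1), Ks saturated conductivity in cm d-1.
    """

    theta_r: float
    theta_s: float
    alpha_vg: float
    n_vg: float
    Ks: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ConfigurationError(
                f"require 0 <= theta_r < theta_s <= 1, got {self.theta_r}, {self.theta_s}")
        if self.alpha_vg <= 0 or self.n_vg <= 1 or self.Ks <= 0:
            raise ConfigurationError(
                f"require alpha_vg > 0, n_vg > 1, Ks > 0, got "
                f"{self.alpha_vg}, {self.n_vg}, {self.Ks}")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg


def load_vg_table() -> dict[str, np.ndarray]:
    """Bundled bulk-density-indexed hydraulic table (synthetic stand-in)."""
    with resources.files("rhizosim.data").joinpath("hagerstown_vg.csv").open() as fh:
        rows = [line.strip().split(",") for line in fh
                if line.strip() and not line.startswith("#") and not line.startswith("bulk")]
    arr = np.asarray(rows, dtype=float)
    return {
        "bulk_density": arr[:, 0], "theta_r": arr[:, 1], "theta_s": arr[:, 2],
        "alpha_vg": arr[:, 3], "n_vg": arr[:, 4], "ks_cm_d": arr[:, 5],
    }


def vg_for_density(rho: float, table: dict[str, np.ndarray] | None = None) -> VanGenuchtenParams:
    """Interpolate hydraulic parameters for a bulk density from the table.

    Ks is interpolated in log space (it spans nearly a decade over the
    1.0-1.6 g cm-3 range).
    """
    t = table if table is not None else load_vg_table()
    bd = t["bulk_density"]
    rho_c = float(np.clip(rho, bd[0], bd[-1]))
    return VanGenuchtenParams(
        theta_r=float(np.interp(rho_c, bd, t["theta_r"])),
        theta_s=float(np.interp(rho_c, bd, t["theta_s"])),
        alpha_vg=float(np.interp(rho_c, bd, t["alpha_vg"])),
        n_vg=float(np.interp(rho_c, bd, t["n_vg"])),
        Ks=float(np.exp(np.interp(rho_c, bd, np.log(t["ks_cm_d"])))),
    )


# ---------------------------------------------------------------------------
# impedance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedotransferConstants:
    """Fitted constants of the penetration-resistance pedotransfer function.

    Defaults are calibrated (see docs/methods.md) so that at moist field
    states Q sits near 0.15-0.3 MPa at 1.0 g cm-3 and 3-8 MPa at
    1.6 g cm-3 — the range where the 1000 vs 4000 kPa half-growth contrast
    is expressed — with the density term dominating the water-status term.
    """

    A_star: float = 170.0
    F: float = 0.8
    p: float = 0.5
    f: float = 0.5

    def __post_init__(self) -> None:
        for name in ("A_star", "F", "p", "f"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ConfigurationError(f"pedotransfer constant {name} must be finite")


@dataclass(frozen=True)
class ImpedanceParams:
    """Root-class response to penetration resistance.

    Q50 is the resistance (kPa) at which elongation is halved; alpha is the
    exponent of the radial-expansion response of new growth (0 disables it).
    """

    Q50_by_class: dict[str, float] = field(
        default_factory=lambda: {"axial": 1000.0, "lateral": 1000.0})
    alpha: float = 0.4

    def __post_init__(self) -> None:
        for cls, q50 in self.Q50_by_class.items():
            if q50 <= 0:
                raise ConfigurationError(f"Q50 for class {cls!r} must be > 0, got {q50}")
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")


def phenotype_q50(phenotype: str) -> dict[str, float]:
    """Map an axial-lateral phenotype label like '4000-1000' to Q50 values."""
    if phenotype not in PHENOTYPES:
        raise ConfigurationError(
            f"unknown phenotype {phenotype!r}; valid: {', '.join(PHENOTYPES)}")
    ax, lat = phenotype.split("-")
    return {"axial": float(ax), "lateral": float(lat)}


# ---------------------------------------------------------------------------
# root classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootClassParams:
    """Growth, geometry, uptake and cost parameters for one root class."""

    name: str
    is_axial: bool
    base_diameter: float            # cm
    potential_elongation: float     # cm d-1
    branch_spacing: float | None    # cm between lateral emergence sites (axials)
    branch_angle: float             # degrees from parent heading (laterals emerge at this)
    growth_duration: float          # d; finite for determinate laterals
    gravitropism: float             # pull toward vertical per cm grown
    wobble_sd: float                # degrees of directional noise per cm grown
    q50_group: str                  # 'axial' or 'lateral' (Table-style split)
    uptake_Imax: float = 10.0       # umol cm-2 root surface d-1
    uptake_Km: float = 0.05         # umol cm-3 solution
    tissue_density: float = 0.10    # g DW cm-3
    respiration_coeff: float = 0.010  # g C (g DW)-1 d-1 maintenance

    def __post_init__(self) -> None:
        if self.base_diameter <= 0 or self.potential_elongation <= 0:
            raise ConfigurationError(f"class {self.name}: diameter and rate must be > 0")
        if self.growth_duration <= 0:
            raise ConfigurationError(f"class {self.name}: growth_duration must be > 0")
        if self.is_axial and (self.branch_spacing is None or self.branch_spacing <= 0):
            raise ConfigurationError(f"axial class {self.name}: branch_spacing must be > 0")


def default_root_classes() -> dict[str, RootClassParams]:
    """Maize root-class defaults (stand-ins approximating common simulator
    parameterizations; the archived reference values are not printed)."""
    inf = float("inf")
    return {
        "primary": RootClassParams(
            name="primary", is_axial=True, base_diameter=0.10,
            potential_elongation=4.5, branch_spacing=0.6, branch_angle=70.0,
            growth_duration=inf, gravitropism=0.18, wobble_sd=6.0,
            q50_group="axial", tissue_density=0.10),
        "seminal": RootClassParams(
            name="seminal", is_axial=True, base_diameter=0.08,
            potential_elongation=4.5, branch_spacing=0.6, branch_angle=70.0,
            growth_duration=inf, gravitropism=0.11, wobble_sd=8.0,
            q50_group="axial", tissue_density=0.10),
        "nodal": RootClassParams(
            name="nodal", is_axial=True, base_diameter=0.12,
            potential_elongation=4.5, branch_spacing=0.6, branch_angle=70.0,
            growth_duration=inf, gravitropism=0.09, wobble_sd=8.0,
            q50_group="axial", tissue_density=0.10),
        "lateral": RootClassParams(
            name="lateral", is_axial=False, base_diameter=0.03,
            potential_elongation=1.2, branch_spacing=None, branch_angle=70.0,
            growth_duration=12.0, gravitropism=0.04, wobble_sd=25.0,
            q50_group="lateral", tissue_density=0.08, respiration_coeff=0.015),
    }


@dataclass(frozen=True)
class EmergenceEvent:
    day: float
    class_name: str
    zenith_deg: float  # initial angle from vertical


def default_emergence_schedule() -> tuple[EmergenceEvent, ...]:
    """Axial initiation: primary at germination, 4 seminals over days 1-3,
    nodal whorls of 4 at days 8/12/16/20."""
    events = [EmergenceEvent(0.0, "primary", 0.0)]
    for day in (1.0, 2.0, 2.0, 3.0):
        events.append(EmergenceEvent(day, "seminal", 40.0))
    for day in (8.0, 12.0, 16.0, 20.0):
        for _ in range(4):
            events.append(EmergenceEvent(day, "nodal", 55.0))
    return tuple(sorted(events, key=lambda e: e.day))


# ---------------------------------------------------------------------------
# forcing and nitrate regimes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForcingRegime:
    """Surface water forcing: rain events (day, cm of water) and evaporation."""

    precipitation_schedule: tuple[tuple[float, float], ...]
    evaporation_rate: float  # cm d-1
    label: str

    def __post_init__(self) -> None:
        days = [d for d, _ in self.precipitation_schedule]
        if any(d2 < d1 for d1, d2 in zip(days, days[1:])):
            raise ConfigurationError("precipitation schedule must be sorted by day")
        if self.evaporation_rate < 0 or any(a < 0 for _, a in self.precipitation_schedule):
            raise ConfigurationError("forcing depths and rates must be non-negative")

    def rain_on_day(self, day: int) -> float:
        return sum(amount for d, amount in self.precipitation_schedule
                   if int(d) == int(day))


def make_forcing(label: str, duration: float = 40.0) -> ForcingRegime:
    """Default forcing stand-ins: high-leach 2.5 cm rain every 3 d,
    low-leach 0.5 cm every 3 d, evaporation 0.2 cm d-1."""
    if label == "high_leach":
        depth = 3.0
    elif label == "low_leach":
        depth = 0.5
    else:
        raise ConfigurationError(
            f"unknown forcing label {label!r}; valid: high_leach, low_leach")
    schedule = tuple((float(d), depth) for d in range(0, int(np.ceil(duration)) + 1, 3))
    return ForcingRegime(schedule, evaporation_rate=0.2, label=label)


@dataclass(frozen=True)
class NitrateRegime:
    """Initial nitrate mass and its coupling to leaching forcing.

    initial_mass is in kg N ha-1 (322.5 high, 107.5 low); the initial depth
    distribution is identical across regimes (default: uniform over 0-30 cm).
    """

    label: str
    initial_mass_kg_ha: float
    forcing: ForcingRegime
    distribution_depth_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.initial_mass_kg_ha <= 0:
            raise ConfigurationError("initial nitrate mass must be > 0")


def make_nitrate_regime(label: str, duration: float = 40.0) -> NitrateRegime:
    specs = {
        "highN_highLeach": (322.5, "high_leach"),
        "lowN_highLeach": (107.5, "high_leach"),
        "highN_lowLeach": (322.5, "low_leach"),
    }
    if label not in specs:
        raise ConfigurationError(
            f"unknown nitrate regime {label!r}; valid: {', '.join(specs)}")
    mass, forcing = specs[label]
    return NitrateRegime(label, mass, make_forcing(forcing, duration))


# ---------------------------------------------------------------------------
# transport numerics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportParams:
    dispersivity: float = 1.0          # cm
    diffusion_d0: float = 0.5          # cm2 d-1, scaled by theta
    richards_dt: float = 0.1           # d, base water substep (halved on
                                       # convergence failure)
    richards_tol: float = 1e-4         # cm of head, Picard convergence
    richards_max_iter: int = 60
    richards_dt_min: float = 1e-5      # d, step-halving floor
    bottom_bc: str = "free_drainage"   # or "no_flux"
    mineralization_rate: float = 0.0   # umol per layer per d, zero-order
    psi_init_kpa: float = -33.0        # initial matric potential (field capacity)


# ---------------------------------------------------------------------------
# plant economy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantParams:
    """Shoot abstraction and carbon/nitrogen economy parameters.

    Defaults produce a plausible 40-d maize plant (shoot of order 5-10 g DW);
    absolute magnitudes are parameterization choices, orderings are the model
    output of interest.
    """

    lue: float = 1.4                 # g C per MJ intercepted PAR
    i0: float = 10.0                 # MJ m-2 d-1 incident PAR
    k_ext: float = 0.6               # canopy extinction coefficient
    sla: float = 300.0               # cm2 leaf per g shoot DW growth
    leaf_fraction: float = 0.6       # fraction of shoot growth forming leaf area
    carbon_fraction: float = 0.45    # g C per g DW
    seed_reserve_c: float = 0.15     # g C
    seed_draw_max: float = 0.03      # g C d-1 cap on reserve draw
    seed_n_umol: float = 1200.0      # kernel N credited to cumulative uptake
    initial_shoot_c: float = 0.02    # g C
    shoot_rgr: float = 0.25          # d-1 potential shoot relative growth rate
    shoot_c_max: float = 25.0        # g C, logistic ceiling of shoot potential
                                     # growth (determinate vegetative phase)
    shoot_maint_resp: float = 0.015  # g C (g shoot C)-1 d-1
    optimal_n_frac: float = 0.055    # g N per g shoot DW at zero stress
    minimal_n_frac: float = 0.02     # g N per g shoot DW at survival
    photo_floor: float = 0.2         # stress multiplier floors
    leaf_floor: float = 0.2
    root_floor: float = 0.5


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """One cell of the soil-profile x phenotype x nitrate-regime factorial."""

    soil_profile: str = "uniform"
    phenotype: str = "1000-1000"
    nitrate_regime: str = "highN_highLeach"
    duration: float = 40.0
    replicates: int = 6
    seed: int = 0
    n_layers: int = 150
    depth: float = 150.0
    footprint: tuple[float, float] = (60.0, 26.0)
    alpha: float = 0.4
    pedotransfer: PedotransferConstants = field(default_factory=PedotransferConstants)
    transport: TransportParams = field(default_factory=TransportParams)
    plant: PlantParams = field(default_factory=PlantParams)
    root_classes: dict[str, RootClassParams] = field(default_factory=default_root_classes)
    emergence_schedule: tuple[EmergenceEvent, ...] = field(
        default_factory=default_emergence_schedule)
    q_profile_override: tuple[tuple[float, float], ...] | None = None
    # optional direct (depth cm, Q kPa) penetration-resistance profile,
    # bypassing the pedotransfer function
    q50_override: dict[str, float] | None = None  # e.g. {'axial': inf} for no-impedance runs
    initial_nitrate_kg_ha: float | None = None    # overrides the regime's mass
    wobble_enabled: bool = True
    growth_dt: float = 1.0  # d, macro step for growth/economy

    def __post_init__(self) -> None:
        if self.soil_profile not in SOIL_PROFILES:
            raise ConfigurationError(
                f"unknown soil profile {self.soil_profile!r}; "
                f"valid: {', '.join(SOIL_PROFILES)}")
        if self.nitrate_regime not in NITRATE_REGIMES:
            raise ConfigurationError(
                f"unknown nitrate regime {self.nitrate_regime!r}; "
                f"valid: {', '.join(NITRATE_REGIMES)}")
        phenotype_q50(self.phenotype)  # validates
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.n_layers < 2:
            raise ConfigurationError("need at least 2 soil layers")

    @property
    def impedance(self) -> ImpedanceParams:
        q50 = phenotype_q50(self.phenotype)
        if self.q50_override:
            q50.update(self.q50_override)
        return ImpedanceParams(q50, alpha=self.alpha)

    @property
    def footprint_area_cm2(self) -> float:
        return self.footprint[0] * self.footprint[1]

    def make_regime(self) -> NitrateRegime:
        regime = make_nitrate_regime(self.nitrate_regime, self.duration)
        if self.initial_nitrate_kg_ha is not None:
            regime = dataclasses.replace(
                regime, initial_mass_kg_ha=self.initial_nitrate_kg_ha)
        return regime

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, float) and np.isinf(obj):
                return "inf"
            return obj
        return convert(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        def fix_inf(x):
            if isinstance(x, dict):
                return {k: fix_inf(v) for k, v in x.items()}
            if isinstance(x, list):
                return [fix_inf(v) for v in x]
            return float("inf") if x == "inf" else x
        d = fix_inf(d)
        if "pedotransfer" in d:
            d["pedotransfer"] = PedotransferConstants(**d["pedotransfer"])
        if "transport" in d:
            d["transport"] = TransportParams(**d["transport"])
        if "plant" in d:
            d["plant"] = PlantParams(**d["plant"])
        if "root_classes" in d:
            d["root_classes"] = {k: RootClassParams(**v) for k, v in d["root_classes"].items()}
        if "emergence_schedule" in d:
            d["emergence_schedule"] = tuple(
                EmergenceEvent(**e) for e in d["emergence_schedule"])
        if "footprint" in d:
            d["footprint"] = tuple(d["footprint"])
        if d.get("q_profile_override") is not None:
            d["q_profile_override"] = tuple(tuple(p) for p in d["q_profile_override"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def factorial_cells() -> list[tuple[str, str, str]]:
    """The full 3 soil x 4 phenotype x 3 regime design grid."""
    return [(s, p, n) for s in SOIL_PROFILES for p in PHENOTYPES for n in NITRATE_REGIMES]
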