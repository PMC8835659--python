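"""3-D maize root system growth.

The root system is a tree of straight segments. Axial roots (primary,
seminal, nodal) emerge at the seed position on a schedule and carry
first-order, determinate laterals at a constant spacing along their length.
Per growth step each active tip demands `potential_elongation * R_I *
stress_multiplier * dt` of new length; if the carbon offered cannot build the
demanded volume, all tips scale back proportionally. New-growth diameter is
the class base diameter times the radial-expansion multiplier D_I evaluated
where the tip grows; existing segments never re-thicken. Impedance changes
the rate, never the direction, of growth: heading evolves by a deterministic
gravitropic pull plus seeded Gaussian wobble, with mirror reflection at the
vertical domain walls (standing in for neighbouring plants) and clamping at
the surface and the column bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, EmergenceEvent, RootClassParams
from .impedance import ImpedanceField, diameter_multiplier, impedance_factor

__all__ = [
    "RootSystem", "initialize_root_system", "elongate_tips", "branch",
    "reflect_heading", "segment_cost_per_cm", "root_carbon_demand",
]

_EPS = 1e-12


def segment_cost_per_cm(diameter: float, tissue_density: float,
                        carbon_fraction: float) -> float:
    """Construction carbon per cm of root at a given diameter (g C cm-1)."""
    return np.pi / 4.0 * diameter ** 2 * tissue_density * carbon_fraction


@dataclass
class RootSystem:
    """Growing root system: append-only segment arrays plus the active tip set."""

    classes: dict[str, RootClassParams]
    domain: tuple[float, float, float] = (60.0, 26.0, 150.0)
    seed_position: tuple[float, float, float] = (30.0, 13.0, 2.0)
    time: float = 0.0

    # segment storage (lists of per-step numpy batches, concatenated lazily)
    _seg_chunks: list = field(default_factory=list)
    _cache: dict = field(default_factory=dict, repr=False)

    # tip arrays
    tip_pos: np.ndarray = None            # (n, 3)
    tip_heading: np.ndarray = None        # (n, 3) unit vectors
    tip_class: np.ndarray = None          # int codes into class_names
    tip_root_id: np.ndarray = None
    tip_age: np.ndarray = None
    tip_since_branch: np.ndarray = None   # cm since last lateral site (axials)
    tip_parent_root: np.ndarray = None
    tip_first_frac: np.ndarray = None     # fraction of the first growth step
    # (laterals emerge mid-step on average, so their first step is a half
    # step; keeps growth totals consistent across macro-step sizes)

    emergence_queue: list = field(default_factory=list)  # pending EmergenceEvents
    n_roots: int = 0
    root_class_of: list = field(default_factory=list)    # class name per root id
    root_parent: list = field(default_factory=list)      # parent root id or -1
    root_birthday: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.class_names = sorted(self.classes)
        self._class_code = {n: i for i, n in enumerate(self.class_names)}
        if self.tip_pos is None:
            z = np.zeros((0, 3))
            self.tip_pos = z.copy()
            self.tip_heading = z.copy()
            self.tip_class = np.zeros(0, dtype=int)
            self.tip_root_id = np.zeros(0, dtype=int)
            self.tip_age = np.zeros(0)
            self.tip_since_branch = np.zeros(0)
            self.tip_parent_root = np.zeros(0, dtype=int)
            self.tip_first_frac = np.zeros(0)

    # -- segment access -----------------------------------------------------

    def _invalidate(self) -> None:
        self._cache.clear()

    def _segments(self) -> dict[str, np.ndarray]:
        if "seg" not in self._cache:
            if self._seg_chunks:
                cols = list(zip(*self._seg_chunks))
                self._cache["seg"] = {
                    "start": np.concatenate(cols[0]),
                    "end": np.concatenate(cols[1]),
                    "class": np.concatenate(cols[2]),
                    "diameter": np.concatenate(cols[3]),
                    "birthday": np.concatenate(cols[4]),
                    "root_id": np.concatenate(cols[5]),
                }
            else:
                self._cache["seg"] = {
                    "start": np.zeros((0, 3)), "end": np.zeros((0, 3)),
                    "class": np.zeros(0, dtype=int), "diameter": np.zeros(0),
                    "birthday": np.zeros(0), "root_id": np.zeros(0, dtype=int),
                }
        return self._cache["seg"]

    @property
    def n_segments(self) -> int:
        return len(self._segments()["diameter"])

    @property
    def seg_start(self) -> np.ndarray:
        return self._segments()["start"]

    @property
    def seg_end(self) -> np.ndarray:
        return self._segments()["end"]

    @property
    def seg_class_code(self) -> np.ndarray:
        return self._segments()["class"]

    @property
    def seg_diameter(self) -> np.ndarray:
        return self._segments()["diameter"]

    @property
    def seg_birthday(self) -> np.ndarray:
        return self._segments()["birthday"]

    @property
    def seg_root_id(self) -> np.ndarray:
        return self._segments()["root_id"]

    @property
    def seg_length(self) -> np.ndarray:
        return np.linalg.norm(self.seg_end - self.seg_start, axis=1)

    def seg_class_names(self) -> np.ndarray:
        return np.asarray(self.class_names)[self.seg_class_code]

    def class_mask(self, group: str | None) -> np.ndarray:
        """Boolean segment mask for 'axial', 'lateral', a class name, or all."""
        if group in (None, "all"):
            return np.ones(self.n_segments, dtype=bool)
        names = self.seg_class_names()
        if group in ("axial", "lateral"):
            grp = np.asarray([self.classes[n].q50_group for n in self.class_names])
            return grp[self.seg_class_code] == group
        return names == group

    def total_length(self, group: str | None = None) -> float:
        return float(np.sum(self.seg_length[self.class_mask(group)]))

    def _append_segments(self, start, end, class_code, diameter, root_id) -> None:
        n = len(diameter)
        self._seg_chunks.append((
            np.asarray(start, dtype=float).reshape(n, 3),
            np.asarray(end, dtype=float).reshape(n, 3),
            np.asarray(class_code, dtype=int),
            np.asarray(diameter, dtype=float),
            np.full(n, self.time),
            np.asarray(root_id, dtype=int),
        ))
        self._invalidate()

    def _new_roots(self, class_names, parent_ids) -> np.ndarray:
        ids = np.arange(self.n_roots, self.n_roots + len(class_names))
        self.n_roots += len(class_names)
        self.root_class_of.extend(class_names)
        self.root_parent.extend(int(p) for p in parent_ids)
        self.root_birthday.extend([self.time] * len(class_names))
        return ids

    def _add_tips(self, pos, heading, class_names, root_ids, parent_roots,
                  first_frac: float = 1.0) -> None:
        codes = np.asarray([self._class_code[c] for c in class_names], dtype=int)
        self.tip_pos = np.vstack([self.tip_pos, pos])
        self.tip_heading = np.vstack([self.tip_heading, heading])
        self.tip_class = np.concatenate([self.tip_class, codes])
        self.tip_root_id = np.concatenate([self.tip_root_id, root_ids]).astype(int)
        self.tip_age = np.concatenate([self.tip_age, np.zeros(len(codes))])
        self.tip_since_branch = np.concatenate([self.tip_since_branch, np.zeros(len(codes))])
        self.tip_parent_root = np.concatenate(
            [self.tip_parent_root, parent_roots]).astype(int)
        self.tip_first_frac = np.concatenate(
            [self.tip_first_frac, np.full(len(codes), first_frac)])


# ---------------------------------------------------------------------------
# construction and geometry helpers
# ---------------------------------------------------------------------------

def initialize_root_system(classes: dict[str, RootClassParams],
                           schedule: tuple[EmergenceEvent, ...],
                           rng: np.random.Generator,
                           domain: tuple[float, float, float] = (60.0, 26.0, 150.0),
                           ) -> RootSystem:
    """Create the system with the primary tip in place and later axials queued.

    The primary root starts at the seed position heading straight down;
    seminal and nodal events wait in the emergence queue. Identical RNG state
    yields an identical system.
    """
    if "lateral" not in classes or not any(c.is_axial for c in classes.values()):
        raise ConfigurationError(
            "root class set must include the lateral class and at least one axial")
    missing = {e.class_name for e in schedule} - set(classes)
    if missing:
        raise ConfigurationError(f"emergence schedule names undefined classes: {missing}")
    system = RootSystem(classes=classes, domain=domain)
    for event in sorted(schedule, key=lambda e: e.day):
        if event.day <= 0.0 and event.class_name == "primary":
            rid = system._new_roots(["primary"], [-1])
            system._add_tips(
                np.array([system.seed_position]), np.array([[0.0, 0.0, 1.0]]),
                ["primary"], rid, np.array([-1]))
        else:
            system.emergence_queue.append(event)
    return system


def reflect_heading(position, heading, domain) -> np.ndarray:
    """Mirror the heading at any x/y wall the position lies on (unit step test).

    z is never reflected: growth clamps at the surface and at the bottom.
    """
    h = np.asarray(heading, dtype=float).copy()
    p = np.asarray(position, dtype=float)
    for axis in (0, 1):
        if (p[axis] <= 0 and h[axis] < 0) or (p[axis] >= domain[axis] and h[axis] > 0):
            h[axis] = -h[axis]
    return h


def _fold_into_box(end, domain):
    """Mirror-fold proposed endpoints back inside the x/y walls; clamp z.

    Returns folded endpoints; headings are recomputed from the realized
    displacement by the caller.
    """
    end = np.array(end, dtype=float)
    for axis in (0, 1):
        width = domain[axis]
        for _ in range(8):  # steps are << domain size; a few folds suffice
            over = end[:, axis] > width
            under = end[:, axis] < 0.0
            if not (over.any() or under.any()):
                break
            end[over, axis] = 2.0 * width - end[over, axis]
            end[under, axis] = -end[under, axis]
        np.clip(end[:, axis], 0.0, width, out=end[:, axis])
    np.clip(end[:, 2], 0.0, domain[2], out=end[:, 2])
    return end


def _perp_basis(v):
    """Orthonormal pair perpendicular to each row of unit vectors v."""
    ref = np.where(np.abs(v[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (len(v), 1)),
                   np.tile([1.0, 0.0, 0.0], (len(v), 1)))
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(v, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _tip_growth_terms(system: RootSystem, impedance_field: ImpedanceField,
                      stress_multiplier: float, dt: float,
                      impedance_params, plant_params):
    """Per-tip demand lengths, construction diameters and costs (g C cm-1)."""
    alpha = impedance_params.alpha if impedance_params is not None else 0.4
    carbon_fraction = plant_params.carbon_fraction if plant_params is not None else 0.45
    q50_of = {g: (impedance_params.Q50_by_class[g] if impedance_params is not None
                  else 1000.0) for g in ("axial", "lateral")}
    cls = [system.classes[system.class_names[c]] for c in system.tip_class]
    duration = np.array([c.growth_duration for c in cls])
    active = system.tip_age < duration
    pot_rate = np.array([c.potential_elongation for c in cls])
    base_diam = np.array([c.base_diameter for c in cls])
    tissue = np.array([c.tissue_density for c in cls])
    q50 = np.array([q50_of[c.q50_group] for c in cls])
    r_i = impedance_factor(impedance_field.q_at(system.tip_pos[:, 2]), q50)
    d_i = diameter_multiplier(np.clip(r_i, 1e-9, 1.0), alpha)
    diam = base_diam * d_i
    dt_tip = dt * system.tip_first_frac
    demand_len = np.where(active, pot_rate * r_i * stress_multiplier * dt_tip, 0.0)
    cost_per_cm = np.pi / 4.0 * diam ** 2 * tissue * carbon_fraction
    return cls, demand_len, diam, cost_per_cm


def root_carbon_demand(system: RootSystem, impedance_field: ImpedanceField,
                       stress_multiplier: float, dt: float,
                       impedance_params=None, plant_params=None) -> float:
    """Construction carbon (g C) the tips would use unconstrained over dt."""
    if len(system.tip_age) == 0:
        return 0.0
    _, demand_len, _, cost = _tip_growth_terms(
        system, impedance_field, stress_multiplier, dt, impedance_params, plant_params)
    return float(np.sum(demand_len * cost))


def elongate_tips(system: RootSystem, impedance_field: ImpedanceField,
                  carbon_budget: float, stress_multiplier: float, dt: float,
                  rng: np.random.Generator,
                  impedance_params=None, plant_params=None,
                  wobble_scale: float = 1.0) -> float:
    """Grow every active tip for dt days within a carbon budget.

    Returns the construction carbon actually used (<= carbon_budget). When
    the summed carbon demand exceeds the budget, every tip's realized length
    scales by the same budget/demand ratio. Laterals older than their class's
    growth duration are determinate and do not elongate.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if carbon_budget < 0:
        raise ValueError("carbon budget must be >= 0")
    n = len(system.tip_age)
    if n == 0:
        return 0.0
    cls, demand_len, diam, cost_per_cm = _tip_growth_terms(
        system, impedance_field, stress_multiplier, dt, impedance_params, plant_params)
    if not np.any(demand_len > 0):
        system.tip_age += dt * system.tip_first_frac
        system.tip_first_frac[:] = 1.0
        return 0.0
    grav = np.array([c.gravitropism for c in cls])
    wobble = np.array([c.wobble_sd for c in cls])
    demand_c = demand_len * cost_per_cm
    total_demand = float(demand_c.sum())
    scale = 1.0 if total_demand <= carbon_budget else carbon_budget / total_demand
    realized = demand_len * scale

    grow = realized > _EPS
    # one wobble draw per tip regardless of growth, so the stream is stable
    noise = rng.standard_normal((n, 3))
    if grow.any():
        idx = np.where(grow)[0]
        # both the gravitropic pull and the wobble scale with the length
        # grown, so trajectories are invariant to the growth-step size
        sd_rad = np.deg2rad(wobble[idx]) * realized[idx] * wobble_scale
        grav_pull = grav[idx] * realized[idx]
        direction = (system.tip_heading[idx]
                     + grav_pull[:, None] * np.array([0.0, 0.0, 1.0])
                     + noise[idx] * sd_rad[:, None])
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        direction = np.where(norms > _EPS, direction / norms, system.tip_heading[idx])

        start = system.tip_pos[idx]
        end = _fold_into_box(start + direction * realized[idx, None], system.domain)
        disp = end - start
        dist = np.linalg.norm(disp, axis=1, keepdims=True)
        new_heading = np.where(dist > _EPS, disp / dist, system.tip_heading[idx])

        moved = (dist[:, 0] > _EPS)
        keep = idx[moved]
        system._append_segments(start[moved], end[moved],
                                system.tip_class[keep], diam[keep],
                                system.tip_root_id[keep])
        system.tip_pos[idx] = end
        system.tip_heading[idx] = new_heading
        is_axial = np.array([c.is_axial for c in cls])
        system.tip_since_branch[idx] += np.where(is_axial[idx], realized[idx], 0.0)

    system.tip_age += dt * system.tip_first_frac
    system.tip_first_frac[:] = 1.0
    return float(np.sum(realized * cost_per_cm))


def branch(system: RootSystem, dt: float, rng: np.random.Generator) -> None:
    """Spawn laterals along axial growth and release queued axial emergences.

    Each axial tip produces one lateral per `branch_spacing` of accumulated
    new length; the sub-spacing remainder persists across steps. Laterals
    emerge at the class branch angle from the parent heading with a uniform
    random azimuth and never branch themselves (first-order only).
    """
    # queued seminal/nodal initiations whose day has arrived
    due = [e for e in system.emergence_queue if e.day <= system.time + 1e-9]
    if due:
        system.emergence_queue = [e for e in system.emergence_queue
                                  if e.day > system.time + 1e-9]
        names = [e.class_name for e in due]
        zen = np.deg2rad([e.zenith_deg for e in due])
        az = rng.uniform(0.0, 2.0 * np.pi, len(due))
        heading = np.column_stack([
            np.sin(zen) * np.cos(az), np.sin(zen) * np.sin(az), np.cos(zen)])
        pos = np.tile(system.seed_position, (len(due), 1))
        rid = system._new_roots(names, [-1] * len(due))
        system._add_tips(pos, heading, names, rid, np.full(len(due), -1))

    # lateral initiation along axials
    cls = [system.classes[system.class_names[c]] for c in system.tip_class]
    spawn_pos, spawn_head, spawn_parent = [], [], []
    for i, c in enumerate(cls):
        if not c.is_axial or c.branch_spacing is None:
            continue
        spacing = c.branch_spacing
        n_new = int(system.tip_since_branch[i] // spacing)
        if n_new == 0:
            continue
        remainder = system.tip_since_branch[i] - n_new * spacing
        system.tip_since_branch[i] = remainder
        h = system.tip_heading[i]
        # emergence sites trail the tip along its (locally straight) recent path
        back = remainder + spacing * np.arange(n_new, dtype=float)
        pts = system.tip_pos[i] - h[None, :] * back[:, None]
        beta = np.deg2rad(system.classes["lateral"].branch_angle)
        e1, e2 = _perp_basis(np.tile(h, (n_new, 1)))
        phi = rng.uniform(0.0, 2.0 * np.pi, n_new)
        direction = (np.cos(beta) * h[None, :]
                     + np.sin(beta) * (np.cos(phi)[:, None] * e1
                                       + np.sin(phi)[:, None] * e2))
        spawn_pos.append(_fold_into_box(pts, system.domain))
        spawn_head.append(direction)
        spawn_parent.append(np.full(n_new, system.tip_root_id[i], dtype=int))

    if spawn_pos:
        pos = np.vstack(spawn_pos)
        head = np.vstack(spawn_head)
        parents = np.concatenate(spawn_parent)
        names = ["lateral"] * len(pos)
        rid = system._new_roots(names, parents)
        system._add_tips(pos, head, names, rid, parents, first_frac=0.5)
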